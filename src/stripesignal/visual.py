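"""Receptor-noise-limited (RNL) chromatic and achromatic contrast model.

The model computes, for each receptor class, the quantum catch of a surface
viewed under an illuminant, normalizes catches to an ideal white under the
same illuminant (von Kries adaptation), takes log receptor signals
f_i = ln q_i, and measures perceptual distance between two stimuli in
just-noticeable-difference (JND) units, limited by channel noise expressed
as Weber fractions omega_i = nu / sqrt(eta_i).

Chromatic distance uses the standard RNL forms for dichromats and
trichromats; for an arbitrary number of channels it minimizes the
noise-weighted distance over the achromatic (equal-shift) direction, which
reduces exactly to the published closed forms at n = 2 and n = 3.
Achromatic distance is the log luminance-catch ratio over the luminance
channel's Weber fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum, SpectrumKind, pigment_template

__all__ = [
    "ReceptorClass",
    "VisualSystem",
    "QuantumCatchVector",
    "quantum_catch",
    "adapt",
    "chromatic_contrast",
    "achromatic_contrast",
    "maxwell_coordinates",
    "CATCH_FLOOR",
]

#: Quantum catches are clamped here before logs (near-black numerical safety).
CATCH_FLOOR = 1e-9


@dataclass(frozen=True)
class ReceptorClass:
    """One photoreceptor class: spectral sensitivity plus noise parameters.

    ``weber_fraction`` may be given explicitly; otherwise it is derived by
    the owning :class:`VisualSystem` as nu / sqrt(relative_density).
    """

    name: str
    sensitivity: Spectrum
    relative_density: float = 1.0
    weber_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sensitivity.kind is not SpectrumKind.sensitivity:
            raise ValueError(f"receptor {self.name!r}: sensitivity kind required")
        if self.relative_density <= 0:
            raise ValueError(f"receptor {self.name!r}: relative_density must be > 0")
        if self.weber_fraction is not None and not (0 < self.weber_fraction < 1):
            raise ValueError(f"receptor {self.name!r}: weber_fraction must be in (0, 1)")


@dataclass(frozen=True)
class VisualSystem:
    """Chromatic receptor set plus a luminance (double-cone) channel."""

    chromatic_receptors: tuple[ReceptorClass, ...]
    luminance_receptor: ReceptorClass
    noise_parameter: float = 0.05
    ocular_transmission: Spectrum | None = None

    def __post_init__(self) -> None:
        recs = tuple(self.chromatic_receptors)
        object.__setattr__(self, "chromatic_receptors", recs)
        if len(recs) < 2:
            raise ValueError("need at least 2 chromatic receptor classes")
        names = [r.name for r in recs] + [self.luminance_receptor.name]
        if len(set(names)) != len(names):
            raise ValueError(f"receptor names must be unique, got {names}")
        if self.noise_parameter <= 0:
            raise ValueError("noise_parameter must be > 0")
        grids = {r.sensitivity.wavelength_nm.tobytes() for r in recs}
        grids.add(self.luminance_receptor.sensitivity.wavelength_nm.tobytes())
        if self.ocular_transmission is not None:
            grids.add(self.ocular_transmission.wavelength_nm.tobytes())
        if len(grids) != 1:
            raise ValueError("all sensitivities must share one wavelength grid")

    @property
    def n_chromatic(self) -> int:
        return len(self.chromatic_receptors)

    def weber_fraction(self, receptor: ReceptorClass) -> float:
        """omega_i: explicit value if set, else nu / sqrt(eta_i)."""
        if receptor.weber_fraction is not None:
            return receptor.weber_fraction
        return self.noise_parameter / np.sqrt(receptor.relative_density)

    @property
    def chromatic_weber_fractions(self) -> np.ndarray:
        return np.array([self.weber_fraction(r) for r in self.chromatic_receptors])

    @property
    def luminance_weber_fraction(self) -> float:
        return self.weber_fraction(self.luminance_receptor)

    @classmethod
    def from_lambda_max(
        cls,
        lambda_max_nm: tuple[float, ...] = (455.0, 530.0, 565.0),
        relative_densities: tuple[float, ...] = (1.0, 2.0, 2.0),
        grid: np.ndarray = DEFAULT_GRID,
        omega_longest: float = 0.05,
        luminance_weber_fraction: float = 0.05,
        ocular_transmission: Spectrum | None = None,
    ) -> "VisualSystem":
        """Build a system from pigment peak wavelengths.

        The system noise parameter nu is set so the longest-wavelength
        chromatic receptor has Weber fraction ``omega_longest``.  The
        luminance channel uses the double-cone convention: the peak-normalized
        sum of the two longest-wavelength chromatic sensitivities.
        """
        if len(lambda_max_nm) != len(relative_densities):
            raise ValueError("lambda_max_nm and relative_densities length mismatch")
        if sorted(lambda_max_nm) != list(lambda_max_nm):
            raise ValueError("lambda_max_nm must be ascending")
        receptors = tuple(
            ReceptorClass(
                name=f"cone_{int(round(lm))}",
                sensitivity=pigment_template(lm, grid),
                relative_density=dens,
            )
            for lm, dens in zip(lambda_max_nm, relative_densities)
        )
        nu = omega_longest * np.sqrt(relative_densities[-1])
        lum_vals = sum(r.sensitivity.value for r in receptors[-2:])
        lum_vals = lum_vals / lum_vals.max()
        lum = ReceptorClass(
            name="double_cone",
            sensitivity=Spectrum(np.asarray(grid, float), lum_vals, SpectrumKind.sensitivity),
            weber_fraction=luminance_weber_fraction,
        )
        return cls(receptors, lum, noise_parameter=nu, ocular_transmission=ocular_transmission)


@dataclass(frozen=True)
class QuantumCatchVector:
    """von Kries-adapted catches for one stimulus under one illuminant."""

    adapted_catches: np.ndarray
    luminance_catch: float
    illuminant_id: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.adapted_catches, dtype=float)
        object.__setattr__(self, "adapted_catches", q)
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValueError("adapted catches must be strictly positive and finite")
        if not np.isfinite(self.luminance_catch) or self.luminance_catch <= 0:
            raise ValueError("luminance catch must be strictly positive and finite")


def _check_common_grid(*spectra: Spectrum) -> None:
    ref = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if s is None:
            continue
        if not np.array_equal(s.wavelength_nm, ref):
            raise ValueError("spectra are not on a common wavelength grid")


def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    receptor: ReceptorClass,
    ocular: Spectrum | None = None,
) -> float:
    """Quantum catch Q = integral of R * I * S (* T) over the grid (trapezoid)."""
    if illuminant.kind is not SpectrumKind.irradiance:
        raise ValueError("illuminant must have kind=irradiance")
    _check_common_grid(reflectance, illuminant, receptor.sensitivity)
    if np.all(illuminant.value == 0):
        raise ValueError("illuminant is identically zero")
    integrand = reflectance.value * illuminant.value * receptor.sensitivity.value
    if ocular is not None:
        _check_common_grid(reflectance, ocular)
        integrand = integrand * ocular.value
    return float(np.trapezoid(integrand, reflectance.wavelength_nm))


def adapt(
    reflectance: Spectrum,
    illuminant: Spectrum,
    system: VisualSystem,
    illuminant_id: str = "",
) -> QuantumCatchVector:
    """von Kries adaptation: normalize catches to an ideal white (R = 1).

    Dividing each receptor's catch by its catch for a perfect reflector under
    the same illuminant makes the result invariant to illuminant intensity
    scaling; a perfect white maps to all-ones.
    """
    white = Spectrum(
        reflectance.wavelength_nm,
        np.ones_like(reflectance.wavelength_nm),
        SpectrumKind.reflectance,
    )
    oc = system.ocular_transmission
    q = []
    for rec in system.chromatic_receptors:
        qw = quantum_catch(white, illuminant, rec, oc)
        if qw <= 0:
            raise ValueError(f"zero white catch for receptor {rec.name!r}")
        q.append(quantum_catch(reflectance, illuminant, rec, oc) / qw)
    lum_rec = system.luminance_receptor
    qw_l = quantum_catch(white, illuminant, lum_rec, oc)
    if qw_l <= 0:
        raise ValueError("zero white catch for luminance channel")
    q_l = quantum_catch(reflectance, illuminant, lum_rec, oc) / qw_l
    q = np.maximum(np.asarray(q), CATCH_FLOOR)
    q_l = max(q_l, CATCH_FLOOR)
    return QuantumCatchVector(q, q_l, illuminant_id)


def _log_signal_diffs(a: QuantumCatchVector, b: QuantumCatchVector) -> np.ndarray:
    qa, qb = a.adapted_catches, b.adapted_catches
    if qa.shape != qb.shape:
        raise ValueError("catch vectors have different numbers of receptors")
    return np.log(qa) - np.log(qb)


def chromatic_contrast(
    a: QuantumCatchVector, b: QuantumCatchVector, system: VisualSystem
) -> float:
    """RNL chromatic distance Delta S in JND between two adapted stimuli.

    n = 2:  |df_1 - df_2| / sqrt(w1^2 + w2^2)
    n = 3:  the standard trichromat quadratic form
    n >= 4: noise-weighted distance minimized over the achromatic direction,
            min_c sum_i (df_i - c)^2 / w_i^2, which coincides with the
            closed forms above for n = 2, 3.
    """
    df = _log_signal_diffs(a, b)
    w = system.chromatic_weber_fractions
    if df.size != w.size:
        raise ValueError("catch vector does not match the visual system")
    if df.size == 2:
        return float(abs(df[0] - df[1]) / np.hypot(w[0], w[1]))
    if df.size == 3:
        w1, w2, w3 = w
        num = (
            w1**2 * (df[1] - df[2]) ** 2
            + w2**2 * (df[0] - df[2]) ** 2
            + w3**2 * (df[0] - df[1]) ** 2
        )
        den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
        return float(np.sqrt(num / den))
    u = 1.0 / w**2
    c = np.sum(u * df) / np.sum(u)
    return float(np.sqrt(np.sum(u * (df - c) ** 2)))


def achromatic_contrast(
    a: QuantumCatchVector, b: QuantumCatchVector, system: VisualSystem
) -> float:
    """Achromatic distance Delta L = |ln(qL_a / qL_b)| / omega_L in JND."""
    w_l = system.luminance_weber_fraction
    return float(abs(np.log(a.luminance_catch) - np.log(b.luminance_catch)) / w_l)


# Unit-side equilateral triangle centred at the origin; vertex order follows
# the receptor order (short, mid, long).
_MAXWELL_VERTICES = np.array(
    [
        [0.0, 1.0 / np.sqrt(3.0)],
        [-0.5, -0.5 / np.sqrt(3.0)],
        [0.5, -0.5 / np.sqrt(3.0)],
    ]
)


def maxwell_coordinates(a: QuantumCatchVector) -> tuple[float, float]:
    """Map a trichromatic catch vector to Maxwell-triangle coordinates.

    Catches are normalized to barycentric weights (sum one) and mapped to a
    unit-side equilateral triangle centred at the origin.
    """
    q = a.adapted_catches
    if q.size != 3:
        raise ValueError(f"Maxwell triangle needs 3 chromatic catches, got {q.size}")
    bary = q / q.sum()
    xy = bary @ _MAXWELL_VERTICES
    return float(xy[0]), float(xy[1])
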