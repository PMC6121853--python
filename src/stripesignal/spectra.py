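"""Spectral data model, resampling, pigment templates, and underwater light.

All downstream visual modeling works on a single common wavelength grid
(:data:`DEFAULT_GRID`, 300-750 nm at 1 nm) so that reflectance, irradiance
and sensitivity curves can be multiplied point-wise without silent
misalignment.  A :class:`Spectrum` is a thin validated container around two
NumPy vectors; a :class:`LightEnvironment` combines a surface irradiance
with a diffuse attenuation coefficient K(lambda) and a depth, from which the
ambient (depth-attenuated) irradiance follows by Beer-Lambert decay.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "LightEnvironment",
    "DEFAULT_GRID",
    "REFLECTANCE_FLOOR",
    "resample",
    "pigment_template",
    "ambient_irradiance",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_long",
    "write_spectra_long",
]

#: Default working grid: 300-750 nm, 1 nm steps (covers the fish-visible range).
DEFAULT_GRID = np.arange(300.0, 751.0, 1.0)

#: Floor applied to spectra before any downstream log transform; black patches
#: approach zero reflectance and logs must stay finite.
REFLECTANCE_FLOOR = 1e-6


class SpectrumKind(str, enum.Enum):
    """What physical quantity a spectrum carries."""

    reflectance = "reflectance"
    irradiance = "irradiance"
    sensitivity = "sensitivity"
    transmission = "transmission"


# Kinds whose values are proportions bounded by 1.  ``transmission`` is left
# unbounded because it doubles as storage for diffuse attenuation coefficients
# K(lambda) in 1/m, which share the "fraction surviving" semantics but not the
# upper bound.
_BOUNDED_KINDS = {SpectrumKind.reflectance, SpectrumKind.sensitivity}


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed curve.

    Parameters
    ----------
    wavelength_nm
        Strictly ascending wavelengths in nanometres, length >= 2.
    value
        Non-negative finite values, same length.  Reflectance and
        sensitivity are proportions in [0, 1]; irradiance is photon
        irradiance in arbitrary units.
    kind
        One of :class:`SpectrumKind`.
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    kind: SpectrumKind = SpectrumKind.reflectance

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if wl.ndim != 1 or val.ndim != 1 or wl.shape != val.shape:
            raise ValueError("wavelength_nm and value must be 1-D of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(val)):
            raise ValueError("spectrum values must be finite")
        if np.any(val < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.kind in _BOUNDED_KINDS and np.any(val > 1.0 + 1e-9):
            raise ValueError(f"{self.kind.value} values must be <= 1")

    def __len__(self) -> int:
        return self.wavelength_nm.size

    def on_grid(self, grid: np.ndarray) -> bool:
        """True if this spectrum is sampled exactly on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        return (
            self.wavelength_nm.shape == grid.shape
            and np.array_equal(self.wavelength_nm, grid)
        )

    def clamped(self, floor: float = REFLECTANCE_FLOOR) -> "Spectrum":
        """Return a copy with values clamped from below (log safety)."""
        return replace(self, value=np.maximum(self.value, floor))


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The target grid must lie inside the source range (no extrapolation).
    Idempotent on the spectrum's own grid; kind is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly ascending")
    lo, hi = s.wavelength_nm[0], s.wavelength_nm[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside source range [{lo}, {hi}]"
        )
    if s.on_grid(grid):
        return s
    vals = np.interp(grid, s.wavelength_nm, s.value)
    if grid.size < 2:
        # single-point queries are returned as a 2-sample degenerate pair is
        # not allowed; callers asking for one node get a plain value instead
        raise ValueError("grid must contain at least 2 wavelengths; use interp_at")
    return Spectrum(grid, vals, s.kind)


def interp_at(s: Spectrum, wavelength_nm: float) -> float:
    """Evaluate a spectrum at a single wavelength by linear interpolation."""
    lo, hi = s.wavelength_nm[0], s.wavelength_nm[-1]
    if not (lo <= wavelength_nm <= hi):
        raise ValueError(f"{wavelength_nm} nm outside source range [{lo}, {hi}]")
    return float(np.interp(wavelength_nm, s.wavelength_nm, s.value))


# --- visual-pigment nomogram ------------------------------------------------

# A1-pigment template constants (alpha band) and the beta-band Gaussian.
# The alpha band is 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)
# with x = lambda_max / lambda; the beta band is a Gaussian rider on the
# short-wavelength limb.  Constants are the published A1 values.
_ALPHA_A = 69.7
_ALPHA_B = 28.0
_ALPHA_b = 0.922
_ALPHA_C = -14.9
_ALPHA_c = 1.104
_ALPHA_D = 0.674

_BETA_AMP = 0.26


def _alpha_band(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    x = lambda_max / wl
    return 1.0 / (
        np.exp(_ALPHA_A * (a - x))
        + np.exp(_ALPHA_B * (_ALPHA_b - x))
        + np.exp(_ALPHA_C * (_ALPHA_c - x))
        + _ALPHA_D
    )


def _beta_band(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    return _BETA_AMP * np.exp(-(((wl - lm_beta) / b_beta) ** 2))


def pigment_template(
    lambda_max: float,
    grid: np.ndarray = DEFAULT_GRID,
    include_beta: bool = True,
) -> Spectrum:
    """Synthesize an A1 visual-pigment absorbance template.

    Sums the alpha band and (optionally) the beta band of the standard A1
    nomogram and peak-normalizes over ``grid`` so the maximum equals 1.

    Parameters
    ----------
    lambda_max
        Peak wavelength of the alpha band, nm; must be in [330, 600].
    grid
        Wavelength grid to evaluate on.
    include_beta
        Include the short-wavelength beta band (default True).
    """
    if not (330.0 <= lambda_max <= 600.0):
        raise ValueError(f"lambda_max {lambda_max} nm outside supported range 330-600")
    wl = np.asarray(grid, dtype=float)
    sens = _alpha_band(lambda_max, wl)
    if include_beta:
        sens = sens + _beta_band(lambda_max, wl)
    sens = np.clip(sens / sens.max(), 0.0, 1.0)
    return Spectrum(wl, sens, SpectrumKind.sensitivity)


# --- light environment ------------------------------------------------------


@dataclass(frozen=True)
class LightEnvironment:
    """Surface irradiance plus depth-dependent attenuation.

    ``attenuation`` holds the diffuse attenuation coefficient K(lambda) in
    1/m (stored with ``kind=transmission``, values unbounded above).
    """

    surface_irradiance: Spectrum
    attenuation: Spectrum
    depth_m: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError("depth_m must be non-negative")
        if self.surface_irradiance.kind is not SpectrumKind.irradiance:
            raise ValueError("surface_irradiance must have kind=irradiance")


def ambient_irradiance(env: LightEnvironment) -> Spectrum:
    """Depth-attenuated ambient irradiance I_d = I_0 * exp(-K * depth)."""
    s0, k = env.surface_irradiance, env.attenuation
    if not np.array_equal(s0.wavelength_nm, k.wavelength_nm):
        raise ValueError(
            "surface irradiance and attenuation must share a wavelength grid; "
            "resample them first"
        )
    vals = s0.value * np.exp(-k.value * env.depth_m)
    return Spectrum(s0.wavelength_nm, vals, SpectrumKind.irradiance)


# --- CSV I/O ----------------------------------------------------------------

# Dialect: UTF-8, '.' decimal, header row.  Single spectra use two columns
# (wavelength_nm, value); collections use long format with columns
# (spectrum_id, kind, wavelength_nm, value).


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelength_nm, "value": s.value}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path, kind: SpectrumKind | str) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), kind
    )


def write_spectra_long(spectra: dict[str, Spectrum], path) -> None:
    frames = []
    for sid, s in spectra.items():
        frames.append(
            pd.DataFrame(
                {
                    "spectrum_id": sid,
                    "kind": s.kind.value,
                    "wavelength_nm": s.wavelength_nm,
                    "value": s.value,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_long(path) -> dict[str, Spectrum]:
    df = pd.read_csv(path)
    out: dict[str, Spectrum] = {}
    for sid, grp in df.groupby("spectrum_id", sort=False):
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"spectrum {sid!r} has mixed kinds {list(kinds)}")
        grp = grp.sort_values("wavelength_nm")
        out[str(sid)] = Spectrum(
            grp["wavelength_nm"].to_numpy(float),
            grp["value"].to_numpy(float),
            kinds[0],
        )
    return out
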