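"""Seeded synthetic data emulating the study's measurements.

Everything the three analysis stages consume can be generated here with a
known statistical structure: facial-patch reflectance spectra (five
patches; the black horizontal stripe brightens when the fish pales), a
trichromatic-plus-luminance visual system built from pigment templates, a
depth-attenuated underwater light field, staged dyadic contests (matched
pairs, ethogram event streams, end-of-contest paling of losers), and
mirror-image-stimulation trials (two of three treatments per fish, bout
counts with treatment multipliers, latencies with censoring).

Default parameter values are synthetic study conditions chosen to mirror
the qualitative structure of the system being emulated (paling raises
stripe reflectance; losers pale, winners mostly do not; manipulated signals
draw more and faster aggression than controls) at realistic sample sizes;
they are not measured values.  All generators are deterministic given
(seed, config).
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .conspicuousness import ColorPatch, PATCH_LABELS
from .contest import DEFAULT_ETHOGRAM, score_ethogram
from .spectra import DEFAULT_GRID, LightEnvironment, Spectrum, SpectrumKind
from .visual import VisualSystem

__all__ = [
    "SyntheticConfig",
    "gen_face_spectra",
    "gen_spectra_dataset",
    "gen_visual_system",
    "gen_light_environment",
    "gen_behavior_events",
    "gen_contests",
    "gen_mis_trials",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0

    # sample sizes
    n_fish: int = 24  # mirror-trial subjects (two trials each)
    n_pairs: int = 20  # contest dyads
    n_spectra_fish: int = 10  # fish measured per stripe state

    # spectral parameters (reflectance proportions)
    r_dark: float = 0.04  # black stripe, dark state
    r_pale: float = 0.30  # horizontal stripe after paling
    white_level: float = 0.80
    white_tilt: float = 0.12  # gentle warm slope of the white patch
    blue_peak_nm: float = 470.0
    blue_width_nm: float = 35.0
    blue_amplitude: float = 0.55
    blue_base: float = 0.05
    yellow_cutoff_nm: float = 520.0
    yellow_steepness_nm: float = 12.0
    yellow_level: float = 0.65
    yellow_base: float = 0.04
    spectral_noise_sd: float = 0.05  # smooth multiplicative measurement noise

    # visual system
    lambda_max_nm: tuple[float, ...] = (455.0, 530.0, 565.0)
    relative_densities: tuple[float, ...] = (1.0, 2.0, 2.0)
    omega_longest: float = 0.05
    luminance_weber_fraction: float = 0.05

    # light environment
    depth_m: float = 10.0
    attenuation_min: float = 0.04  # 1/m at the clearest wavelength
    attenuation_clear_nm: float = 490.0  # centre of the clear-water window

    # contests
    size_effect: float = 6.0  # logit slope of win prob on length diff (per cm)
    length_mean_cm: float = 6.0
    length_sd_cm: float = 0.8
    pair_length_sd_cm: float = 0.25  # within-pair matching tightness
    p_pale_loser: float = 0.9
    p_pale_winner: float = 0.1
    rate_aggressive_winner: float = 30.0  # expected events per contest
    rate_aggressive_loser: float = 14.0
    rate_submissive_winner: float = 4.0
    rate_submissive_loser: float = 18.0
    rate_neutral: float = 10.0
    contest_duration_s: float = 1200.0

    # mirror-image-stimulation trials
    bout_baseline: float = 10.0
    bout_multipliers: dict = field(
        default_factory=lambda: {"control": 1.0, "paled": 1.5, "darkened": 2.6}
    )
    individual_sd: float = 0.3  # SD of per-fish log-scale random effect
    order_effect: float = 0.0  # log-scale shift of the second trial
    latency_baseline_s: float = 60.0
    latency_multipliers: dict = field(
        default_factory=lambda: {"control": 1.0, "darkened": 1.0 / 1.7, "paled": 1.0 / 1.2}
    )
    latency_sigma: float = 0.5  # lognormal shape
    trial_duration_s: float = 600.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_pale_loser <= 1 and 0 <= self.p_pale_winner <= 1):
            raise ValueError("paling probabilities must be in [0, 1]")
        if self.r_pale <= self.r_dark:
            raise ValueError("paling must raise reflectance: r_pale > r_dark required")
        for name in ("bout_multipliers", "latency_multipliers"):
            m = getattr(self, name)
            if set(m) != {"control", "paled", "darkened"} or any(v <= 0 for v in m.values()):
                raise ValueError(f"{name} must map all three treatments to values > 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lambda_max_nm"] = list(self.lambda_max_nm)
        d["relative_densities"] = list(self.relative_densities)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("lambda_max_nm", "relative_densities"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _rng(config: SyntheticConfig, *keys) -> np.random.Generator:
    """Deterministic per-entity generator: seed + stable hash of the keys."""
    tokens = [config.seed & 0x7FFFFFFF]
    for k in keys:
        tokens.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(tokens)


def _smooth_noise(rng: np.random.Generator, grid: np.ndarray, sd: float) -> np.ndarray:
    """Smooth multiplicative noise field: coarse normal knots, interpolated."""
    if sd == 0:
        return np.ones_like(grid)
    knots = np.linspace(grid[0], grid[-1], 8)
    vals = rng.normal(0.0, sd, knots.size)
    return np.exp(np.interp(grid, knots, vals))


def _base_reflectance(config: SyntheticConfig, label: str, stripe_level: float) -> np.ndarray:
    wl = DEFAULT_GRID
    if label == "black_horizontal_stripe":
        return np.full_like(wl, stripe_level)
    if label == "black_vertical_stripe":
        return np.full_like(wl, config.r_dark)
    if label == "white":
        # broadband reflector with a gentle warm tilt, as in real scale tissue
        tilt = 1.0 + config.white_tilt * (wl - 525.0) / 450.0
        return np.clip(config.white_level * tilt, 0.0, 1.0)
    if label == "blue":
        return config.blue_base + config.blue_amplitude * np.exp(
            -0.5 * ((wl - config.blue_peak_nm) / config.blue_width_nm) ** 2
        )
    if label == "yellow":
        return config.yellow_base + config.yellow_level / (
            1.0 + np.exp(-(wl - config.yellow_cutoff_nm) / config.yellow_steepness_nm)
        )
    raise ValueError(f"unknown patch label {label!r}")


#: States in which the horizontal stripe is pale rather than dark.
_PALE_STATES = {"subordinate", "manipulated_pale"}
_VALID_STATES = {"dominant", "subordinate", "manipulated_dark", "manipulated_pale", "control"}


def gen_face_spectra(config: SyntheticConfig, fish_id: str, state: str) -> list[ColorPatch]:
    """Generate the five facial-patch reflectance spectra for one fish.

    The horizontal stripe is dark (``r_dark``) in dominant, control and
    darkened-manipulation states and pale (``r_pale``) in subordinate and
    paled-manipulation states; the vertical stripe is always dark.  Smooth
    multiplicative noise (per fish/state/patch) emulates measurement and
    between-individual variation.
    """
    if state not in _VALID_STATES:
        raise ValueError(f"unknown state {state!r}")
    stripe_level = config.r_pale if state in _PALE_STATES else config.r_dark
    patches = []
    for label in PATCH_LABELS:
        base = _base_reflectance(config, label, stripe_level)
        rng = _rng(config, "spectra", fish_id, state, label)
        noisy = np.clip(base * _smooth_noise(rng, DEFAULT_GRID, config.spectral_noise_sd), 0.0, 1.0)
        patches.append(
            ColorPatch(
                patch_label=label,
                fish_id=fish_id,
                state=state,
                reflectance=Spectrum(DEFAULT_GRID.copy(), noisy, SpectrumKind.reflectance),
            )
        )
    return patches


def gen_spectra_dataset(
    config: SyntheticConfig, states: tuple[str, ...] = ("dominant", "subordinate")
) -> list[ColorPatch]:
    """Patch spectra for ``n_spectra_fish`` fish in each requested state.

    Distinct fish are generated per state (measuring different individuals
    in each stripe state, as when dominants and subordinates are sampled
    from contest outcomes).
    """
    out: list[ColorPatch] = []
    for state in states:
        for i in range(config.n_spectra_fish):
            out.extend(gen_face_spectra(config, f"{state[:3]}_{i:02d}", state))
    return out


def gen_visual_system(config: SyntheticConfig) -> VisualSystem:
    """Trichromatic-plus-luminance system from the configured pigment peaks."""
    if not (2 <= len(config.lambda_max_nm) <= 4):
        raise ValueError("need 2-4 pigment peaks")
    return VisualSystem.from_lambda_max(
        lambda_max_nm=config.lambda_max_nm,
        relative_densities=config.relative_densities,
        grid=DEFAULT_GRID,
        omega_longest=config.omega_longest,
        luminance_weber_fraction=config.luminance_weber_fraction,
    )


def gen_light_environment(config: SyntheticConfig) -> LightEnvironment:
    """Broadband surface light over a clear-water attenuation window.

    The surface irradiance is a smooth broadband curve peaking in the
    visible; the diffuse attenuation coefficient K(lambda) is U-shaped with
    its minimum inside the 450-550 nm clear-water window, so ambient light
    at depth concentrates there.
    """
    wl = DEFAULT_GRID
    surface = 0.15 + np.exp(-0.5 * ((wl - 560.0) / 130.0) ** 2)
    k = config.attenuation_min + 2e-5 * (wl - config.attenuation_clear_nm) ** 2
    return LightEnvironment(
        surface_irradiance=Spectrum(wl.copy(), surface, SpectrumKind.irradiance),
        attenuation=Spectrum(wl.copy(), k, SpectrumKind.transmission),
        depth_m=config.depth_m,
    )


_AGGRESSIVE_CODES = [c for c, v in DEFAULT_ETHOGRAM.items() if v == "aggressive"]
_SUBMISSIVE_CODES = [c for c, v in DEFAULT_ETHOGRAM.items() if v == "submissive"]
_NEUTRAL_CODES = [c for c, v in DEFAULT_ETHOGRAM.items() if v == "neutral"]


def gen_behavior_events(
    config: SyntheticConfig,
    fish_id: str,
    rate_aggressive: float,
    rate_submissive: float,
    key: str = "events",
) -> pd.DataFrame:
    """Poisson event stream for one fish over the contest duration."""
    rng = _rng(config, key, fish_id)
    rows = []
    for rate, codes in (
        (rate_aggressive, _AGGRESSIVE_CODES),
        (rate_submissive, _SUBMISSIVE_CODES),
        (config.rate_neutral, _NEUTRAL_CODES),
    ):
        n = rng.poisson(rate)
        times = rng.uniform(0.0, config.contest_duration_s, n)
        for t in times:
            rows.append(
                {
                    "time_s": float(t),
                    "actor_id": fish_id,
                    "behavior_code": codes[rng.integers(len(codes))],
                }
            )
    df = pd.DataFrame(rows, columns=["time_s", "actor_id", "behavior_code"])
    return df.sort_values("time_s").reset_index(drop=True)


def gen_contests(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate matched dyadic contests.

    Returns ``(dyads, events)``: one row per fish in ``dyads`` (pair id,
    sex, morphometrics, behavior counts, stripe states, winner id) and the
    pooled behavior-event stream in ``events``.  Pairs are size-matched
    with small within-pair differences; win probability follows a logistic
    function of the within-pair length difference; winners show higher
    aggressive and lower submissive rates; both fish start dark and losers
    pale with probability ``p_pale_loser`` (winners ``p_pale_winner``).
    """
    if config.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    dyad_rows = []
    event_frames = []
    for p in range(config.n_pairs):
        rng = _rng(config, "contest", p)
        sex = "m" if p % 2 == 0 else "f"
        base_len = rng.normal(config.length_mean_cm, config.length_sd_cm)
        lens = base_len + rng.normal(0.0, config.pair_length_sd_cm, 2)
        masses = 0.025 * lens**3 * np.exp(rng.normal(0.0, 0.05, 2))
        ids = [f"P{p:03d}_A", f"P{p:03d}_B"]
        # logistic win probability on the length difference
        p_a_wins = 1.0 / (1.0 + np.exp(-config.size_effect * (lens[0] - lens[1])))
        winner_idx = 0 if rng.random() < p_a_wins else 1
        for i in (0, 1):
            is_winner = i == winner_idx
            ra = config.rate_aggressive_winner if is_winner else config.rate_aggressive_loser
            rs = config.rate_submissive_winner if is_winner else config.rate_submissive_loser
            ev = gen_behavior_events(config, ids[i], ra, rs)
            event_frames.append(ev.assign(pair_id=f"P{p:03d}"))
            agg, sub = score_ethogram(ev, ids[i])
            p_pale = config.p_pale_loser if not is_winner else config.p_pale_winner
            pale = rng.random() < p_pale
            dyad_rows.append(
                {
                    "pair_id": f"P{p:03d}",
                    "fish_id": ids[i],
                    "sex": sex,
                    "standard_length_cm": float(lens[i]),
                    "mass_g": float(masses[i]),
                    "stripe_begin": "dark",
                    "stripe_end": "pale" if pale else "dark",
                    "aggressive_count": agg,
                    "submissive_count": sub,
                    "winner_id": ids[winner_idx],
                }
            )
    dyads = pd.DataFrame(dyad_rows)
    events = pd.concat(event_frames, ignore_index=True)
    return dyads, events


def gen_mis_trials(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate mirror-image-stimulation trials.

    Each fish receives two of the three treatments, drawn uniformly without
    replacement, in randomized order.  Bout counts are Poisson-lognormal
    (log-mean = log baseline + log treatment multiplier + individual effect
    + order effect), which gives the overdispersion real bout counts show;
    latencies are lognormal with treatment multipliers and right-censored
    at the trial duration.
    """
    if config.n_fish < 3:
        raise ValueError("n_fish must be >= 3")
    rows = []
    for i in range(config.n_fish):
        rng = _rng(config, "mis", i)
        fish = f"F{i:03d}"
        sex = "m" if i % 2 == 0 else "f"
        pair = rng.choice(len(_TREATMENT_PAIRS))
        trs = list(_TREATMENT_PAIRS[pair])
        rng.shuffle(trs)
        a_i = rng.normal(0.0, config.individual_sd)
        for order, tr in enumerate(trs, start=1):
            log_mu = (
                np.log(config.bout_baseline)
                + np.log(config.bout_multipliers[tr])
                + a_i
                + (config.order_effect if order == 2 else 0.0)
            )
            bouts = int(rng.poisson(np.exp(log_mu)))
            lat = float(
                np.exp(
                    np.log(config.latency_baseline_s * config.latency_multipliers[tr])
                    + rng.normal(0.0, config.latency_sigma)
                )
            )
            censored = lat >= config.trial_duration_s
            rows.append(
                {
                    "fish_id": fish,
                    "sex": sex,
                    "treatment": tr,
                    "order_index": order,
                    "aggressive_bouts": bouts,
                    "latency_s": min(lat, config.trial_duration_s),
                    "censored": censored,
                }
            )
    return pd.DataFrame(rows)


_TREATMENT_PAIRS = (
    ("darkened", "paled"),
    ("darkened", "control"),
    ("paled", "control"),
)
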