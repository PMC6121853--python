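"""Out-of-equilibrium manipulation analysis (mirror-image stimulation).

Each fish faces its own mirror image twice, with the facial stripe of the
"opponent" (its reflection) manipulated to one of three states: darkened,
paled, or a sham-manipulated control.  Aggression received by the
manipulated signal (bout counts, latency to first attack) measures the
social cost of unreliable signaling.

Models: LMMs with treatment, sex and their interaction as fixed effects
and crossed random intercepts for individual and trial order; bout counts
are square-root transformed.  Treatment levels are compared post hoc with
single-step (Tukey-type) familywise-adjusted z tests on the fitted
contrasts, and effect sizes are reported as ratios of treatment means with
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .lmm import MixedModelFit, fit_random_intercept_lmm

__all__ = [
    "TREATMENTS",
    "validate_trials",
    "mis_lmm",
    "tukey_posthoc",
    "fold_effects",
]

TREATMENTS = ("darkened", "paled", "control")

#: Default trial duration (s); latencies are right-censored here.
DEFAULT_TRIAL_DURATION_S = 600.0


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the two-of-three within-fish trial design invariants."""
    need = ["fish_id", "sex", "treatment", "order_index", "aggressive_bouts", "latency_s"]
    missing = [c for c in need if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table missing columns: {missing}")
    bad_tr = set(trials["treatment"]) - set(TREATMENTS)
    if bad_tr:
        raise ValueError(f"unknown treatments: {bad_tr}")
    per_fish = trials.groupby("fish_id").agg(
        n=("treatment", "size"), ntr=("treatment", "nunique"), no=("order_index", "nunique")
    )
    bad = per_fish[(per_fish["n"] != 2) | (per_fish["ntr"] != 2) | (per_fish["no"] != 2)]
    if not bad.empty:
        raise ValueError(
            f"each fish must have exactly 2 trials with 2 distinct treatments and "
            f"orders; offending fish: {list(bad.index)}"
        )
    if (trials["aggressive_bouts"] < 0).any():
        raise ValueError("aggressive_bouts must be >= 0")
    if (trials["latency_s"] <= 0).any():
        raise ValueError("latency_s must be positive")
    df = trials.copy()
    if "censored" not in df.columns:
        df["censored"] = False
    return df


def mis_lmm(
    trials: pd.DataFrame,
    response: str = "bouts",
    latency_transform: str | None = None,
) -> MixedModelFit:
    """LMM of aggression received on treatment, sex and their interaction.

    Random intercepts for individual and trial order (crossed).  The bouts
    response is square-root transformed; latency is left untransformed by
    default (``latency_transform="log"`` is available) and censored trials
    (no attack within the trial) are excluded from the latency model.
    """
    df = validate_trials(trials)
    present = set(df["treatment"])
    absent = set(TREATMENTS) - present
    if absent:
        raise ValueError(f"treatment level(s) absent from the data: {sorted(absent)}")
    if df["fish_id"].nunique() < 10:
        raise ValueError("need at least 10 fish")

    if response == "bouts":
        resp, transform = "aggressive_bouts", "sqrt"
    elif response == "latency":
        resp = "latency_s"
        transform = None
        if latency_transform == "log":
            df["latency_s"] = np.log(df["latency_s"])
        elif latency_transform is not None:
            raise ValueError(f"unknown latency transform {latency_transform!r}")
        n_cens = int(df["censored"].sum())
        if n_cens:
            warnings.warn(f"excluding {n_cens} censored latency trial(s)", stacklevel=2)
            df = df[~df["censored"]]
    else:
        raise ValueError("response must be 'bouts' or 'latency'")

    df = df.reset_index(drop=True)
    dark = (df["treatment"] == "darkened").astype(float).to_numpy()
    pale = (df["treatment"] == "paled").astype(float).to_numpy()
    sexes = sorted(df["sex"].unique())
    cols = {"Intercept": 1.0, "tr_darkened": dark, "tr_paled": pale}
    terms = {"treatment": ["tr_darkened", "tr_paled"]}
    if len(sexes) > 1:
        sex_m = (df["sex"] == sexes[-1]).astype(float).to_numpy()
        cols["sex"] = sex_m
        cols["tr_darkened:sex"] = dark * sex_m
        cols["tr_paled:sex"] = pale * sex_m
        terms["sex"] = ["sex"]
        terms["treatment:sex"] = ["tr_darkened:sex", "tr_paled:sex"]
    else:
        warnings.warn("single sex present; dropping sex terms", stacklevel=2)
    X = pd.DataFrame(cols)
    return fit_random_intercept_lmm(
        df,
        response=resp,
        design=X,
        terms=terms,
        group="fish_id",
        crossed=["order_index"],
        transform=transform,
        formula=f"{resp} ~ treatment * sex + (1 | fish) + (1 | order)",
    )


def _treatment_contrasts(fit: MixedModelFit) -> dict[str, np.ndarray]:
    """Contrast vectors for pairwise treatment-level marginal means.

    Marginal means average over the sexes with equal weight, so with the
    0/1 dummy coding each treatment coefficient contributes 1 and its sex
    interaction 1/2.
    """
    names = list(fit.params.index)
    has_sex = "sex" in names

    def level_vec(level: str) -> np.ndarray:
        v = np.zeros(len(names))
        if level != "control":
            v[names.index(f"tr_{level}")] = 1.0
            if has_sex:
                v[names.index(f"tr_{level}:sex")] = 0.5
        return v

    return {
        "darkened - control": level_vec("darkened") - level_vec("control"),
        "paled - control": level_vec("paled") - level_vec("control"),
        "darkened - paled": level_vec("darkened") - level_vec("paled"),
    }


def tukey_posthoc(fit: MixedModelFit) -> pd.DataFrame:
    """Single-step familywise-adjusted pairwise treatment comparisons.

    For each of the three treatment contrasts a z statistic is formed from
    the fitted fixed effects and their covariance; adjusted p-values are
    computed single-step from the joint normal distribution of the three
    statistics (the Tukey-type max-|z| adjustment), so the familywise error
    over the three comparisons is controlled.
    """
    contrasts = _treatment_contrasts(fit)
    C = np.vstack(list(contrasts.values()))
    V = fit.cov_params.to_numpy()
    est = C @ fit.params.to_numpy()
    cov = C @ V @ C.T
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # degenerate noise-free fit: all contrasts and their variances vanish
    tol = 1e-8 * max(1.0, float(np.abs(fit.params).max()))
    if np.all(sd < tol):
        if np.all(np.abs(est) < tol):
            return pd.DataFrame(
                [
                    {"comparison": name, "estimate": 0.0, "se": 0.0, "z": 0.0, "p_adj": 1.0}
                    for name in contrasts
                ]
            )
        raise np.linalg.LinAlgError("rank-deficient contrast covariance")
    z = est / sd
    R = cov / np.outer(sd, sd)
    R = (R + R.T) / 2.0 + 1e-10 * np.eye(len(z))
    # single-step max-|t| adjustment over the joint distribution of the
    # three statistics; denominator df taken from the treatment term's
    # containment df so small-sample familywise error stays near nominal.
    # The CDF integrator is quasi-Monte Carlo, hence the fixed internal
    # seed: adjusted p-values must be reproducible run to run.
    ddf = float(fit.anova.loc[fit.anova["term"] == "treatment", "df_den"].iloc[0])
    mvt = st.multivariate_t(
        loc=np.zeros(len(z)), shape=R, df=ddf, allow_singular=True, seed=0
    )
    rows = []
    for k, name in enumerate(contrasts):
        zk = abs(z[k])
        inside = float(mvt.cdf(np.full(len(z), zk), lower_limit=np.full(len(z), -zk)))
        rows.append(
            {
                "comparison": name,
                "estimate": float(est[k]),
                "se": float(sd[k]),
                "z": float(z[k]),
                "p_adj": float(min(max(1.0 - inside, 0.0), 1.0)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class _Ratio:
    name: str
    value: float
    lo: float
    hi: float


def fold_effects(
    trials: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratios of treatment means: how much more (and faster) aggression.

    Bout ratios compare mean aggressive bouts between treatments
    (darkened/paled, darkened/control, paled/control); latency ratios are
    oriented as control/treatment so that values > 1 mean *faster* attack
    under the manipulated signal.  Censored latencies are excluded from the
    latency means but counted in the output.  Confidence intervals are
    percentile bootstrap over fish (cluster resampling), seeded.
    """
    df = validate_trials(trials)
    absent = set(TREATMENTS) - set(df["treatment"])
    if absent:
        raise ValueError(f"treatment level(s) absent: {sorted(absent)}")

    def ratios(frame: pd.DataFrame) -> dict[str, float]:
        mb = frame.groupby("treatment")["aggressive_bouts"].mean()
        lat = frame[~frame["censored"]]
        ml = lat.groupby("treatment")["latency_s"].mean()
        out = {}
        pairs_bouts = [
            ("bouts darkened/paled", "darkened", "paled"),
            ("bouts darkened/control", "darkened", "control"),
            ("bouts paled/control", "paled", "control"),
        ]
        for name, num, den in pairs_bouts:
            d = mb.get(den, np.nan)
            out[name] = mb.get(num, np.nan) / d if (np.isfinite(d) and d != 0) else np.nan
        for name, num, den in [
            ("latency control/darkened", "control", "darkened"),
            ("latency control/paled", "control", "paled"),
        ]:
            d = ml.get(den, np.nan)
            out[name] = ml.get(num, np.nan) / d if d and np.isfinite(d) else np.nan
        return out

    point = ratios(df)
    fish = df["fish_id"].unique()
    rng = np.random.default_rng(seed)
    boot = {k: [] for k in point}
    by_fish = {f: g for f, g in df.groupby("fish_id")}
    for _ in range(n_boot):
        take = rng.choice(fish, size=len(fish), replace=True)
        bs = pd.concat([by_fish[f] for f in take], ignore_index=True)
        r = ratios(bs)
        for k, v in r.items():
            boot[k].append(v)
    rows = []
    n_cens = int(df["censored"].sum())
    for k, v in point.items():
        bvals = np.asarray(boot[k], dtype=float)
        bvals = bvals[np.isfinite(bvals)]
        lo, hi = (np.percentile(bvals, [2.5, 97.5]) if bvals.size else (np.nan, np.nan))
        rows.append(
            {
                "ratio": k,
                "value": float(v) if np.isfinite(v) else np.nan,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "n_trials": len(df),
                "n_censored_latency": n_cens,
            }
        )
    return pd.DataFrame(rows)
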