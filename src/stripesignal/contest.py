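"""Dyadic-contest analysis: who wins, and what the stripe says about it.

Staged territorial combats between size- and sex-matched fish are scored
from an ethogram into aggressive and submissive behavior counts; a
fighting-ability index is their difference.  The analyses ask

* whether the matching held (paired signed-rank tests on within-pair length
  and mass differences),
* whether winners differ from losers in mass and fighting ability
  (random-intercept LMMs with pair as the grouping factor), and
* whether the horizontal-stripe state (pale/dark) at the start or end of
  the contest is associated with winning (binomial random-intercept GLMM
  with a single-df likelihood-ratio test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .glmm import GlmmFit, fit_binomial_glmm, glmm_lrt
from .lmm import MixedModelFit, fit_random_intercept_lmm

__all__ = [
    "DEFAULT_ETHOGRAM",
    "score_ethogram",
    "fighting_ability",
    "matching_test",
    "outcome_lmm",
    "stripe_outcome_glmm",
    "StripeOutcomeResult",
]

#: Behavior-code -> valence mapping (the ethogram).  Config-overridable.
DEFAULT_ETHOGRAM: dict[str, str] = {
    # aggressive repertoire
    "bite": "aggressive",
    "chase": "aggressive",
    "ram": "aggressive",
    "mouth_fight": "aggressive",
    "lateral_display": "aggressive",
    "frontal_display": "aggressive",
    "fin_spread": "aggressive",
    # submissive repertoire
    "flee": "submissive",
    "retreat": "submissive",
    "submissive_posture": "submissive",
    "tail_quiver": "submissive",
    "freeze": "submissive",
    # neutral maintenance behaviors
    "swim": "neutral",
    "hover": "neutral",
    "feed": "neutral",
    "dig": "neutral",
}

_VALENCES = ("aggressive", "submissive", "neutral")


def score_ethogram(
    events: pd.DataFrame,
    fish_id: str,
    ethogram: dict[str, str] | None = None,
) -> tuple[int, int]:
    """Count aggressive and submissive behaviors of one fish.

    ``events`` needs columns ``time_s, actor_id, behavior_code``; rows are
    expected time-sorted.  Neutral behaviors are ignored.  Unknown behavior
    codes raise, listing the offending codes.
    """
    etho = DEFAULT_ETHOGRAM if ethogram is None else ethogram
    bad_val = {c: v for c, v in etho.items() if v not in _VALENCES}
    if bad_val:
        raise ValueError(f"ethogram has invalid valences: {bad_val}")
    if len(events) == 0:
        return 0, 0
    if not events["time_s"].is_monotonic_increasing:
        raise ValueError("events must be time-sorted")
    mine = events[events["actor_id"] == fish_id]
    unknown = sorted(set(mine["behavior_code"]) - set(etho))
    if unknown:
        raise KeyError(f"behavior codes missing from the ethogram: {unknown}")
    val = mine["behavior_code"].map(etho)
    return int((val == "aggressive").sum()), int((val == "submissive").sum())


def fighting_ability(aggressive_count: int, submissive_count: int) -> int:
    """Fighting-ability index: aggressive minus submissive behavior count."""
    if aggressive_count < 0 or submissive_count < 0:
        raise ValueError("behavior counts must be non-negative")
    return int(aggressive_count) - int(submissive_count)


def _require_dyad_columns(dyads: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in dyads.columns]
    if missing:
        raise KeyError(f"dyad table missing columns: {missing}")


def _pair_frame(dyads: pd.DataFrame) -> pd.DataFrame:
    """Validate the one-row-per-fish dyad table and annotate winners."""
    _require_dyad_columns(
        dyads, ["pair_id", "fish_id", "sex", "standard_length_cm", "mass_g", "winner_id"]
    )
    sizes = dyads.groupby("pair_id").size()
    if not (sizes == 2).all():
        raise ValueError(f"each pair needs exactly 2 fish; got {sizes.to_dict()}")
    df = dyads.copy()
    df["is_winner"] = df["fish_id"] == df["winner_id"]
    winner_ok = df.groupby("pair_id")["is_winner"].sum()
    if not (winner_ok == 1).all():
        raise ValueError("winner_id must name exactly one fish of each pair")
    sexes = df.groupby("pair_id")["sex"].nunique()
    if not (sexes == 1).all():
        raise ValueError("pairs must be same-sex by design")
    return df


def matching_test(dyads: pd.DataFrame) -> pd.DataFrame:
    """Paired signed-rank tests of within-pair size differences.

    For standard length and body mass, the within-pair absolute difference
    (winner minus loser ordering is irrelevant for the two-sided test on
    signed differences taken in a fixed pair order) is tested against zero.
    Exact null distribution for n <= 25 pairs (no ties), normal
    approximation with continuity correction otherwise.  Reports statistic
    V, p, and mean +/- sd of the differences.
    """
    df = _pair_frame(dyads)
    n_pairs = df["pair_id"].nunique()
    if n_pairs < 6:
        raise ValueError("need at least 6 pairs")
    rows = []
    for var in ("standard_length_cm", "mass_g"):
        diffs = (
            df.sort_values(["pair_id", "fish_id"])
            .groupby("pair_id")[var]
            .agg(lambda s: s.iloc[0] - s.iloc[1])
            .to_numpy()
        )
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            stat, p = 0.0, 1.0
        else:
            mode = "exact" if (nonzero.size <= 25 and _no_tied_ranks(nonzero)) else "approx"
            res = st.wilcoxon(
                nonzero,
                alternative="two-sided",
                correction=(mode == "approx"),
                method=mode,
            )
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": var,
                "n_pairs": n_pairs,
                "V": stat,
                "p": p,
                "mean_diff": float(diffs.mean()),
                "sd_diff": float(diffs.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def _no_tied_ranks(x: np.ndarray) -> bool:
    a = np.abs(x)
    return np.unique(a).size == a.size


def outcome_lmm(dyads: pd.DataFrame, response: str = "fighting_ability") -> MixedModelFit:
    """LMM of mass or fighting ability on combat success, sex, interaction.

    Pair is the random-intercept grouping factor, so success (within-pair)
    is tested against within-pair residual df and sex (between-pair)
    against between-pair df.
    """
    df = _pair_frame(dyads)
    if df["pair_id"].nunique() < 6:
        raise ValueError("need at least 6 pairs")
    if response == "fighting_ability":
        _require_dyad_columns(df, ["aggressive_count", "submissive_count"])
        df["fighting_ability"] = [
            fighting_ability(a, s)
            for a, s in zip(df["aggressive_count"], df["submissive_count"])
        ]
        resp = "fighting_ability"
    elif response == "mass":
        resp = "mass_g"
    else:
        raise ValueError("response must be 'fighting_ability' or 'mass'")

    success = df["is_winner"].astype(float).to_numpy()
    sexes = sorted(df["sex"].unique())
    if len(sexes) == 1:
        warnings.warn("single sex present; dropping sex and interaction", stacklevel=2)
        X = pd.DataFrame({"Intercept": 1.0, "success": success})
        terms = {"success": ["success"]}
    else:
        sex_m = (df["sex"] == sexes[-1]).astype(float).to_numpy()
        X = pd.DataFrame(
            {
                "Intercept": 1.0,
                "success": success,
                "sex": sex_m,
                "success:sex": success * sex_m,
            }
        )
        terms = {"success": ["success"], "sex": ["sex"], "success:sex": ["success:sex"]}
    return fit_random_intercept_lmm(
        df.reset_index(drop=True),
        response=resp,
        design=X,
        terms=terms,
        group="pair_id",
        formula=f"{resp} ~ success * sex + (1 | pair)",
    )


@dataclass
class StripeOutcomeResult:
    """Association between stripe state and combat success."""

    timepoint: str
    chi2: float
    p: float
    odds_ratio: float
    separation: bool
    fit: GlmmFit


def stripe_outcome_glmm(dyads: pd.DataFrame, timepoint: str = "end") -> StripeOutcomeResult:
    """Binomial GLMM of winning on stripe state at a contest timepoint.

    Models P(win) with a pale-stripe indicator as predictor and pair as the
    random-intercept grouping factor; reports the single-df
    likelihood-ratio chi-square and the pale-vs-dark odds ratio.  Complete
    separation (e.g. every loser pale, every winner dark) is flagged and the
    comparison falls back to bias-reduced logistic fits.
    """
    if timepoint not in ("begin", "end"):
        raise ValueError("timepoint must be 'begin' or 'end'")
    col = f"stripe_{timepoint}"
    df = _pair_frame(dyads)
    _require_dyad_columns(df, [col])
    bad = set(df[col]) - {"pale", "dark"}
    if bad:
        raise ValueError(f"stripe states must be 'pale' or 'dark'; got {bad}")
    y = df["is_winner"].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcomes must be present")
    pale = (df[col] == "pale").astype(float).to_numpy()
    Xf = pd.DataFrame({"Intercept": 1.0, "stripe_pale": pale})
    X0 = pd.DataFrame({"Intercept": np.ones(len(df))})
    groups = df["pair_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        full = fit_binomial_glmm(y, Xf, groups)
        if full.separation:
            # refit reduced model with the same (fallback) method
            from .glmm import firth_logistic

            beta0, ll0 = firth_logistic(y.astype(float), X0.to_numpy())
            reduced = GlmmFit(
                params=pd.Series(beta0, index=["Intercept"]),
                random_intercept_sd=0.0,
                loglike=ll0,
                n_obs=len(y),
                n_groups=full.n_groups,
                separation=False,
                method="firth",
            )
        else:
            reduced = fit_binomial_glmm(y, X0, groups)
    chi2, p = glmm_lrt(full, reduced, df=1)
    return StripeOutcomeResult(
        timepoint=timepoint,
        chi2=chi2,
        p=p,
        odds_ratio=float(np.exp(full.params["stripe_pale"])),
        separation=full.separation,
        fit=full,
    )
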