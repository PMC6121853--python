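"""Color-pattern conspicuousness analysis.

Computes receptor-noise-limited chromatic (Delta S) and achromatic
(Delta L) contrasts between all pairs of facial color patches under the
ambient light of the habitat, separates adjacent from nonadjacent patch
pairs, and tests the two structural questions the signaling framework
poses:

* is the pattern *designed* for conspicuousness (adjacent pairs contrast
  more than nonadjacent pairs)?  -> random-intercept LMM per individual;
* which patch pairs *change* when the horizontal stripe pales with loss of
  dominance?  -> per-pair-type rank tests with false-discovery-rate control.

A sequential sum-of-squares partition of the fixed design expresses how
much contrast variance adjacency versus stripe state explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .lmm import MixedModelFit, fit_random_intercept_lmm, sequential_ss
from .spectra import LightEnvironment, Spectrum, ambient_irradiance
from .visual import VisualSystem, achromatic_contrast, adapt, chromatic_contrast

__all__ = [
    "PATCH_LABELS",
    "PATCH_STATES",
    "ColorPatch",
    "AdjacencyMap",
    "DEFAULT_ADJACENCY",
    "pairwise_contrasts",
    "aggregate_per_fish",
    "adjacency_lmm",
    "variance_partition",
    "per_patch_change_tests",
]

#: Canonical facial patch labels in fixed order (defines pair orientation).
PATCH_LABELS = (
    "black_horizontal_stripe",
    "black_vertical_stripe",
    "white",
    "blue",
    "yellow",
)

PATCH_STATES = ("dominant", "subordinate", "manipulated_dark", "manipulated_pale", "control")


@dataclass(frozen=True)
class ColorPatch:
    """One measured color patch of one fish in one state."""

    patch_label: str
    fish_id: str
    state: str
    reflectance: Spectrum

    def __post_init__(self) -> None:
        if self.state not in PATCH_STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {PATCH_STATES}")


class AdjacencyMap:
    """Symmetric, irreflexive adjacency relation over patch labels."""

    def __init__(self, adjacent_pairs: set[tuple[str, str]] | list[tuple[str, str]]):
        pairs = set()
        for a, b in adjacent_pairs:
            if a == b:
                raise ValueError(f"adjacency must be irreflexive; got ({a}, {b})")
            pairs.add(frozenset((a, b)))
        self._pairs = frozenset(pairs)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._pairs

    def labels(self) -> set[str]:
        out: set[str] = set()
        for p in self._pairs:
            out |= set(p)
        return out

    def __len__(self) -> int:
        return len(self._pairs)


#: Default 5-patch facial adjacency.  White bands border both black stripes
#: and the blue markings; the yellow eye-region patch borders both stripes
#: and blue (complementary colors side by side, the classic conspicuousness
#: design).  The two black stripes do not touch each other, and white and
#: yellow lie on opposite sides of the horizontal stripe, so those two
#: pairs are nonadjacent.  Config-overridable.
DEFAULT_ADJACENCY = AdjacencyMap(
    [
        ("black_horizontal_stripe", "white"),
        ("black_horizontal_stripe", "blue"),
        ("black_horizontal_stripe", "yellow"),
        ("black_vertical_stripe", "white"),
        ("black_vertical_stripe", "blue"),
        ("black_vertical_stripe", "yellow"),
        ("white", "blue"),
        ("blue", "yellow"),
    ]
)


def _ordered_pair(a: str, b: str, order: tuple[str, ...] = PATCH_LABELS) -> tuple[str, str]:
    key = {lab: i for i, lab in enumerate(order)}
    ia = key.get(a, len(order))
    ib = key.get(b, len(order))
    return (a, b) if (ia, ib) <= (ib, ia) and ia <= ib else (b, a)


def pairwise_contrasts(
    patches: list[ColorPatch],
    adjacency: AdjacencyMap,
    system: VisualSystem,
    env: LightEnvironment,
) -> pd.DataFrame:
    """Delta S / Delta L for every unordered patch pair per fish and state.

    Returns a frame with columns ``fish_id, state, patch_a, patch_b,
    adjacent, delta_S, delta_L`` where (patch_a, patch_b) follows the fixed
    label order and each pair appears once.
    """
    illum = ambient_irradiance(env)
    groups: dict[tuple[str, str], dict[str, ColorPatch]] = {}
    for p in patches:
        groups.setdefault((p.fish_id, p.state), {})
        if p.patch_label in groups[(p.fish_id, p.state)]:
            raise ValueError(
                f"duplicate patch {p.patch_label!r} for fish {p.fish_id!r} state {p.state!r}"
            )
        groups[(p.fish_id, p.state)][p.patch_label] = p

    rows = []
    for (fish, state), byname in groups.items():
        if len(byname) < 2:
            raise ValueError(f"fish {fish!r} state {state!r} has fewer than 2 patches")
        for lab in byname:
            if lab not in adjacency.labels():
                raise KeyError(f"patch {lab!r} missing from the adjacency map")
        catches = {
            lab: adapt(p.reflectance.clamped(), illum, system) for lab, p in byname.items()
        }
        for la, lb in combinations(sorted(byname, key=_label_rank), 2):
            a, b = _ordered_pair(la, lb)
            rows.append(
                {
                    "fish_id": fish,
                    "state": state,
                    "patch_a": a,
                    "patch_b": b,
                    "adjacent": adjacency.adjacent(a, b),
                    "delta_S": chromatic_contrast(catches[a], catches[b], system),
                    "delta_L": achromatic_contrast(catches[a], catches[b], system),
                }
            )
    return pd.DataFrame(rows)


def _label_rank(lab: str) -> tuple[int, str]:
    try:
        return (PATCH_LABELS.index(lab), lab)
    except ValueError:
        return (len(PATCH_LABELS), lab)


def aggregate_per_fish(records: pd.DataFrame) -> pd.DataFrame:
    """Average contrasts per (fish, state, adjacency category).

    Because each fish contributes several patch pairs to both categories,
    all adjacent and all nonadjacent contrasts are collapsed to one mean per
    individual and state before modeling.  Fish/state cells lacking one of
    the two categories are excluded with a warning.
    """
    if records.empty:
        raise ValueError("no contrast records to aggregate")
    agg = (
        records.groupby(["fish_id", "state", "adjacent"], as_index=False)
        .agg(mean_delta_S=("delta_S", "mean"), mean_delta_L=("delta_L", "mean"))
    )
    counts = agg.groupby(["fish_id", "state"])["adjacent"].nunique()
    incomplete = counts[counts < 2]
    if not incomplete.empty:
        warnings.warn(
            f"excluding fish/state cells missing an adjacency category: "
            f"{list(incomplete.index)}",
            stacklevel=2,
        )
        keep = counts[counts == 2].index
        agg = agg.set_index(["fish_id", "state"]).loc[keep].reset_index()
    return agg.sort_values(["fish_id", "state", "adjacent"]).reset_index(drop=True)


def adjacency_lmm(
    aggregated: pd.DataFrame,
    contrast_kind: str = "chromatic",
    design: str = "dominant_only",
) -> MixedModelFit:
    """LMM of per-fish mean contrast on adjacency (and stripe state).

    ``design="dominant_only"`` models contrast ~ adjacency with a random
    intercept per fish (signal-design question).  With
    ``design="dominant_and_subordinate"`` the model adds stripe state
    (dominant = dark, subordinate = pale) and its interaction with
    adjacency.  Achromatic contrasts are square-root transformed before
    fitting; residual normality is summarized by a Shapiro-Wilk test on the
    fitted model.
    """
    if contrast_kind not in ("chromatic", "achromatic"):
        raise ValueError("contrast_kind must be 'chromatic' or 'achromatic'")
    resp = "mean_delta_S" if contrast_kind == "chromatic" else "mean_delta_L"
    transform = None if contrast_kind == "chromatic" else "sqrt"

    if design == "dominant_only":
        df = aggregated[aggregated["state"] == "dominant"].copy()
        if df["fish_id"].nunique() < 4:
            raise ValueError("need at least 4 fish")
        X = pd.DataFrame(
            {"Intercept": 1.0, "adjacency": df["adjacent"].astype(float).to_numpy()}
        )
        terms = {"adjacency": ["adjacency"]}
        formula = f"{resp} ~ adjacency + (1 | fish)"
    elif design == "dominant_and_subordinate":
        df = aggregated[aggregated["state"].isin(["dominant", "subordinate"])].copy()
        if df["fish_id"].nunique() < 4:
            raise ValueError("need at least 4 fish")
        adj = df["adjacent"].astype(float).to_numpy()
        pale = (df["state"] == "subordinate").astype(float).to_numpy()
        X = pd.DataFrame(
            {
                "Intercept": 1.0,
                "adjacency": adj,
                "stripe_pale": pale,
                "adjacency:stripe_pale": adj * pale,
            }
        )
        terms = {
            "adjacency": ["adjacency"],
            "stripe": ["stripe_pale"],
            "adjacency:stripe": ["adjacency:stripe_pale"],
        }
        formula = f"{resp} ~ adjacency * stripe + (1 | fish)"
    else:
        raise ValueError(f"unknown design {design!r}")

    return fit_random_intercept_lmm(
        df.reset_index(drop=True),
        response=resp,
        design=X,
        terms=terms,
        group="fish_id",
        transform=transform,
        formula=formula,
    )


def variance_partition(fit: MixedModelFit) -> pd.DataFrame:
    """Percent of response variance explained by each fixed term.

    Sequential (type-I) sums of squares of the fixed design on the
    (transformed) response, in the model's term order; ``pct_of_total``
    sums to the total explained by the fixed effects.
    """
    out = sequential_ss(fit.response, fit.design, fit.terms)
    return out


def per_patch_change_tests(
    records: pd.DataFrame,
    state_a: str = "dominant",
    state_b: str = "subordinate",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Which patch pairs change contrast between two stripe states?

    For every patch-pair type, a two-sided Mann-Whitney test compares the
    contrast distribution between states, separately for Delta S and
    Delta L.  Benjamini-Hochberg adjustment is applied across pair types
    *within* each contrast kind; ``significant`` flags adjusted p < alpha.
    """
    for s in (state_a, state_b):
        if s not in set(records["state"]):
            raise ValueError(f"state {s!r} absent from records")
    rows = []
    for kind, col in (("chromatic", "delta_S"), ("achromatic", "delta_L")):
        for (pa, pb), grp in records.groupby(["patch_a", "patch_b"]):
            xa = grp.loc[grp["state"] == state_a, col].to_numpy()
            xb = grp.loc[grp["state"] == state_b, col].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"skipping pair ({pa}, {pb}) {kind}: group size < 2", stacklevel=2
                )
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                u, p = len(xa) * len(xb) / 2.0, 1.0
            else:
                u, p = st.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                {
                    "contrast_kind": kind,
                    "patch_a": pa,
                    "patch_b": pb,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "U": float(u),
                    "p_raw": float(p),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    adj = np.empty(len(table))
    for kind in table["contrast_kind"].unique():
        mask = (table["contrast_kind"] == kind).to_numpy()
        adj[mask] = multipletests(table.loc[mask, "p_raw"], method="fdr_bh")[1]
    table["p_adj"] = adj
    table["significant"] = table["p_adj"] < alpha
    return table
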