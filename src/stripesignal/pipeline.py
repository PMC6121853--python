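"""Stage orchestration: run the three analyses end to end and write reports.

Each stage reads its inputs (synthetic by default, or CSV files when paths
are provided), runs the corresponding analysis, and writes plain CSV
tables plus a JSON run manifest (inputs, config hash, seed, package
version) so a run can be audited and reproduced.  Reruns with the same
seed and config produce byte-identical numeric tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conspicuousness import (
    DEFAULT_ADJACENCY,
    AdjacencyMap,
    ColorPatch,
    adjacency_lmm,
    aggregate_per_fish,
    pairwise_contrasts,
    per_patch_change_tests,
    variance_partition,
)
from .contest import matching_test, outcome_lmm, stripe_outcome_glmm
from .punishment import fold_effects, mis_lmm, tukey_posthoc
from .spectra import read_spectra_long
from .synth import (
    SyntheticConfig,
    gen_contests,
    gen_light_environment,
    gen_mis_trials,
    gen_spectra_dataset,
    gen_visual_system,
)

__all__ = ["RunConfig", "run_stage1", "run_stage2", "run_stage3", "run_all"]


@dataclass
class RunConfig:
    """Inputs and options for a pipeline run."""

    out_dir: str
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    # optional real-data inputs; when None the synthetic generator is used
    spectra_csv: str | None = None
    dyad_csv: str | None = None
    trial_csv: str | None = None
    adjacency: AdjacencyMap = field(default_factory=lambda: DEFAULT_ADJACENCY)

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        for p in (self.spectra_csv, self.dyad_csv, self.trial_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write(df: pd.DataFrame, out: Path, name: str, written: dict) -> None:
    path = out / name
    df.to_csv(path, index=False, float_format="%.10g")
    written[name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_summary(fits: dict) -> pd.DataFrame:
    rows = []
    for label, fit in fits.items():
        for _, r in fit.anova.iterrows():
            rows.append(
                {
                    "model": label,
                    "term": r["term"],
                    "F": r["F"],
                    "df_num": r["df_num"],
                    "df_den": r["df_den"],
                    "p": r["p"],
                    "shapiro_p": fit.shapiro_p,
                }
            )
    return pd.DataFrame(rows)


def _manifest(out: Path, config: RunConfig, stage: str, written: dict) -> None:
    cfg = asdict(config.synthetic)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "package_version": __version__,
        "synthetic_config_sha256": hashlib.sha256(blob).hexdigest(),
        "inputs": {
            "spectra_csv": config.spectra_csv,
            "dyad_csv": config.dyad_csv,
            "trial_csv": config.trial_csv,
        },
        "outputs": written,
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_patches(config: RunConfig) -> list[ColorPatch]:
    if config.spectra_csv is None:
        return gen_spectra_dataset(config.synthetic)
    spectra = read_spectra_long(config.spectra_csv)
    patches = []
    for sid, s in spectra.items():
        try:
            fish_id, state, label = sid.split("|")
        except ValueError as err:
            raise ValueError(
                f"spectrum_id {sid!r} must be 'fish|state|patch_label'"
            ) from err
        patches.append(ColorPatch(label, fish_id, state, s))
    return patches


def run_stage1(config: RunConfig) -> dict:
    """Signal design: patch contrasts and the adjacency model (dominant fish)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    system = gen_visual_system(config.synthetic)
    env = gen_light_environment(config.synthetic)
    patches = _load_patches(config)
    records = pairwise_contrasts(patches, config.adjacency, system, env)
    agg = aggregate_per_fish(records)
    fits = {
        "chromatic_adjacency": adjacency_lmm(agg, "chromatic", "dominant_only"),
        "achromatic_adjacency": adjacency_lmm(agg, "achromatic", "dominant_only"),
    }
    _write(records, out, "stage1_contrasts.csv", written)
    _write(agg, out, "stage1_aggregated.csv", written)
    _write(_fit_summary(fits), out, "stage1_models.csv", written)
    _manifest(out, config, "stage1", written)
    return {"records": records, "aggregated": agg, "fits": fits}


def run_stage2(config: RunConfig, stage1: dict | None = None) -> dict:
    """Signal message: contest outcomes, stripe state, and contrast changes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    if config.dyad_csv is not None:
        dyads = pd.read_csv(config.dyad_csv)
    else:
        dyads, _events = gen_contests(config.synthetic)

    match = matching_test(dyads)
    fits = {
        "mass_outcome": outcome_lmm(dyads, "mass"),
        "ability_outcome": outcome_lmm(dyads, "fighting_ability"),
    }
    stripe_end = stripe_outcome_glmm(dyads, "end")
    stripe_begin = stripe_outcome_glmm(dyads, "begin")
    stripe_tbl = pd.DataFrame(
        [
            {
                "timepoint": r.timepoint,
                "chi2": r.chi2,
                "p": r.p,
                "odds_ratio_pale": r.odds_ratio,
                "separation": r.separation,
            }
            for r in (stripe_begin, stripe_end)
        ]
    )

    # contrast changes with dominance, reusing stage-1 spectral records
    if stage1 is None:
        stage1 = run_stage1(config)
    records = stage1["records"]
    change = per_patch_change_tests(records)
    agg = stage1["aggregated"]
    dom_sub_fits = {
        "chromatic_adjacency_x_stripe": adjacency_lmm(agg, "chromatic", "dominant_and_subordinate"),
        "achromatic_adjacency_x_stripe": adjacency_lmm(agg, "achromatic", "dominant_and_subordinate"),
    }
    parts = {
        label: variance_partition(fit).assign(model=label)
        for label, fit in dom_sub_fits.items()
    }
    partition = pd.concat(parts.values(), ignore_index=True)

    _write(match, out, "stage2_matching.csv", written)
    _write(_fit_summary({**fits, **dom_sub_fits}), out, "stage2_models.csv", written)
    _write(stripe_tbl, out, "stage2_stripe_outcome.csv", written)
    _write(change, out, "stage2_contrast_change.csv", written)
    _write(partition, out, "stage2_variance_partition.csv", written)
    _manifest(out, config, "stage2", written)
    return {
        "dyads": dyads,
        "matching": match,
        "fits": {**fits, **dom_sub_fits},
        "stripe": {"begin": stripe_begin, "end": stripe_end},
        "contrast_change": change,
        "variance_partition": partition,
    }


def run_stage3(config: RunConfig) -> dict:
    """Reliability source: aggression toward out-of-equilibrium signals."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    if config.trial_csv is not None:
        trials = pd.read_csv(config.trial_csv)
    else:
        trials = gen_mis_trials(config.synthetic)
    fits = {
        "bouts": mis_lmm(trials, "bouts"),
        "latency": mis_lmm(trials, "latency"),
    }
    posthoc = pd.concat(
        [tukey_posthoc(fit).assign(model=label) for label, fit in fits.items()],
        ignore_index=True,
    )
    folds = fold_effects(trials, seed=config.seed)
    _write(trials, out, "stage3_trials.csv", written)
    _write(_fit_summary(fits), out, "stage3_models.csv", written)
    _write(posthoc, out, "stage3_posthoc.csv", written)
    _write(folds, out, "stage3_fold_effects.csv", written)
    _manifest(out, config, "stage3", written)
    return {"trials": trials, "fits": fits, "posthoc": posthoc, "fold_effects": folds}


def run_all(config: RunConfig) -> dict:
    """Run stages 1-3 and return their combined results."""
    s1 = run_stage1(config)
    s2 = run_stage2(config, stage1=s1)
    s3 = run_stage3(config)
    return {"stage1": s1, "stage2": s2, "stage3": s3}
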