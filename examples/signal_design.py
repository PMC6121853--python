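"""Stage 1: is the facial pattern built for conspicuousness?

Generates facial-patch reflectance spectra for 10 dominant fish, computes
all pairwise patch contrasts under depth-attenuated ambient light, and
tests whether adjacent patch pairs contrast more than nonadjacent ones
(random-intercept LMM per fish).  A large adjacency F with a high
explained-variance share is the signature of a pattern designed for
conspicuousness.
"""

from stripesignal import (
    DEFAULT_ADJACENCY,
    SyntheticConfig,
    adjacency_lmm,
    aggregate_per_fish,
    pairwise_contrasts,
    variance_partition,
)
from stripesignal.synth import gen_light_environment, gen_spectra_dataset, gen_visual_system

cfg = SyntheticConfig(seed=1)
patches = gen_spectra_dataset(cfg)  # 10 dominant + 10 subordinate fish
system = gen_visual_system(cfg)
env = gen_light_environment(cfg)

records = pairwise_contrasts(patches, DEFAULT_ADJACENCY, system, env)
agg = aggregate_per_fish(records)

dom = records[records["state"] == "dominant"]
print(f"mean adjacent    Delta S: {dom.loc[dom.adjacent, 'delta_S'].mean():5.2f} JND")
print(f"mean nonadjacent Delta S: {dom.loc[~dom.adjacent, 'delta_S'].mean():5.2f} JND")

fit = adjacency_lmm(agg, "chromatic", "dominant_only")
f, p = fit.term_f("adjacency")
row = fit.anova.iloc[0]
print(f"adjacency LMM: F({row.df_num:.0f},{row.df_den:.0f}) = {f:.2f}, p = {p:.2g}")

fit2 = adjacency_lmm(agg, "chromatic", "dominant_and_subordinate")
part = variance_partition(fit2)
print("chromatic variance shares (sequential SS):")
for _, r in part.iterrows():
    print(f"  {r['term']:<18} {r['pct_of_total']:6.2f} %")
print("-> adjacency, not stripe state, carries the chromatic structure")
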