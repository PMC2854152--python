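"""Tissue-corrected distributional bias test of the core sets.

Each gene's expression is ranked across 23 tissues; a core set's ranks in
one tissue are compared with the rest of the genome by KS statistics.
Because core sets derive from inflorescence material, the raw comparison
is biased toward inflorescence-like tissues; the corrected test re-draws
1,000 random gene sets with the same inflorescence ranks and reports the
empirical p of the observed statistic among them, per direction.
"""

from mircompass.synthetic_data import SimConfig, simulate_all
from mircompass.tissue_bias import (
    BiasConfig,
    rank_across_tissues,
    raw_bias_test,
    significance_matrix,
    tissue_corrected_bias_test,
)

bundle = simulate_all(SimConfig(seed=7))
truth = bundle.truth
atlas = bundle.atlas
cfg = BiasConfig(n_perm=1000)

# the raw (uncorrected) view of the inflorescence itself
ranks = rank_across_tissues(atlas)
ref = [g for g in atlas.index if g not in truth.planted_up]
d, p, sign = raw_bias_test(ranks.loc[sorted(truth.planted_up), "FL1"],
                           ranks.loc[ref, "FL1"])
print(f"raw inflorescence comparison: D={d:.3f}, p={p:.2e}, direction={sign}")
# significant by construction — core genes come from inflorescence arrays

res = tissue_corrected_bias_test(sorted(truth.planted_up), atlas, cfg,
                                 seed=0, set_name="up")
sig = res[res["p_corrected"] < 0.01]
print("\ncorrected test, tissues flagged at p < 0.01 (up-regulated set):")
print(sig[["tissue", "direction", "D", "p_corrected"]].to_string(index=False))
# only the planted tissue biases survive the correction: the generator
# plants the up set high in the meristem tissue and low in mature pollen

mats = significance_matrix(res)
print("\ntier matrix (first rows):")
print(mats["tiers"].head(8).to_string())
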