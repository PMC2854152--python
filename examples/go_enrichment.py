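"""GO-SLIM molecular-function enrichment of the core sets.

Works on the published annotation-count table distributed with the
package: 15 molecular-function categories, annotation counts for the
up-/down-regulated core sets and their complements on the ATH1 array.
The omnibus question — do category proportions differ between a core set
and the rest of the genome? — is answered with a Monte Carlo estimate of
the exact 15x2 Fisher test (a million Patefield tables with the observed
margins).
"""

from mircompass.enrichment import (
    ContingencyTable,
    chisq_residuals,
    fisher_rxc_montecarlo,
    load_reference_counts,
    proportion_table,
)

ref = load_reference_counts()
up = ContingencyTable(tuple(ref.index), ref[["up", "non_up"]].to_numpy(),
                      column_labels=("up", "non_up"))

print("category proportions (%, up-regulated core set vs rest):")
print(proportion_table(up).to_string())
# transcription factors at 12.12% vs 5.84% background: the core set is
# enriched for the class plant miRNAs preferentially target

p_up, se_up = fisher_rxc_montecarlo(up, n_sim=1_000_000, seed=0)
print(f"\nup-regulated omnibus exact p (MC): {p_up:.2e} ± {se_up:.0e}")

down = ContingencyTable(tuple(ref.index), ref[["down", "non_down"]].to_numpy(),
                        column_labels=("down", "non_down"))
p_down, se_down = fisher_rxc_montecarlo(down, n_sim=1_000_000, seed=1)
print(f"down-regulated omnibus exact p (MC): {p_down:.3f} ± {se_down:.0e}")
# the up set deviates strongly from genomic proportions (p ~ 2e-4); the
# down set does not (p ~ 0.16)

print("\nPearson residuals (which categories drive the signal):")
resid = chisq_residuals(up)["up"].sort_values()
print(resid.to_string(float_format="%.2f"))
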