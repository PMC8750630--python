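"""Nonamer enumeration and combined affinity/stability binder selection.

Enumerates every overlapping 9-mer of a small synthetic protein set, scores
each against HLA-A*02:01 with the deterministic toy predictor, keeps strong
binders under 100 nM, intersects with stability calls, and prints the
per-protein summary and affinity tier counts.
"""

from taascan import epitope as ep, hpa_io, synthetic_data as sd

config = sd.SimulationConfig(seed=21, n_tumor_proteins=9, tumor_protein_length=120)
proteins, _, _ = sd.gen_proteomes(config)
predictor = ep.toy_predictor(seed=21)

predictions = ep.predict_epitopes(proteins, predictor, alleles=("HLA-A*02:01",))
print(f"enumerated {len(predictions)} peptide x allele predictions "
      f"({len(proteins)} proteins, L-8 windows each)")

strong = ep.select_strong_binders(predictions, max_affinity=100.0)
print(f"affinity-selected strong binders (<100 nM): {len(strong)}")
print("affinity tiers:", ep.tier_counts(strong))

stability_rows = [
    hpa_io.PredictorOutputRow(p.peptide, p.allele,
                              thalf_h=predictor.stability(p.peptide, p.allele)[0],
                              binder_class=predictor.stability(p.peptide, p.allele)[1])
    for p in strong
]
combined, n_missing = ep.combine_stability(strong, stability_rows)
print(f"after stability intersection: {len(combined)} (missing rows: {n_missing})")
print("per-protein summary:", ep.per_protein_summary(combined))
# The per-protein mean tells you how many vaccine-candidate epitopes each
# antigen contributes; proteins with zero survivors drop out of the summary.
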