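"""Exhaustive viral molecular-mimicry scan with a planted homolog.

Plants a 7/9-identity homolog of the MDK-derived epitope ALLALTSAV inside a
50-protein synthetic viral proteome, scans every 9-residue window, filters
matches on predicted binding to HLA-A*02:01, and prints the ranked pair
table.
"""

from taascan import epitope as ep, mimicry, synthetic_data as sd

config = sd.SimulationConfig(seed=33, n_viral_proteins=50, viral_protein_length=300)
specs = [sd.HomologSpec(epitope="ALLALTSAV", identity=7, accession="VIRAL012", position=101)]
_, viral_proteome, truth = sd.gen_proteomes(config, homolog_specs=specs)
print("planted:", truth.planted_homologs[0])

epitopes = [ep.EpitopePrediction(protein_id="MDK", start=1, peptide="ALLALTSAV")]
matches = mimicry.scan_viral_proteome(epitopes, viral_proteome, min_identity=7)
print(f"windows with >= 7/9 identity: {len(matches)} "
      f"(scanned {sum(len(p) - 8 for p in viral_proteome)} windows)")

pairs = mimicry.filter_viral_binders(
    matches, ep.toy_predictor(seed=33), allele="HLA-A*02:01", min_thalf_h=3.0
)
print(mimicry.pair_report(pairs).to_string(index=False))
# Each row pairs a tumor epitope with a viral 9-mer a memory T cell raised
# against the virus could cross-recognize; identity counts and the predicted
# affinity/stability of the viral peptide justify the pairing.
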