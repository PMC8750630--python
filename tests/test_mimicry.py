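import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taascan import mimicry, synthetic_data as sd
from taascan.epitope import EpitopePrediction
from taascan.hpa_io import ProteinSequence

AA = "ACDEFGHIKLMNPQRSTVWY"
ninemers = st.text(alphabet=AA, min_size=9, max_size=9)


def make_epitope(peptide, protein="TAA"):
    return EpitopePrediction(protein_id=protein, start=1, peptide=peptide)


def naive_double_loop_scan(epitopes, proteome, min_identity):
    """Independent brute-force reference: all windows, position-wise count."""
    found = set()
    for record in proteome:
        seq = record.sequence
        for i in range(len(seq) - 8):
            window = seq[i : i + 9]
            for peptide, protein in epitopes:
                ident = sum(
                    1 for x, y in zip(peptide, window) if x == y and x != "X"
                )
                if ident >= min_identity:
                    found.add((protein, peptide, record.protein_id, i + 1, window, ident))
    return found


def as_tuples(matches):
    return {
        (m.tumor_protein_id, m.tumor_peptide, m.viral_accession,
         m.viral_position, m.viral_peptide, m.identity)
        for m in matches
    }


class TestIdentityScore:
    @pytest.mark.parametrize(
        "a,b,identity,mismatches",
        [
            ("ALLALTSAV", "ALMAFTSAV", 7, [3, 5]),
            ("LLLTLLALL", "LLLTLLLLL", 8, [7]),
            ("LLGPQLVLL", "LLGPLLVLL", 8, [5]),
            ("MLAGNEFQV", "MLAGNAFTA", 6, [6, 8, 9]),  # position-wise count
        ],
    )
    def test_validated_peptide_pairs(self, a, b, identity, mismatches):
        assert mimicry.identity_score(a, b) == (identity, mismatches)

    def test_self_identity(self):
        assert mimicry.identity_score("MLAGNEFQV", "MLAGNEFQV") == (9, [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mimicry.identity_score("MLAGNEFQV", "MLAG")

    def test_ambiguous_residue_never_matches(self):
        identity, mismatches = mimicry.identity_score("XLAGNEFQV", "XLAGNEFQV")
        assert identity == 8 and mismatches == [1]

    @given(ninemers, ninemers)
    @settings(max_examples=100, deadline=None)
    def test_symmetric(self, a, b):
        assert mimicry.identity_score(a, b)[0] == mimicry.identity_score(b, a)[0]

    @given(ninemers, ninemers, ninemers)
    @settings(max_examples=100, deadline=None)
    def test_triangle_property(self, a, b, c):
        iac = mimicry.identity_score(a, c)[0]
        iab = mimicry.identity_score(a, b)[0]
        ibc = mimicry.identity_score(b, c)[0]
        assert iac >= iab + ibc - 9


class TestScan:
    def test_verbatim_epitope_found_and_flagged(self):
        epitope = make_epitope("ALLALTSAV")
        proteome = [ProteinSequence("v1", "GGGGG" + "ALLALTSAV" + "KKKKK")]
        matches = mimicry.scan_viral_proteome([epitope], proteome, min_identity=9)
        assert len(matches) == 1
        m = matches[0]
        assert (m.viral_position, m.identity, m.is_self_match) == (6, 9, True)

    def test_planted_homolog_found_and_scan_equals_oracle(self, sim_config):
        specs = [sd.HomologSpec("ALLALTSAV", identity=7, accession="VIRAL001", position=20)]
        _, viral, truth = sd.gen_proteomes(sim_config, specs)
        epitope = make_epitope("ALLALTSAV", protein="MDK")
        matches = mimicry.scan_viral_proteome([epitope], viral, min_identity=7)
        planted = truth.planted_homologs[0]
        assert any(
            m.viral_accession == "VIRAL001" and m.viral_position == 20 and m.identity == 7
            and m.viral_peptide == planted["viral_peptide"]
            for m in matches
        )
        oracle = naive_double_loop_scan([("ALLALTSAV", "MDK")], viral, 7)
        assert as_tuples(matches) == oracle

    def test_strict_floor_on_random_proteome_is_empty(self):
        cfg = sd.SimulationConfig(seed=77, n_viral_proteins=20, viral_protein_length=200)
        _, viral, _ = sd.gen_proteomes(cfg)
        matches = mimicry.scan_viral_proteome([make_epitope("ALLALTSAV")], viral, min_identity=9)
        assert matches == []

    def test_empty_proteome_warns_and_returns_empty(self):
        assert mimicry.scan_viral_proteome([make_epitope("ALLALTSAV")], [], 7) == []

    def test_min_identity_domain(self):
        with pytest.raises(ValueError):
            mimicry.scan_viral_proteome([], [ProteinSequence("v", "A" * 20)], min_identity=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_equivalence_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        proteome = [
            ProteinSequence(f"v{j}", "".join(rng.choice(list(AA), size=int(rng.integers(60, 200)))))
            for j in range(int(rng.integers(2, 5)))
        ]
        epitopes = ["".join(rng.choice(list(AA), size=9)) for _ in range(3)]
        min_identity = int(rng.integers(3, 8))
        matches = mimicry.scan_viral_proteome(
            [make_epitope(p, protein=f"t{k}") for k, p in enumerate(epitopes)],
            proteome, min_identity,
        )
        oracle = naive_double_loop_scan(
            [(p, f"t{k}") for k, p in enumerate(epitopes)], proteome, min_identity
        )
        assert as_tuples(matches) == oracle

    def test_record_order_invariance(self, sim_config):
        _, viral, _ = sd.gen_proteomes(sim_config)
        epitope = make_epitope("ALLALTSAV")
        fwd = mimicry.scan_viral_proteome([epitope], viral, min_identity=5)
        rev = mimicry.scan_viral_proteome([epitope], list(reversed(viral)), min_identity=5)
        assert as_tuples(fwd) == as_tuples(rev)


class FixedPredictor:
    """Stub returning preconfigured (affinity, class) and (thalf, class)."""

    def __init__(self, table):
        self.table = table

    def affinity(self, peptide, allele):
        affinity, _, cls = self.table[peptide]
        return affinity, cls

    def stability(self, peptide, allele):
        _, thalf, cls = self.table[peptide]
        return thalf, cls


class TestViralBinderFilter:
    def make_match(self, viral_peptide):
        return mimicry.MimicryMatch(
            tumor_protein_id="TAA", tumor_peptide="LLGPQLVLL",
            viral_accession="v1", viral_position=1,
            viral_peptide=viral_peptide, identity=8, mismatch_positions=(5,),
        )

    def test_stability_gate_at_three_hours(self):
        # validated WB viral peptide with Thalf 3.38 h passes; 0.65 h does not
        predictor = FixedPredictor({
            "LLGPLLVLL": (20.91, 3.38, "WB"),
            "GSPACTFTF": (658.27, 0.65, "WB"),
        })
        matches = [self.make_match("LLGPLLVLL"), self.make_match("GSPACTFTF")]
        pairs = mimicry.filter_viral_binders(matches, predictor, "HLA-A*02:01")
        assert [p.viral_peptide for p in pairs] == ["LLGPLLVLL"]
        assert pairs[0].viral_thalf_h == 3.38
        assert pairs[0].viral_binder_class == "WB"

    def test_class_filter(self):
        predictor = FixedPredictor({"LLGPLLVLL": (20.91, 8.0, "NB")})
        assert mimicry.filter_viral_binders([self.make_match("LLGPLLVLL")], predictor, "A2") == []

    def test_empty_matches(self):
        assert mimicry.filter_viral_binders([], FixedPredictor({}), "A2") == []


class TestPairReport:
    def make_pair(self, identity, accession="v1", tumor="TAA1"):
        return mimicry.MimicryPair(
            tumor_protein_id=tumor, tumor_peptide="LLGPQLVLL",
            viral_accession=accession, viral_position=1, viral_peptide="LLGPLLVLL",
            identity=identity, mismatch_positions=(5,),
            allele="HLA-A*02:01", viral_affinity_nM=20.91, viral_thalf_h=3.38,
            viral_binder_class="WB",
        )

    def test_sorted_by_descending_identity(self):
        report = mimicry.pair_report([self.make_pair(7), self.make_pair(8)])
        assert list(report["identity"]) == [8, 7]

    def test_duplicate_viral_window_keeps_both_rows(self):
        pairs = [self.make_pair(8, tumor="TAA1"), self.make_pair(8, tumor="TAA2")]
        assert len(mimicry.pair_report(pairs)) == 2

    def test_round_trips_through_tsv(self, tmp_path):
        report = mimicry.pair_report([self.make_pair(8), self.make_pair(7, accession="v0")])
        path = tmp_path / "pairs.tsv"
        report.to_csv(path, sep="\t", index=False)
        import pandas as pd
        back = pd.read_csv(path, sep="\t")
        assert len(back) == 2 and list(back.columns) == list(report.columns)
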