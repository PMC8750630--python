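import pytest
from hypothesis import given, settings, strategies as st

from taascan import epitope as ep
from taascan.hpa_io import PredictorOutputRow, ProteinSequence

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=9, max_size=120)


class TestEnumeration:
    @pytest.mark.parametrize("length,expected", [(9, 1), (20, 12), (100, 92)])
    def test_window_count_is_length_minus_eight(self, length, expected):
        protein = ProteinSequence("p", "A" * length)
        assert len(ep.enumerate_nonamers(protein)) == expected

    def test_short_sequence_yields_empty(self):
        assert ep.enumerate_nonamers(ProteinSequence("p", "MLAGNEFQ")) == []

    def test_windows_reconstruct_the_sequence(self):
        import numpy as np
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AA), size=200))
        windows = ep.enumerate_nonamers(ProteinSequence("p", seq))
        assert windows[0].start == 1 and windows[-1].start == 192
        rebuilt = windows[0].peptide + "".join(w.peptide[-1] for w in windows[1:])
        assert rebuilt == seq
        for a, b in zip(windows, windows[1:]):
            assert a.peptide[1:] == b.peptide[:-1]

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_count_property(self, seq):
        assert len(ep.enumerate_nonamers(ProteinSequence("p", seq))) == len(seq) - 8


class TestAffinityBins:
    @pytest.mark.parametrize(
        "affinity,bin_",
        [(4.35, "lt10"), (37.45, "10to50"), (10.0, "10to50"), (50.0, "50to100"),
         (99.99, "50to100"), (100.0, "gt100"), (658.27, "gt100")],
    )
    def test_tier_assignment(self, affinity, bin_):
        assert ep.classify_affinity_bin(affinity) == bin_

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ep.classify_affinity_bin(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bins_partition_positive_reals(self, affinity):
        assert ep.classify_affinity_bin(affinity) in ep.AFFINITY_BINS


def make_prediction(peptide, affinity, cls, protein="p", allele="HLA-A*02:01"):
    return ep.EpitopePrediction(
        protein_id=protein, start=1, peptide=peptide, allele=allele,
        affinity_nM=affinity, binder_class=cls,
    )


class TestStrongBinderSelection:
    def test_affinity_boundary_is_strict(self):
        just_under = make_prediction("MLAGNEFQV", 99.9, "SB")
        at_limit = make_prediction("ALLALTSAV", 100.0, "SB")
        weak = make_prediction("LLGPQLVLL", 5.0, "WB")
        selected = ep.select_strong_binders([just_under, at_limit, weak])
        assert selected == [just_under]

    def test_matches_brute_force_over_toy_run(self):
        import numpy as np
        rng = np.random.default_rng(1)
        proteins = [
            ProteinSequence(f"p{i}", "".join(rng.choice(list(AA), size=60)))
            for i in range(5)
        ]
        predictor = ep.toy_predictor(seed=2)
        predictions = ep.predict_epitopes(proteins, predictor, alleles=("HLA-A*02:01",))
        selected = ep.select_strong_binders(predictions)
        brute = [p for p in predictions if p.binder_class == "SB" and p.affinity_nM < 100.0]
        assert selected == brute

    def test_selection_idempotent(self):
        preds = [make_prediction("MLAGNEFQV", 4.35, "SB"), make_prediction("ALLALTSAV", 250.0, "SB")]
        once = ep.select_strong_binders(preds)
        assert ep.select_strong_binders(once) == once


class TestCombineStability:
    def test_joint_filter(self):
        preds = [make_prediction("MLAGNEFQV", 4.35, "SB"), make_prediction("ALLALTSAV", 10.06, "SB")]
        stability = [
            PredictorOutputRow("MLAGNEFQV", "HLA-A*02:01", thalf_h=5.22, binder_class="SB"),
            PredictorOutputRow("ALLALTSAV", "HLA-A*02:01", thalf_h=0.3, binder_class="WB"),
        ]
        kept, n_missing = ep.combine_stability(preds, stability)
        assert [k.peptide for k in kept] == ["MLAGNEFQV"]
        assert kept[0].thalf_h == 5.22
        assert n_missing == 0

    def test_missing_stability_row_dropped_and_counted(self):
        preds = [make_prediction("MLAGNEFQV", 4.35, "SB")]
        kept, n_missing = ep.combine_stability(preds, [])
        assert kept == [] and n_missing == 1

    def test_optional_min_thalf(self):
        preds = [make_prediction("MLAGNEFQV", 4.35, "SB")]
        stability = [PredictorOutputRow("MLAGNEFQV", "HLA-A*02:01", thalf_h=2.0, binder_class="SB")]
        assert ep.combine_stability(preds, stability, min_thalf_h=3.0)[0] == []
        assert len(ep.combine_stability(preds, stability, min_thalf_h=1.0)[0]) == 1


class TestPerProteinSummary:
    def test_printed_composition(self):
        # 28 selected epitopes over 9 proteins, counts 1..6
        counts = {"ISG15": 1, "MDK": 1, "C1QTNF12": 1, "KLC1": 2, "SEMA3A": 3,
                  "BMP6": 4, "DYRK4": 4, "CAPN7": 6, "PLTP": 6}
        selected = [
            make_prediction("MLAGNEFQV", 5.0, "SB", protein=prot)
            for prot, n in counts.items() for _ in range(n)
        ]
        summary = ep.per_protein_summary(selected)
        assert summary.n_total == 28
        assert summary.mean == 3.11
        assert summary.minimum == 1 and summary.maximum == 6

    def test_single_protein(self):
        selected = [make_prediction("MLAGNEFQV", 5.0, "SB")] * 5
        assert ep.per_protein_summary(selected).mean == 5.00

    def test_empty_selection_flagged(self):
        summary = ep.per_protein_summary([])
        assert summary.mean is None and "no selected" in str(summary)


class TestToyPredictor:
    def test_deterministic(self):
        p = ep.toy_predictor(seed=3)
        assert p.affinity("MLAGNEFQV", "HLA-A*02:01") == p.affinity("MLAGNEFQV", "HLA-A*02:01")
        assert p.stability("MLAGNEFQV", "HLA-A*02:01") == p.stability("MLAGNEFQV", "HLA-A*02:01")

    def test_anchor_breaking_weakens_affinity(self):
        p = ep.toy_predictor(seed=4)
        optimal = "GLAGNEFQV"  # L at p2, V at p9
        broken_p2 = "GGAGNEFQV"
        broken_p9 = "GLAGNEFQG"
        aff_opt = p.affinity(optimal, "HLA-A*02:01")[0]
        assert aff_opt < p.affinity(broken_p2, "HLA-A*02:01")[0]
        assert aff_opt < p.affinity(broken_p9, "HLA-A*02:01")[0]

    def test_full_pipeline_selects_planted_strong_peptides(self):
        # a protein tiled with anchor-intact 9-mers yields SB calls at every window
        protein = ProteinSequence("plant", "GLFGNDWQVLV" + "GLAGNEFQV")
        predictor = ep.toy_predictor(seed=5)
        predictions = ep.predict_epitopes([protein], predictor, alleles=("HLA-A*02:01",))
        selected = ep.select_strong_binders(predictions)
        peptides = {s.peptide for s in selected}
        assert "GLAGNEFQV" in peptides  # anchors intact -> affinity < 15 nM < 50
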