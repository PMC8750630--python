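"""MHC class I nonamer enumeration and affinity/stability binder selection.

The selection logic mirrors a two-predictor workflow: an affinity predictor
classifies each 9-mer x allele pair as strong/weak/non binder (SB/WB/NB) and
reports a predicted IC50-like affinity in nM; a stability predictor reports
the predicted half-life of the peptide-MHC complex (Thalf, hours) and its own
SB/WB call. Candidate epitopes are strong binders with affinity < 100 nM that
remain SB under the stability predictor.

Real predictor output is consumed through :func:`taascan.hpa_io.
read_predictor_output`; :func:`toy_predictor` provides a deterministic,
anchor-position-aware stand-in so the full selection path is exercisable
offline. The toy predictor is NOT a scientific binding model.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Protocol, Sequence

from .hpa_io import PredictorOutputRow, ProteinSequence

logger = logging.getLogger(__name__)

AFFINITY_BINS = ("lt10", "10to50", "50to100", "gt100")

DEFAULT_ALLELES = ("HLA-A*02:01", "HLA-A*24:02")


class Predictor(Protocol):
    """Deterministic peptide x allele predictor contract."""

    def affinity(self, peptide: str, allele: str) -> tuple[float, str]:
        """Return (affinity_nM, binder_class) for the pair."""
        ...

    def stability(self, peptide: str, allele: str) -> tuple[float, str]:
        """Return (thalf_h, binder_class) for the pair."""
        ...


@dataclass(frozen=True)
class EpitopePrediction:
    protein_id: str
    start: int  # 1-based start in the source protein
    peptide: str
    allele: str | None = None
    affinity_nM: float | None = None
    thalf_h: float | None = None
    binder_class: str | None = None

    @property
    def affinity_bin(self) -> str | None:
        return None if self.affinity_nM is None else classify_affinity_bin(self.affinity_nM)


def enumerate_nonamers(protein: ProteinSequence) -> list[EpitopePrediction]:
    """All overlapping 9-mers with a one-residue lateral shift.

    A protein of length L yields exactly L-8 windows with 1-based starts
    1..L-8, in sequence order. Proteins shorter than nine residues yield an
    empty list with a logged warning.
    """
    seq = protein.sequence
    if len(seq) < 9:
        logger.warning("protein %s shorter than 9 residues; no nonamers", protein.protein_id)
        return []
    return [
        EpitopePrediction(protein_id=protein.protein_id, start=i + 1, peptide=seq[i : i + 9])
        for i in range(len(seq) - 8)
    ]


def classify_affinity_bin(affinity_nM: float) -> str:
    """Affinity tier: <10 nM, [10,50) nM, [50,100) nM, or >=100 nM.

    The half-open boundary convention places 10 and 50 in the upper tier.
    """
    if affinity_nM <= 0:
        raise ValueError("affinity must be positive")
    if affinity_nM < 10:
        return "lt10"
    if affinity_nM < 50:
        return "10to50"
    if affinity_nM < 100:
        return "50to100"
    return "gt100"


def predict_epitopes(
    proteins: Iterable[ProteinSequence],
    predictor: Predictor,
    alleles: Sequence[str] = DEFAULT_ALLELES,
    with_stability: bool = True,
) -> list[EpitopePrediction]:
    """Enumerate nonamers and annotate each (peptide, allele) pair."""
    out: list[EpitopePrediction] = []
    for protein in proteins:
        for skeleton in enumerate_nonamers(protein):
            for allele in alleles:
                aff, cls = predictor.affinity(skeleton.peptide, allele)
                thalf = predictor.stability(skeleton.peptide, allele)[0] if with_stability else None
                out.append(
                    replace(skeleton, allele=allele, affinity_nM=aff, thalf_h=thalf, binder_class=cls)
                )
    return out


def select_strong_binders(
    predictions: Iterable[EpitopePrediction],
    max_affinity: float = 100.0,
    require_class: str = "SB",
) -> list[EpitopePrediction]:
    """Strong binders with predicted affinity strictly below ``max_affinity`` nM."""
    return [
        p
        for p in predictions
        if p.binder_class == require_class
        and p.affinity_nM is not None
        and p.affinity_nM < max_affinity
    ]


def tier_counts(predictions: Iterable[EpitopePrediction]) -> dict[str, int]:
    """Number of predictions per affinity tier (all four tiers reported)."""
    counts = {b: 0 for b in AFFINITY_BINS}
    for p in predictions:
        if p.affinity_nM is not None:
            counts[classify_affinity_bin(p.affinity_nM)] += 1
    return counts


def combine_stability(
    predictions: Iterable[EpitopePrediction],
    stability_rows: Iterable[PredictorOutputRow],
    require_class: str = "SB",
    min_thalf_h: float | None = None,
) -> tuple[list[EpitopePrediction], int]:
    """Join stability predictions on (peptide, allele) and keep epitopes whose
    stability call is ``require_class`` (optionally also Thalf > ``min_thalf_h``).

    Epitopes lacking a stability row are dropped; the drop count is returned.
    """
    stability = {(r.peptide, r.allele): r for r in stability_rows}
    kept: list[EpitopePrediction] = []
    n_missing = 0
    for p in predictions:
        row = stability.get((p.peptide, p.allele))
        if row is None:
            n_missing += 1
            logger.warning("no stability row for %s / %s; dropped", p.peptide, p.allele)
            continue
        if row.binder_class != require_class:
            continue
        if min_thalf_h is not None and (row.thalf_h is None or row.thalf_h <= min_thalf_h):
            continue
        kept.append(replace(p, thalf_h=row.thalf_h))
    return kept, n_missing


@dataclass
class ProteinSummary:
    counts: dict[str, int]
    n_total: int
    minimum: int | None
    maximum: int | None
    mean: float | None  # reported to 2 decimals

    def __str__(self) -> str:
        if self.mean is None:
            return "no selected epitopes"
        return (
            f"{self.n_total} epitopes over {len(self.counts)} proteins; "
            f"per-protein mean {self.mean:.2f}, range {self.minimum}-{self.maximum}"
        )


def per_protein_summary(selected: Iterable[EpitopePrediction]) -> ProteinSummary:
    """Per-protein selected-epitope counts with min/max/mean (2-decimal mean)."""
    counts: dict[str, int] = {}
    for p in selected:
        counts[p.protein_id] = counts.get(p.protein_id, 0) + 1
    if not counts:
        return ProteinSummary(counts={}, n_total=0, minimum=None, maximum=None, mean=None)
    values = list(counts.values())
    return ProteinSummary(
        counts=counts,
        n_total=sum(values),
        minimum=min(values),
        maximum=max(values),
        mean=round(sum(values) / len(values), 2),
    )


# ---------------------------------------------------------------------------
# Toy predictor

#: residues scored as favourable at the primary anchors of an A2-like motif
_P2_ANCHORS = set("LM")
_P9_ANCHORS = set("VLI")


class ToyPredictor:
    """Deterministic pseudo-predictor driven by anchor positions 2 and 9.

    The affinity is a base value multiplied by a penalty of 20x per broken
    anchor and a seeded-hash perturbation in [1, 3); a peptide with both
    anchors intact therefore always scores strictly stronger (lower nM) than
    the same peptide with a broken anchor. Thalf decreases monotonically with
    affinity, perturbed the same way. SB/WB/NB follow fixed affinity
    thresholds (SB < 50 nM, WB < 500 nM); the stability call uses a Thalf
    threshold. Same inputs always give the same outputs.

    This is test plumbing, not a binding model: no training data, no allele
    specificity beyond the hash.
    """

    def __init__(
        self,
        seed: int = 0,
        base_affinity_nM: float = 5.0,
        anchor_penalty: float = 20.0,
        sb_max_nM: float = 50.0,
        wb_max_nM: float = 500.0,
        stability_sb_min_h: float = 1.0,
    ) -> None:
        self.seed = seed
        self.base_affinity_nM = base_affinity_nM
        self.anchor_penalty = anchor_penalty
        self.sb_max_nM = sb_max_nM
        self.wb_max_nM = wb_max_nM
        self.stability_sb_min_h = stability_sb_min_h

    def _hash_factor(self, key: str) -> float:
        h = zlib.crc32(f"{self.seed}:{key}".encode())
        return 1.0 + 2.0 * (h / 0xFFFFFFFF)  # in [1, 3)

    def affinity(self, peptide: str, allele: str) -> tuple[float, str]:
        if len(peptide) != 9:
            raise ValueError("toy predictor handles 9-mers only")
        penalty = 1.0
        if peptide[1] not in _P2_ANCHORS:
            penalty *= self.anchor_penalty
        if peptide[8] not in _P9_ANCHORS:
            penalty *= self.anchor_penalty
        aff = self.base_affinity_nM * penalty * self._hash_factor(f"aff:{peptide}:{allele}")
        if aff < self.sb_max_nM:
            cls = "SB"
        elif aff < self.wb_max_nM:
            cls = "WB"
        else:
            cls = "NB"
        return aff, cls

    def stability(self, peptide: str, allele: str) -> tuple[float, str]:
        aff, _ = self.affinity(peptide, allele)
        # strong binders get multi-hour half-lives, decaying with affinity
        thalf = 40.0 / (1.0 + aff / 10.0) * self._hash_factor(f"stab:{peptide}:{allele}")
        cls = "SB" if thalf > self.stability_sb_min_h else "WB"
        return thalf, cls


def toy_predictor(seed: int = 0, **kwargs) -> ToyPredictor:
    """Construct the deterministic stand-in predictor (see :class:`ToyPredictor`)."""
    return ToyPredictor(seed=seed, **kwargs)


class TablePredictor:
    """Predictor backed by parsed predictor-output rows (affinity + stability)."""

    def __init__(
        self,
        affinity_rows: Iterable[PredictorOutputRow],
        stability_rows: Iterable[PredictorOutputRow] = (),
    ) -> None:
        self._aff = {(r.peptide, r.allele): r for r in affinity_rows}
        self._stab = {(r.peptide, r.allele): r for r in stability_rows}

    def affinity(self, peptide: str, allele: str) -> tuple[float, str]:
        row = self._aff[(peptide, allele)]
        return row.affinity_nM, row.binder_class or "NB"

    def stability(self, peptide: str, allele: str) -> tuple[float, str]:
        row = self._stab[(peptide, allele)]
        return row.thalf_h, row.binder_class or "NB"
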