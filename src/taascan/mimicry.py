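"""Exhaustive ungapped molecular-mimicry scan of viral proteomes.

Candidate tumor epitopes are compared against every 9-residue window of every
viral protein by position-wise identity. At desk scale (proteomes up to ~10^7
residues) the exhaustive O(N x L) scan is fast, exact, and — unlike a
heuristic local-alignment search — guaranteed to find every window above the
identity floor. Retained matches are annotated with predicted binding of the
viral peptide to the restricting allele and filtered on binder class and
complex stability.

Ambiguous residues (X) never match anything, including another X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .hpa_io import ProteinSequence
from .epitope import EpitopePrediction, Predictor

logger = logging.getLogger(__name__)


def identity_score(a: str, b: str) -> tuple[int, list[int]]:
    """Position-wise identity of two 9-mers.

    Returns (number of identical residues, 1-based mismatch positions).
    Symmetric; X matches nothing.
    """
    if len(a) != len(b) or len(a) != 9:
        raise ValueError(f"peptides must both be 9-mers, got lengths {len(a)}, {len(b)}")
    mismatches = [
        i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y or x == "X"
    ]
    return 9 - len(mismatches), mismatches


@dataclass(frozen=True)
class MimicryMatch:
    """A viral 9-mer window meeting the identity floor against one epitope."""

    tumor_protein_id: str
    tumor_peptide: str
    viral_accession: str
    viral_position: int  # 1-based start of the window
    viral_peptide: str
    identity: int
    mismatch_positions: tuple[int, ...]

    @property
    def is_self_match(self) -> bool:
        return self.identity == 9


@dataclass(frozen=True)
class MimicryPair(MimicryMatch):
    """A retained match annotated with viral-peptide binding predictions."""

    allele: str = ""
    viral_affinity_nM: float | None = None
    viral_thalf_h: float | None = None
    viral_binder_class: str | None = None


def scan_viral_proteome(
    epitopes: Iterable[EpitopePrediction],
    proteome: Sequence[ProteinSequence],
    min_identity: int = 7,
) -> list[MimicryMatch]:
    """All (epitope, viral window) pairs with identity >= ``min_identity``.

    Every 9-residue window of every proteome record is scanned. Exact
    (identity 9) matches are included and flagged via ``is_self_match``.
    """
    if not (1 <= min_identity <= 9):
        raise ValueError("min_identity must lie in [1, 9]")
    epitopes = list(epitopes)
    if not proteome:
        logger.warning("empty viral proteome; no matches possible")
        return []
    matches: list[MimicryMatch] = []
    for record in proteome:
        seq = record.sequence
        for pos in range(len(seq) - 8):
            window = seq[pos : pos + 9]
            for ep in epitopes:
                identity, mismatches = identity_score(ep.peptide, window)
                if identity >= min_identity:
                    matches.append(
                        MimicryMatch(
                            tumor_protein_id=ep.protein_id,
                            tumor_peptide=ep.peptide,
                            viral_accession=record.protein_id,
                            viral_position=pos + 1,
                            viral_peptide=window,
                            identity=identity,
                            mismatch_positions=tuple(mismatches),
                        )
                    )
    return matches


def filter_viral_binders(
    matches: Iterable[MimicryMatch],
    predictor: Predictor,
    allele: str,
    min_thalf_h: float = 3.0,
    allowed_classes: frozenset[str] = frozenset({"SB", "WB"}),
) -> list[MimicryPair]:
    """Annotate viral peptides with predicted binding and keep pairs whose
    binder class is allowed and whose predicted Thalf exceeds ``min_thalf_h``.

    The class filter defaults to {SB, WB} because validated mimic pairs may
    include weak-binder viral peptides with adequate complex stability.
    """
    pairs: list[MimicryPair] = []
    for m in matches:
        try:
            affinity, cls = predictor.affinity(m.viral_peptide, allele)
            thalf, _ = predictor.stability(m.viral_peptide, allele)
        except Exception as exc:  # predictor failure drops the pair, never the scan
            logger.warning("predictor failed on %s/%s: %s", m.viral_peptide, allele, exc)
            continue
        if cls not in allowed_classes or thalf <= min_thalf_h:
            continue
        pairs.append(
            MimicryPair(
                **{f: getattr(m, f) for f in (
                    "tumor_protein_id", "tumor_peptide", "viral_accession",
                    "viral_position", "viral_peptide", "identity", "mismatch_positions",
                )},
                allele=allele,
                viral_affinity_nM=affinity,
                viral_thalf_h=thalf,
                viral_binder_class=cls,
            )
        )
    return pairs


def pair_report(pairs: Iterable[MimicryPair]) -> pd.DataFrame:
    """One row per retained pair, sorted by (allele, tumor protein,
    descending identity), ties broken by viral accession."""
    rows = [
        {
            "allele": p.allele,
            "tumor_protein": p.tumor_protein_id,
            "tumor_peptide": p.tumor_peptide,
            "viral_accession": p.viral_accession,
            "viral_position": p.viral_position,
            "viral_peptide": p.viral_peptide,
            "identity": p.identity,
            "mismatch_positions": ",".join(map(str, p.mismatch_positions)),
            "viral_affinity_nM": p.viral_affinity_nM,
            "viral_thalf_h": p.viral_thalf_h,
            "viral_binder_class": p.viral_binder_class,
        }
        for p in pairs
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "allele", "tumor_protein", "tumor_peptide", "viral_accession",
            "viral_position", "viral_peptide", "identity", "mismatch_positions",
            "viral_affinity_nM", "viral_thalf_h", "viral_binder_class",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["allele", "tumor_protein", "identity", "viral_accession", "viral_position"],
            ascending=[True, True, False, True, True],
        ).reset_index(drop=True)
    return df
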