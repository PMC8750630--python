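"""Five-stage liver-cancer-specific protein selection cascade.

The cascade narrows a gene universe to candidate tumor-associated antigens:

1. ``liver_negative`` — not detected by IHC in hepatocytes and bile duct
   cells of normal liver (requires at least one measurement there; genes with
   no liver record are excluded and reported separately — absence of evidence
   is not evidence of absence).
2. ``tumor_expressed`` — detected at any level in at least one patient sample
   of the named cancer in the pathology table.
3. ``high_multi_sample`` — high IHC staining in at least ``min_high``
   patient samples (default 2, a strict reading of "more than one sample").
4. ``pan_normal_negative`` — not detected in any normal-tissue cell type
   outside the exempt liver cells.
5. ``prognostic`` — best-cutoff survival p below ``alpha`` with the required
   direction (high expression associated with poor survival).

Stage survivor sets are nested by construction, and per-stage audit counts
and drop sets are carried on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hpa_io import (
    NOT_DETECTED,
    ConfigurationError,
    ExpressionRecord,
    PathologyProfile,
)

logger = logging.getLogger(__name__)

DEFAULT_LIVER_TISSUE = "liver"
DEFAULT_TARGET_CELLS = frozenset({"hepatocytes", "bile duct cells"})

STAGE_NAMES = (
    "universe",
    "liver_negative",
    "tumor_expressed",
    "high_multi_sample",
    "pan_normal_negative",
    "prognostic",
)


@dataclass
class CascadeConfig:
    cancer: str = "liver cancer"
    liver_tissue: str = DEFAULT_LIVER_TISSUE
    target_cells: frozenset[str] = DEFAULT_TARGET_CELLS
    min_high: int = 2
    alpha: float = 0.05
    direction: str = "unfavorable"
    #: if set, ignore normal-tissue records whose reliability is Uncertain
    #: in the pan-normal check
    require_reliable: bool = False


@dataclass
class CascadeResult:
    stage_names: tuple[str, ...]
    stage_survivors: dict[str, set[str]]
    config_snapshot: CascadeConfig
    dropped: dict[str, set[str]] = field(default_factory=dict)

    @property
    def stage_counts(self) -> dict[str, int]:
        return {name: len(self.stage_survivors[name]) for name in self.stage_names}

    @property
    def final_survivors(self) -> set[str]:
        return self.stage_survivors[self.stage_names[-1]]


def stage_liver_negative(
    records: Iterable[ExpressionRecord],
    target_cells: frozenset[str] = DEFAULT_TARGET_CELLS,
    liver_tissue: str = DEFAULT_LIVER_TISSUE,
) -> tuple[set[str], set[str]]:
    """Genes not detected in all measured liver target cells.

    Returns ``(retained, unmeasured)``: a gene is retained iff it has at
    least one record for (liver, target cell) and every such record is
    ``Not detected``; genes with no liver target-cell record at all are
    returned in the second set.
    """
    if not target_cells:
        raise ConfigurationError("target_cells must be non-empty")
    all_genes: set[str] = set()
    measured: set[str] = set()
    detected: set[str] = set()
    for rec in records:
        all_genes.add(rec.gene_id)
        if rec.tissue == liver_tissue and rec.cell_type in target_cells:
            measured.add(rec.gene_id)
            if rec.level != NOT_DETECTED:
                detected.add(rec.gene_id)
    retained = measured - detected
    unmeasured = all_genes - measured
    if unmeasured:
        logger.info("%d genes have no liver target-cell measurement", len(unmeasured))
    return retained, unmeasured


def stage_tumor_expressed(
    profiles: Iterable[PathologyProfile],
    genes: set[str],
    cancer: str = "liver cancer",
) -> set[str]:
    """Genes detected (high/medium/low) in >= 1 patient sample of ``cancer``."""
    retained: set[str] = set()
    profiled: set[str] = set()
    for p in profiles:
        if p.cancer != cancer or p.gene_id not in genes:
            continue
        profiled.add(p.gene_id)
        if p.n_detected >= 1:
            retained.add(p.gene_id)
    missing = genes - profiled
    if missing:
        logger.info("%d genes absent from the pathology table; excluded", len(missing))
    return retained


def stage_high_multi_sample(
    profiles: Iterable[PathologyProfile],
    genes: set[str],
    cancer: str = "liver cancer",
    min_high: int = 2,
) -> set[str]:
    """Genes with high staining in at least ``min_high`` patient samples."""
    if min_high < 1:
        raise ConfigurationError("min_high must be >= 1")
    return {
        p.gene_id
        for p in profiles
        if p.cancer == cancer and p.gene_id in genes and p.n_high >= min_high
    }


def stage_pan_normal_negative(
    records: Iterable[ExpressionRecord],
    genes: set[str],
    exempt_cells: frozenset[str] = DEFAULT_TARGET_CELLS,
    liver_tissue: str = DEFAULT_LIVER_TISSUE,
    require_reliable: bool = False,
) -> set[str]:
    """Genes with no detectable staining in any normal cell type outside the
    exempt liver cells."""
    detected: set[str] = set()
    for rec in records:
        if rec.gene_id not in genes:
            continue
        if rec.tissue == liver_tissue and rec.cell_type in exempt_cells:
            continue
        if require_reliable and rec.reliability == "Uncertain":
            continue
        if rec.level != NOT_DETECTED:
            detected.add(rec.gene_id)
    return genes - detected


def stage_prognostic(
    profiles: Iterable[PathologyProfile],
    genes: set[str],
    cancer: str = "liver cancer",
    alpha: float = 0.05,
    direction: str = "unfavorable",
) -> set[str]:
    """Genes whose best-cutoff survival p is strictly below ``alpha`` with
    the required prognosis direction; genes lacking prognostic data are
    excluded and logged."""
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError("alpha must lie in (0, 1)")
    retained: set[str] = set()
    n_missing = 0
    for p in profiles:
        if p.cancer != cancer or p.gene_id not in genes:
            continue
        if p.prognostic_p is None or p.prognosis_direction is None:
            n_missing += 1
            continue
        if p.prognostic_p < alpha and p.prognosis_direction == direction:
            retained.add(p.gene_id)
    if n_missing:
        logger.info("%d genes lacked prognostic annotation; excluded", n_missing)
    return retained


def run_cascade(
    records: Sequence[ExpressionRecord],
    profiles: Sequence[PathologyProfile],
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Apply the five stages in fixed order and collect per-stage audit sets."""
    cfg = config or CascadeConfig()
    universe = {r.gene_id for r in records} | {p.gene_id for p in profiles}

    s1, unmeasured = stage_liver_negative(records, cfg.target_cells, cfg.liver_tissue)
    s2 = stage_tumor_expressed(profiles, s1, cfg.cancer)
    s3 = stage_high_multi_sample(profiles, s2, cfg.cancer, cfg.min_high)
    s4 = stage_pan_normal_negative(
        records, s3, cfg.target_cells, cfg.liver_tissue, cfg.require_reliable
    )
    s5 = stage_prognostic(profiles, s4, cfg.cancer, cfg.alpha, cfg.direction)

    survivors: dict[str, set[str]] = {
        "universe": universe,
        "liver_negative": s1,
        "tumor_expressed": s2,
        "high_multi_sample": s3,
        "pan_normal_negative": s4,
        "prognostic": s5,
    }
    dropped = {"liver_unmeasured": unmeasured}
    for prev, cur in zip(STAGE_NAMES, STAGE_NAMES[1:]):
        dropped[cur] = survivors[prev] - survivors[cur]
    return CascadeResult(
        stage_names=STAGE_NAMES,
        stage_survivors=survivors,
        config_snapshot=cfg,
        dropped=dropped,
    )
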