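"""Paired and unpaired tumor-vs-normal expression comparison.

Count-like expression values are log2(x+1)-transformed by default before
testing. The paired comparison is a two-sided paired t-test on matched
tumor/normal samples; the unpaired comparison is a two-sided Welch
(unequal-variance) t-test. Direction is the sign of the mean tumor-minus-
normal difference on the transformed scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with tumor/normal labels and optional pairing.

    ``pairing`` maps tumor sample id -> normal sample id and must be a
    bijection between subsets of the two groups.
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: pd.Series  # sample id -> "tumor" | "normal"
    pairing: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        unknown = set(self.groups.unique()) - {"tumor", "normal"}
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        if self.pairing is not None:
            tumors = [t for t in self.pairing]
            normals = [n for n in self.pairing.values()]
            if len(set(normals)) != len(normals):
                raise ValueError("pairing is not a bijection (duplicate normal sample)")
            for t, n in self.pairing.items():
                if self.groups.get(t) != "tumor" or self.groups.get(n) != "normal":
                    raise ValueError(f"pair ({t}, {n}) does not map tumor -> normal")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


@dataclass
class CompareResult:
    statistic: float
    p_value: float
    direction: int  # sign of mean tumor - normal difference
    n: int
    warnings: list[str] = field(default_factory=list)


def _transform(x: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log2(x + 1.0) if log_transform else x


def paired_compare(
    matrix: ExpressionMatrix, gene: str, log_transform: bool = True
) -> CompareResult:
    """Two-sided paired t-test of tumor vs matched normal for one gene."""
    if matrix.pairing is None:
        raise ValueError("matrix has no pairing; use unpaired_compare")
    warnings: list[str] = []
    tumor_vals, normal_vals = [], []
    for t, n in matrix.pairing.items():
        if t not in matrix.values.columns or n not in matrix.values.columns:
            warnings.append(f"pair ({t}, {n}) incomplete; dropped")
            logger.warning("pair (%s, %s) incomplete; dropped", t, n)
            continue
        tumor_vals.append(matrix.values.at[gene, t])
        normal_vals.append(matrix.values.at[gene, n])
    n_pairs = len(tumor_vals)
    if n_pairs < 3:
        raise ValueError(f"paired comparison needs >= 3 complete pairs, have {n_pairs}")
    tumor = _transform(np.asarray(tumor_vals, dtype=float), log_transform)
    normal = _transform(np.asarray(normal_vals, dtype=float), log_transform)
    diff = tumor - normal
    if np.allclose(diff, 0.0):
        return CompareResult(statistic=0.0, p_value=1.0, direction=0, n=n_pairs, warnings=warnings)
    stat, p = stats.ttest_rel(tumor, normal)
    return CompareResult(
        statistic=float(stat),
        p_value=float(p),
        direction=int(np.sign(diff.mean())),
        n=n_pairs,
        warnings=warnings,
    )


def unpaired_compare(
    matrix: ExpressionMatrix, gene: str, log_transform: bool = True
) -> CompareResult:
    """Two-sided Welch t-test of tumor vs normal groups for one gene."""
    tumor_ids = matrix.samples("tumor")
    normal_ids = matrix.samples("normal")
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("both groups need >= 2 samples")
    tumor = _transform(matrix.values.loc[gene, tumor_ids].to_numpy(dtype=float), log_transform)
    normal = _transform(matrix.values.loc[gene, normal_ids].to_numpy(dtype=float), log_transform)
    warnings: list[str] = []
    if np.var(tumor) == 0 and np.var(normal) == 0:
        if np.isclose(tumor.mean(), normal.mean()):
            return CompareResult(0.0, 1.0, 0, len(tumor) + len(normal), ["degenerate: zero variance, equal means"])
        raise ValueError("degenerate comparison: zero variance in both groups with unequal means")
    stat, p = stats.ttest_ind(tumor, normal, equal_var=False)
    return CompareResult(
        statistic=float(stat),
        p_value=float(p),
        direction=int(np.sign(tumor.mean() - normal.mean())),
        n=len(tumor) + len(normal),
        warnings=warnings,
    )


def significance_stars(p: float) -> str:
    """Conventional star labels: ns / * (<0.05) / ** (<0.01) / *** (<0.001) /
    **** (<0.0001)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def read_expression_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Load a genes x samples TSV plus a sample sheet (sample, group, pair_id).

    Tumor/normal samples sharing a ``pair_id`` are matched.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    groups = pd.Series(sheet["group"].values, index=sheet["sample"])
    pairing = None
    if "pair_id" in sheet.columns:
        pairing = {}
        for pair_id, sub in sheet.dropna(subset=["pair_id"]).groupby("pair_id"):
            by_group = dict(zip(sub["group"], sub["sample"]))
            if {"tumor", "normal"} <= set(by_group):
                pairing[by_group["tumor"]] = by_group["normal"]
    return ExpressionMatrix(values=values, groups=groups, pairing=pairing or None)
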