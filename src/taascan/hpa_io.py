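"""Readers and writers for the table and sequence formats the pipeline touches.

All tabular formats are UTF-8, tab-separated, header required. Column names
follow the public Human Protein Atlas download dialect (``Gene``,
``Gene name``, ``Tissue``, ``Cell type``, ``Level``, ``Reliability`` for the
normal-tissue table; ``Gene``, ``Cancer``, ``High``, ``Medium``, ``Low``,
``Not detected`` for the pathology table) with a configurable alias map.
Parsers never silently coerce categorical tokens: every rejection carries a
row locator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

LEVELS = ("Not detected", "Low", "Medium", "High")
RELIABILITIES = ("Enhanced", "Supported", "Approved", "Uncertain")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical level token used throughout the package for absent staining.
NOT_DETECTED = "Not detected"


class SchemaError(ValueError):
    """A required column is missing from a table."""


class ValidationError(ValueError):
    """A cell value violates the schema; the message carries a row locator."""


class ConfigurationError(ValueError):
    """An option value is not usable (unknown dialect, empty set, ...)."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene x tissue x cell-type immunohistochemistry detection call."""

    gene_id: str
    gene_name: str
    tissue: str
    cell_type: str
    level: str
    reliability: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level token {self.level!r}")
        if self.reliability is not None and self.reliability not in RELIABILITIES:
            raise ValidationError(f"unknown reliability token {self.reliability!r}")


@dataclass(frozen=True)
class PathologyProfile:
    """Per-gene patient counts at each staining level for one cancer type.

    ``prognostic_p`` and ``prognosis_direction`` are optional best-cutoff
    survival annotations (log-rank p at the best expression cutoff, and
    whether high expression associates with worse or better survival).
    """

    gene_id: str
    cancer: str
    n_high: int
    n_medium: int
    n_low: int
    n_not_detected: int
    prognostic_p: float | None = None
    prognosis_direction: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_high", "n_medium", "n_low", "n_not_detected"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.prognostic_p is not None and not (0.0 < self.prognostic_p <= 1.0):
            raise ValidationError("prognostic_p must lie in (0, 1]")
        if self.prognosis_direction is not None and self.prognosis_direction not in (
            "unfavorable",
            "favorable",
        ):
            raise ValidationError(
                f"unknown prognosis direction {self.prognosis_direction!r}"
            )

    @property
    def n_detected(self) -> int:
        return self.n_high + self.n_medium + self.n_low


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with its accession; X is permitted but flagged."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for record {self.protein_id!r}")
        bad = set(self.sequence) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValidationError(
                f"illegal residue(s) {sorted(bad)} in record {self.protein_id!r}"
            )

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictorOutputRow:
    """One peptide x allele row parsed from a binding/stability predictor file."""

    peptide: str
    allele: str
    affinity_nM: float | None = None
    thalf_h: float | None = None
    binder_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.peptide) != 9:
            raise ValidationError(f"peptide {self.peptide!r} is not a 9-mer")
        if self.affinity_nM is not None and self.affinity_nM <= 0:
            raise ValidationError("affinity_nM must be positive")
        if self.binder_class is not None and self.binder_class not in ("SB", "WB", "NB"):
            raise ValidationError(f"unknown binder class {self.binder_class!r}")


# ---------------------------------------------------------------------------
# Normal-tissue table

NORMAL_ALIASES: Mapping[str, Sequence[str]] = {
    "gene_id": ("Gene",),
    "gene_name": ("Gene name", "Gene_name"),
    "tissue": ("Tissue",),
    "cell_type": ("Cell type", "Cell_type"),
    "level": ("Level",),
    "reliability": ("Reliability",),
}

PATHOLOGY_ALIASES: Mapping[str, Sequence[str]] = {
    "gene_id": ("Gene",),
    "cancer": ("Cancer",),
    "n_high": ("High",),
    "n_medium": ("Medium",),
    "n_low": ("Low",),
    "n_not_detected": ("Not detected", "Not_detected"),
    "prognostic_p": ("Prognostic p", "prognostic_p"),
    "prognosis_direction": ("Prognosis direction", "prognosis_direction"),
}


def _resolve_columns(
    columns: Iterable[str],
    aliases: Mapping[str, Sequence[str]],
    required: Sequence[str],
) -> dict[str, str]:
    present = list(columns)
    mapping: dict[str, str] = {}
    for canon, names in aliases.items():
        for name in names:
            if name in present:
                mapping[canon] = name
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(sorted(missing))} "
            f"(have: {', '.join(present)})"
        )
    return mapping


def read_expression_table(
    path: str | Path,
    aliases: Mapping[str, Sequence[str]] = NORMAL_ALIASES,
    missing_as_not_detected: bool = False,
) -> list[ExpressionRecord]:
    """Read a normal-tissue detection table into validated records.

    Rows are returned in file order. Unknown level tokens raise
    :class:`ValidationError` with the offending 1-based data-row number;
    empty/``N/A`` level cells are rejected unless ``missing_as_not_detected``
    is set, in which case they are coerced to ``Not detected``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df.columns, aliases, required=["gene_id", "gene_name", "tissue", "cell_type", "level"]
    )
    records: list[ExpressionRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i in range(1, len(df) + 1):
        values = dict(zip(df.columns, df.iloc[i - 1]))
        level = values[cols["level"]].strip()
        if level in ("", "N/A", "NA"):
            if missing_as_not_detected:
                level = NOT_DETECTED
            else:
                raise ValidationError(f"row {i}: missing level value")
        if level not in LEVELS:
            raise ValidationError(f"row {i}: unknown level token {level!r}")
        reliability = None
        if "reliability" in cols:
            token = values[cols["reliability"]].strip()
            if token:
                if token not in RELIABILITIES:
                    raise ValidationError(f"row {i}: unknown reliability token {token!r}")
                reliability = token
        rec = ExpressionRecord(
            gene_id=values[cols["gene_id"]].strip(),
            gene_name=values[cols["gene_name"]].strip(),
            tissue=values[cols["tissue"]].strip(),
            cell_type=values[cols["cell_type"]].strip(),
            level=level,
            reliability=reliability,
        )
        key = (rec.gene_id, rec.tissue, rec.cell_type)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate (gene, tissue, cell type) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [
        {
            "Gene": r.gene_id,
            "Gene name": r.gene_name,
            "Tissue": r.tissue,
            "Cell type": r.cell_type,
            "Level": r.level,
            "Reliability": r.reliability or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_count(token: str, row: int, column: str) -> int:
    try:
        value = int(token)
    except ValueError as exc:
        raise ValidationError(f"row {row}: non-numeric count {token!r} in {column}") from exc
    if value < 0:
        raise ValidationError(f"row {row}: negative count {value} in {column}")
    return value


def read_pathology_table(
    path: str | Path,
    aliases: Mapping[str, Sequence[str]] = PATHOLOGY_ALIASES,
) -> list[PathologyProfile]:
    """Read a pathology (per-cancer patient count) table.

    Missing prognostic cells yield ``None``, never zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df.columns,
        aliases,
        required=["gene_id", "cancer", "n_high", "n_medium", "n_low", "n_not_detected"],
    )
    profiles: list[PathologyProfile] = []
    for i in range(len(df)):
        values = dict(zip(df.columns, df.iloc[i]))
        row_no = i + 1
        counts = {
            name: _parse_count(values[cols[name]].strip(), row_no, cols[name])
            for name in ("n_high", "n_medium", "n_low", "n_not_detected")
        }
        prognostic_p = None
        direction = None
        if "prognostic_p" in cols:
            token = values[cols["prognostic_p"]].strip()
            if token not in ("", "N/A", "NA"):
                try:
                    prognostic_p = float(token)
                except ValueError as exc:
                    raise ValidationError(
                        f"row {row_no}: non-numeric prognostic p {token!r}"
                    ) from exc
        if "prognosis_direction" in cols:
            token = values[cols["prognosis_direction"]].strip()
            if token not in ("", "N/A", "NA"):
                direction = token
        profiles.append(
            PathologyProfile(
                gene_id=values[cols["gene_id"]].strip(),
                cancer=values[cols["cancer"]].strip(),
                prognostic_p=prognostic_p,
                prognosis_direction=direction,
                **counts,
            )
        )
    return profiles


def write_pathology_table(profiles: Iterable[PathologyProfile], path: str | Path) -> None:
    rows = [
        {
            "Gene": p.gene_id,
            "Cancer": p.cancer,
            "High": p.n_high,
            "Medium": p.n_medium,
            "Low": p.n_low,
            "Not detected": p.n_not_detected,
            "Prognostic p": "" if p.prognostic_p is None else repr(p.prognostic_p),
            "Prognosis direction": p.prognosis_direction or "",
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein FASTA; the accession is the first whitespace token of the header."""
    out: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"empty sequence under header {record.id!r}")
        out.append(ProteinSequence(protein_id=record.id, sequence=seq))
    return out


def write_fasta(proteins: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Predictor output files

DIALECTS = ("simple_tsv", "netmhcpan41", "netmhcstabpan10")


@dataclass
class PredictorParseResult:
    rows: list[PredictorOutputRow] = field(default_factory=list)
    n_skipped: int = 0


def _parse_simple_tsv(lines: Iterable[str]) -> PredictorParseResult:
    """Whitespace-separated: peptide allele affinity_nM [thalf_h] [class]."""
    result = PredictorParseResult()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        peptide, allele = parts[0], parts[1]
        if len(peptide) != 9:
            logger.warning("skipping non-9-mer peptide %r", peptide)
            result.n_skipped += 1
            continue
        affinity = float(parts[2]) if len(parts) > 2 else None
        thalf = None
        binder_class = None
        for token in parts[3:]:
            if token in ("SB", "WB", "NB"):
                binder_class = token
            else:
                thalf = float(token)
        result.rows.append(
            PredictorOutputRow(
                peptide=peptide,
                allele=allele,
                affinity_nM=affinity,
                thalf_h=thalf,
                binder_class=binder_class,
            )
        )
    return result


def _parse_netmhc_style(lines: Iterable[str], value_column: str) -> PredictorParseResult:
    """Parse the whitespace-aligned block format emitted by the NetMHC tools.

    Data lines start with an integer position; a header line names the
    columns. ``value_column`` selects the quantity of interest
    (``Aff(nM)`` for the affinity tool, ``Thalf(h)`` for the stability tool).
    Binder class is taken from a trailing ``<= SB`` / ``<= WB`` annotation.
    """
    result = PredictorParseResult()
    header: list[str] | None = None
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "---")):
            continue
        parts = stripped.split()
        if header is None and "Peptide" in parts:
            header = parts
            continue
        if not parts[0].lstrip("-").isdigit():
            continue
        if header is None:
            raise ValidationError("data line encountered before header line")
        idx = {name: i for i, name in enumerate(header)}
        pep_i = idx["Peptide"]
        allele_i = idx.get("MHC", idx.get("HLA", 1))
        try:
            value_i = idx[value_column]
        except KeyError as exc:
            raise SchemaError(f"missing column {value_column!r} in predictor output") from exc
        peptide = parts[pep_i]
        if len(peptide) != 9:
            logger.warning("skipping non-9-mer peptide %r", peptide)
            result.n_skipped += 1
            continue
        binder_class = None
        if "<=" in parts:
            binder_class = parts[parts.index("<=") + 1]
        value = float(parts[value_i])
        kwargs = dict(peptide=peptide, allele=parts[allele_i], binder_class=binder_class)
        if value_column == "Aff(nM)":
            kwargs["affinity_nM"] = value
        else:
            kwargs["thalf_h"] = value
        result.rows.append(PredictorOutputRow(**kwargs))
    return result


def read_predictor_output(path: str | Path, dialect: str = "simple_tsv") -> PredictorParseResult:
    """Parse a binding/stability predictor output file.

    Peptides of length other than nine are skipped with a logged warning;
    the skip count is reported on the result.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "simple_tsv":
        return _parse_simple_tsv(lines)
    if dialect == "netmhcpan41":
        return _parse_netmhc_style(lines, "Aff(nM)")
    return _parse_netmhc_style(lines, "Thalf(h)")


def write_predictor_output(rows: Iterable[PredictorOutputRow], path: str | Path) -> None:
    """Write rows in the ``simple_tsv`` dialect."""
    with open(path, "w") as fh:
        for r in rows:
            fields = [r.peptide, r.allele]
            if r.affinity_nM is not None:
                fields.append(repr(r.affinity_nM))
            if r.thalf_h is not None:
                fields.append(repr(r.thalf_h))
            if r.binder_class is not None:
                fields.append(r.binder_class)
            fh.write("\t".join(fields) + "\n")
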