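"""Synthetic inputs with planted, machine-readable ground truth.

Every input format the pipeline consumes can be generated here with known
answers: protein-atlas-style normal-tissue and pathology tables whose planted
positives survive all five cascade stages while each distractor fails exactly
one named stage; survival cohorts calibrated to target 5-year survival
fractions via exponential event times; tumor/viral protein FASTA with
homologs planted at exact identity; and assay data (dose-response binding
series, exponential decay series, multimer event mixtures with planted clone
frequencies).

All randomness flows through :class:`numpy.random.Generator` seeded from the
config, so outputs are byte-identical across runs for a fixed seed.
Background residues are drawn uniformly over the 20 amino acids, which keeps
chance-match rates exactly analyzable at the cost of realism; see the methods
note for what this does and does not emulate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_quant import (
    DEFAULT_CONCENTRATIONS_UM,
    DEFAULT_TIMEPOINTS_H,
    BindingSeries,
    DecaySeries,
    MultimerEventTable,
)
from .hpa_io import ExpressionRecord, NOT_DETECTED, PathologyProfile, ProteinSequence
from .survival import SurvivalCohort

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_TISSUES: Mapping[str, tuple[str, ...]] = {
    "liver": ("hepatocytes", "bile duct cells"),
    "cerebral cortex": ("neuronal cells", "glial cells"),
    "kidney": ("cells in tubules", "cells in glomeruli"),
    "lung": ("pneumocytes", "macrophages"),
    "colon": ("glandular cells", "endothelial cells"),
}

FAILURE_MODES = (
    "fail_liver_negative",
    "fail_tumor_expressed",
    "fail_high_multi_sample",
    "fail_pan_normal_negative",
    "fail_prognostic",
)


class GenerationError(ValueError):
    """A generator config is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Knobs for every generator, fully JSON-serializable.

    Defaults encode the study conditions the rest of the package is tested
    under: a 1000-gene universe with 9 full-cascade positives, 24 matched
    tumor/normal pairs, survival calibrated per-gene to published 5-year
    rates, and multimer clone frequencies at the published group averages.
    """

    seed: int = 0
    # cascade tables
    n_genes: int = 1000
    n_planted_cascade_positives: int = 9
    n_patients_pathology: int = 12
    cancer: str = "liver cancer"
    # survival
    surv5_high: float = 0.28
    surv5_low: float = 0.53
    n_per_group: int = 500
    censor_fraction: float = 0.0
    # expression matrices
    n_pairs: int = 24
    log2_fold_change: float = 2.0
    expression_noise_sd: float = 0.5
    baseline_log2_expression: float = 6.0
    # proteomes
    n_tumor_proteins: int = 9
    tumor_protein_length: int = 120
    n_viral_proteins: int = 50
    viral_protein_length: int = 300
    # toy predictor thresholds are owned by epitope.ToyPredictor
    # assays
    concentrations_uM: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    decay_half_life_h: float = 4.0
    decay_noise_cv: float = 0.0
    binding_fi_max: float = 2.5
    binding_ec50_uM: float = 15.0
    mfi_background: float = 100.0
    # multimer events
    n_events: int = 100_000
    n_donors_hcc: int = 4
    n_donors_healthy: int = 3
    background_median: float = 100.0
    clone_median: float = 10_000.0
    channel_log_sd: float = 0.25
    gate_fraction: float = 1.0  # fraction of events passing live/CD3/CD8

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


@dataclass
class GroundTruth:
    """Machine-readable record of what each generator planted."""

    planted_cascade_positives: list[str] = field(default_factory=list)
    distractor_failure_modes: dict[str, str] = field(default_factory=dict)
    prognostic_direction: dict[str, str] = field(default_factory=dict)
    planted_homologs: list[dict] = field(default_factory=list)
    clone_frequencies: dict[str, float] = field(default_factory=dict)
    cross_frequencies: dict[str, float] = field(default_factory=dict)
    assay_parameters: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# Protein-atlas-style tables


def gen_hpa_tables(
    config: SimulationConfig,
    tissues: Mapping[str, tuple[str, ...]] = DEFAULT_TISSUES,
) -> tuple[list[ExpressionRecord], list[PathologyProfile], GroundTruth]:
    """Generate normal-tissue and pathology tables with planted cascade truth.

    Planted positives satisfy all five stages by construction. Every
    distractor gene fails exactly one stage (assigned round-robin over the
    five failure modes) and passes the stages before it, so each stage is
    guaranteed to drop someone.
    """
    if config.n_planted_cascade_positives > config.n_genes:
        raise GenerationError("cannot plant more positives than genes")
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    n_pos = config.n_planted_cascade_positives
    positives = set(genes[:n_pos])
    truth = GroundTruth(planted_cascade_positives=sorted(positives))

    liver_cells = tissues["liver"]
    other = [(t, c) for t, cells in tissues.items() if t != "liver" for c in cells]
    n_patients = config.n_patients_pathology

    records: list[ExpressionRecord] = []
    profiles: list[PathologyProfile] = []
    for idx, gene in enumerate(genes):
        if gene in positives:
            mode = "positive"
        else:
            mode = FAILURE_MODES[(idx - n_pos) % len(FAILURE_MODES)]
            truth.distractor_failure_modes[gene] = mode

        # --- normal-tissue records
        liver_levels = {c: NOT_DETECTED for c in liver_cells}
        if mode == "fail_liver_negative":
            liver_levels[liver_cells[int(rng.integers(len(liver_cells)))]] = "Low"
        other_levels = {tc: NOT_DETECTED for tc in other}
        if mode == "fail_pan_normal_negative":
            tissue, cell = other[int(rng.integers(len(other)))]
            other_levels[(tissue, cell)] = str(rng.choice(["Low", "Medium", "High"]))
        for cell, level in liver_levels.items():
            records.append(
                ExpressionRecord(
                    gene_id=gene, gene_name=gene.replace("GENE", "G"),
                    tissue="liver", cell_type=cell, level=level, reliability="Supported",
                )
            )
        for (tissue, cell), level in other_levels.items():
            records.append(
                ExpressionRecord(
                    gene_id=gene, gene_name=gene.replace("GENE", "G"),
                    tissue=tissue, cell_type=cell, level=level, reliability="Supported",
                )
            )

        # --- pathology counts
        if mode == "fail_tumor_expressed":
            n_high, n_medium, n_low = 0, 0, 0
        elif mode == "fail_high_multi_sample":
            n_high = int(rng.integers(0, 2))  # 0 or 1 high samples
            n_medium = int(rng.integers(1, 4))
            n_low = int(rng.integers(0, 4))
        else:
            n_high = int(rng.integers(2, n_patients - 1))
            n_medium = int(rng.integers(0, n_patients - n_high))
            n_low = int(rng.integers(0, n_patients - n_high - n_medium + 1))
        n_nd = n_patients - n_high - n_medium - n_low

        if mode == "positive":
            p_val = float(rng.uniform(0.001, 0.049))
            direction = "unfavorable"
        elif mode == "fail_prognostic":
            # half miss on significance, half on direction
            if rng.random() < 0.5:
                p_val = float(rng.uniform(0.05, 0.9))
                direction = "unfavorable"
            else:
                p_val = float(rng.uniform(0.001, 0.049))
                direction = "favorable"
        else:
            p_val = float(rng.uniform(0.001, 0.9))
            direction = str(rng.choice(["unfavorable", "favorable"]))
        truth.prognostic_direction[gene] = direction
        profiles.append(
            PathologyProfile(
                gene_id=gene, cancer=config.cancer,
                n_high=n_high, n_medium=n_medium, n_low=n_low, n_not_detected=n_nd,
                prognostic_p=p_val, prognosis_direction=direction,
            )
        )
    return records, profiles, truth


# ---------------------------------------------------------------------------
# Survival cohorts


def gen_survival_cohort(
    n_per_group: int,
    surv5_high: float,
    surv5_low: float,
    seed: int,
    gene: str = "GENE",
    censor_fraction: float = 0.0,
    max_follow_up: float = 10.0,
) -> tuple[SurvivalCohort, float]:
    """Exponential-survival cohort calibrated to target 5-year fractions.

    Event times are exponential with rate lambda = -ln(surv5)/5 per group, so
    the true survival fraction at five years equals the target exactly.
    High-expression subjects get expression above the returned cutoff, low
    below. Censoring (uniform on (0, max_follow_up)) is off by default so the
    product-limit estimate equals the empirical surviving fraction.

    Returns (cohort, expression cutoff separating the groups).
    """
    for s in (surv5_high, surv5_low):
        if not (0.0 < s < 1.0):
            raise GenerationError("5-year survival targets must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lam_high = -math.log(surv5_high) / 5.0
    lam_low = -math.log(surv5_low) / 5.0
    t_high = rng.exponential(1.0 / lam_high, size=n_per_group)
    t_low = rng.exponential(1.0 / lam_low, size=n_per_group)
    cutoff = 1.0
    expr_high = rng.uniform(1.5, 3.0, size=n_per_group)
    expr_low = rng.uniform(0.0, 0.5, size=n_per_group)
    time = np.concatenate([t_high, t_low])
    expr = np.concatenate([expr_high, expr_low])
    event = np.ones(2 * n_per_group, dtype=bool)
    if censor_fraction > 0:
        censored = rng.random(2 * n_per_group) < censor_fraction
        c_times = rng.uniform(0.0, max_follow_up, size=2 * n_per_group)
        cut = censored & (c_times < time)
        time = np.where(cut, c_times, time)
        event = ~cut
    cohort = SurvivalCohort(
        time=time,
        event=event,
        expression=pd.DataFrame({gene: expr}),
        subject_id=np.array([f"S{i:05d}" for i in range(2 * n_per_group)]),
    )
    return cohort, cutoff


# ---------------------------------------------------------------------------
# Expression matrices


def gen_expression_matrix(config: SimulationConfig, gene: str = "GENE00000"):
    """Paired tumor/normal matrix with one planted log2 fold-change gene.

    Values are 2**(baseline + effect + noise) - 1, i.e. count-like on the
    natural scale with Gaussian structure after the pipeline's log2(x+1).
    """
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(config.seed + 17)
    n = config.n_pairs
    tumor_ids = [f"T{i:03d}" for i in range(n)]
    normal_ids = [f"N{i:03d}" for i in range(n)]
    base = config.baseline_log2_expression
    tumor_log = base + config.log2_fold_change + rng.normal(0, config.expression_noise_sd, n)
    normal_log = base + rng.normal(0, config.expression_noise_sd, n)
    values = pd.DataFrame(
        [np.concatenate([2.0**tumor_log - 1, 2.0**normal_log - 1])],
        index=[gene],
        columns=tumor_ids + normal_ids,
    )
    groups = pd.Series(
        ["tumor"] * n + ["normal"] * n, index=tumor_ids + normal_ids
    )
    pairing = dict(zip(tumor_ids, normal_ids))
    return ExpressionMatrix(values=values, groups=groups, pairing=pairing)


# ---------------------------------------------------------------------------
# Proteomes with planted homologs


@dataclass
class HomologSpec:
    """One viral homolog to plant: which epitope, at what identity, where."""

    epitope: str
    identity: int
    accession: str
    position: int  # 1-based start within the viral protein


def _mutate_to_identity(epitope: str, identity: int, rng: np.random.Generator) -> str:
    if not (1 <= identity <= 9):
        raise GenerationError("planted identity must lie in [1, 9]")
    n_mut = 9 - identity
    positions = rng.choice(9, size=n_mut, replace=False)
    peptide = list(epitope)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != epitope[pos]]
        peptide[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(peptide)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteomes(
    config: SimulationConfig,
    homolog_specs: Sequence[HomologSpec] = (),
    tumor_epitopes: Sequence[str] = (),
) -> tuple[list[ProteinSequence], list[ProteinSequence], GroundTruth]:
    """Tumor-protein and viral-proteome FASTA collections with planted truth.

    Each requested tumor epitope is embedded verbatim in one tumor protein;
    each homolog spec plants a viral 9-mer at exactly the requested identity
    to its epitope, at the recorded accession and position, over an i.i.d.
    uniform-residue background.
    """
    rng = np.random.default_rng(config.seed + 29)
    truth = GroundTruth()

    tumor: list[ProteinSequence] = []
    for i in range(config.n_tumor_proteins):
        seq = _random_sequence(config.tumor_protein_length, rng)
        if i < len(tumor_epitopes):
            ep = tumor_epitopes[i]
            insert_at = int(rng.integers(0, config.tumor_protein_length - 9))
            seq = seq[:insert_at] + ep + seq[insert_at + 9 :]
        tumor.append(ProteinSequence(protein_id=f"TUMOR{i:03d}", sequence=seq))

    by_accession: dict[str, list[HomologSpec]] = {}
    for spec in homolog_specs:
        by_accession.setdefault(spec.accession, []).append(spec)

    viral: list[ProteinSequence] = []
    for i in range(config.n_viral_proteins):
        accession = f"VIRAL{i:03d}"
        seq = _random_sequence(config.viral_protein_length, rng)
        for spec in by_accession.get(accession, []):
            if spec.position < 1 or spec.position + 8 > len(seq):
                raise GenerationError(
                    f"homolog position {spec.position} outside protein of "
                    f"length {len(seq)}"
                )
            homolog = _mutate_to_identity(spec.epitope, spec.identity, rng)
            start = spec.position - 1
            seq = seq[:start] + homolog + seq[start + 9 :]
            truth.planted_homologs.append(
                {
                    "epitope": spec.epitope,
                    "viral_peptide": homolog,
                    "identity": spec.identity,
                    "accession": accession,
                    "position": spec.position,
                }
            )
        viral.append(ProteinSequence(protein_id=accession, sequence=seq))
    unknown = set(by_accession) - {p.protein_id for p in viral}
    if unknown:
        raise GenerationError(f"homolog spec names unknown accession(s) {sorted(unknown)}")
    return tumor, viral, truth


# ---------------------------------------------------------------------------
# Assay data


def gen_binding_series(
    config: SimulationConfig, peptide: str = "PEP", binder: bool = True, seed_offset: int = 0
) -> BindingSeries:
    """Saturating dose-response binding series (flat at background if not a binder)."""
    rng = np.random.default_rng(config.seed + 37 + seed_offset)
    bg = config.mfi_background
    mfi = []
    for c in config.concentrations_uM:
        fi = config.binding_fi_max * c / (c + config.binding_ec50_uM) if binder else 0.0
        noise = rng.normal(0, config.decay_noise_cv) if config.decay_noise_cv > 0 else 0.0
        mfi.append(bg * (1.0 + fi) * math.exp(noise))
    return BindingSeries(
        peptide=peptide,
        concentration_uM=tuple(config.concentrations_uM),
        mfi=tuple(mfi),
        mfi_background=bg,
    )


def gen_decay_series(
    half_life_h: float,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    mfi0: float = 1000.0,
    noise_cv: float = 0.0,
    peptide: str = "PEP",
    seed: int = 0,
) -> DecaySeries:
    """Exponential decay series with configured half-life and optional
    multiplicative log-normal noise (time zero is left noise-free so
    normalization is exact)."""
    if half_life_h <= 0:
        raise GenerationError("half-life must be positive")
    rng = np.random.default_rng(seed)
    mfi = []
    for t in timepoints_h:
        value = mfi0 * 2.0 ** (-t / half_life_h)
        if noise_cv > 0 and t > 0:
            value *= float(rng.lognormal(0.0, noise_cv))
        mfi.append(value)
    return DecaySeries(peptide=peptide, timepoints_h=tuple(timepoints_h), mfi=tuple(mfi))


def gen_multimer_events(
    config: SimulationConfig,
    donor_id: str,
    group: str,
    clone_frequencies: Mapping[str, float],
    cross_frequencies: Mapping[str, tuple[str, str, float]] | None = None,
    seed: int = 0,
) -> MultimerEventTable:
    """Per-event multimer table with clones planted at exact frequencies.

    ``clone_frequencies`` maps channel name -> TOTAL positive fraction among
    gated events. ``cross_frequencies`` maps pair name -> (TAA channel, viral
    channel, fraction) of events positive in both channels; cross events are
    planted first and count toward both channels' totals, so each pair's
    fraction must not exceed either channel total.

    Intensities are log-normal: background at ``background_median``, clones at
    ``clone_median``, both with ``channel_log_sd`` on the log scale. With the
    defaults the two populations sit ~18 log-SD apart, so any threshold
    between them gates without error.
    """
    rng = np.random.default_rng(seed)
    n = config.n_events
    channels = list(clone_frequencies)
    cross_frequencies = cross_frequencies or {}

    cross_per_channel: dict[str, float] = {c: 0.0 for c in channels}
    for name, (taa_ch, viral_ch, frac) in cross_frequencies.items():
        for ch in (taa_ch, viral_ch):
            if ch not in clone_frequencies:
                raise GenerationError(f"cross pair {name!r} references unknown channel {ch!r}")
            cross_per_channel[ch] += frac
            if cross_per_channel[ch] > clone_frequencies[ch] + 1e-12:
                raise GenerationError(
                    f"cross fraction for channel {ch!r} exceeds its total frequency"
                )
    if any(f < 0 or f > 1 for f in clone_frequencies.values()):
        raise GenerationError("clone frequencies must lie in [0, 1]")

    positive = {c: np.zeros(n, dtype=bool) for c in channels}
    order = rng.permutation(n)
    cursor = 0
    for name, (taa_ch, viral_ch, frac) in cross_frequencies.items():
        k = int(round(frac * n))
        idx = order[cursor : cursor + k]
        cursor += k
        positive[taa_ch][idx] = True
        positive[viral_ch][idx] = True
    for c in channels:
        single = clone_frequencies[c] - cross_per_channel[c]
        k = int(round(single * n))
        # draw from events not yet positive in this channel
        candidates = np.flatnonzero(~positive[c])
        idx = rng.choice(candidates, size=k, replace=False)
        positive[c][idx] = True

    log_bg = math.log(config.background_median)
    log_clone = math.log(config.clone_median)
    sd = config.channel_log_sd
    data = {
        "live": np.ones(n, dtype=int),
        "cd3": rng.lognormal(log_clone, sd, n),
        "cd8": rng.lognormal(log_clone, sd, n),
    }
    if config.gate_fraction < 1.0:
        fail = rng.random(n) >= config.gate_fraction
        data["live"][fail] = 0
    for c in channels:
        intensities = rng.lognormal(log_bg, sd, n)
        pos = positive[c]
        intensities[pos] = rng.lognormal(log_clone, sd, int(pos.sum()))
        data[c] = intensities
    return MultimerEventTable(donor_id=donor_id, group=group, events=pd.DataFrame(data))


def gen_assay_data(
    config: SimulationConfig,
    clone_frequencies: Mapping[str, float] | None = None,
    cross_frequencies: Mapping[str, tuple[str, str, float]] | None = None,
) -> tuple[list[BindingSeries], list[DecaySeries], list[MultimerEventTable], GroundTruth]:
    """Generate one bundle of assay inputs and record the planted parameters."""
    clone_frequencies = dict(clone_frequencies or {"TAA_MDK": 0.0088})
    cross_frequencies = dict(cross_frequencies or {})
    truth = GroundTruth(
        clone_frequencies=dict(clone_frequencies),
        cross_frequencies={k: v[2] for k, v in cross_frequencies.items()},
        assay_parameters={
            "decay_half_life_h": config.decay_half_life_h,
            "binding_ec50_uM": config.binding_ec50_uM,
            "binding_fi_max": config.binding_fi_max,
        },
    )
    binding = [
        gen_binding_series(config, peptide="CANDIDATE", binder=True, seed_offset=0),
        gen_binding_series(config, peptide="OVA_CONTROL", binder=False, seed_offset=1),
    ]
    decay = [
        gen_decay_series(
            config.decay_half_life_h,
            config.timepoints_h,
            noise_cv=config.decay_noise_cv,
            peptide="CANDIDATE",
            seed=config.seed + 41,
        )
    ]
    donors = [(f"HCC{i+1}", "HCC") for i in range(config.n_donors_hcc)] + [
        (f"HD{i+1}", "healthy") for i in range(config.n_donors_healthy)
    ]
    events = [
        gen_multimer_events(
            config,
            donor_id=donor,
            group=group,
            clone_frequencies=clone_frequencies,
            cross_frequencies=cross_frequencies,
            seed=config.seed + 1000 + i,
        )
        for i, (donor, group) in enumerate(donors)
    ]
    return binding, decay, events, truth
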