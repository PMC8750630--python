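"""Quantification of the wet-lab validation assays.

Three readouts are covered:

* **T2 binding** — TAP-deficient T2 cells display surface MHC only when an
  exogenous peptide stabilizes the complex; binding is quantified as the
  fluorescence index FI = (MFI_sample - MFI_background) / MFI_background,
  with FI > 0.5 (strict) calling a binder.
* **BFA decay** — brefeldin A blocks export of new complexes, so surface MFI
  decays as loaded complexes dissociate; DC50 is the time for the signal to
  fall to 50% of its value at time zero. The default *discrete* mode reports
  the first sampled timepoint at or below 50% (how timecourse experiments
  sampled every 2 h are read); *interpolated* mode linearly interpolates the
  crossing between bracketing samples.
* **pMHC multimers** — per-event flow tables are gated on live / CD3+ / CD8+
  and the fraction of gated events positive for each multimer channel is
  reported; cross-reactivity is double positivity in a configured TAA/viral
  channel pair within the same event.

Replicate MFI measurements are averaged before FI/DC50 computation, with the
standard error of the mean carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CONCENTRATIONS_UM = (5.0, 10.0, 20.0, 50.0, 100.0)
DEFAULT_TIMEPOINTS_H = (0.0, 2.0, 4.0, 6.0, 8.0)

FI_BINDER_THRESHOLD = 0.5


@dataclass
class BindingSeries:
    """MFI per peptide concentration for one peptide, plus no-peptide background."""

    peptide: str
    concentration_uM: tuple[float, ...]
    mfi: tuple[float, ...]
    mfi_background: float

    def __post_init__(self) -> None:
        if self.mfi_background <= 0 or any(m <= 0 for m in self.mfi):
            raise ValueError("MFI values must be positive")
        if any(b <= a for a, b in zip(self.concentration_uM, self.concentration_uM[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.concentration_uM) != len(self.mfi):
            raise ValueError("concentration and MFI lengths differ")


@dataclass
class DecaySeries:
    """MFI per timepoint after export block, for one peptide."""

    peptide: str
    timepoints_h: tuple[float, ...]
    mfi: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.timepoints_h[0] != 0:
            raise ValueError("timepoints must start at 0")
        if any(b <= a for a, b in zip(self.timepoints_h, self.timepoints_h[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.timepoints_h) != len(self.mfi):
            raise ValueError("timepoint and MFI lengths differ")
        if self.mfi[0] <= 0:
            raise ValueError("MFI at time 0 must be positive")


def fluorescence_index(mfi_sample: float, mfi_background: float) -> float:
    """FI = (MFI_sample - MFI_background) / MFI_background."""
    if mfi_background <= 0:
        raise ValueError("background MFI must be positive")
    return (mfi_sample - mfi_background) / mfi_background


def is_binder(fi: float, threshold: float = FI_BINDER_THRESHOLD) -> bool:
    """Binder call: FI strictly above the threshold."""
    return fi > threshold


@dataclass
class BindingProfile:
    peptide: str
    concentration_uM: tuple[float, ...]
    fi: tuple[float, ...]
    binder: bool
    monotone: bool


def binding_profile(series: BindingSeries, threshold: float = FI_BINDER_THRESHOLD) -> BindingProfile:
    """Per-concentration FI, overall binder call (FI > threshold at any dose),
    and a dose-monotonicity flag (FI non-decreasing with concentration)."""
    if len(series.concentration_uM) < 2:
        raise ValueError("binding profile needs >= 2 concentrations")
    fi = tuple(fluorescence_index(m, series.mfi_background) for m in series.mfi)
    return BindingProfile(
        peptide=series.peptide,
        concentration_uM=series.concentration_uM,
        fi=fi,
        binder=any(is_binder(v, threshold) for v in fi),
        monotone=all(b >= a for a, b in zip(fi, fi[1:])),
    )


def percent_remaining(series: DecaySeries) -> tuple[float, ...]:
    """MFI normalized to time zero, in percent (100 at t=0)."""
    m0 = series.mfi[0]
    return tuple(100.0 * m / m0 for m in series.mfi)


@dataclass(frozen=True)
class DC50Result:
    """DC50 in hours, or not-reached within the sampled window."""

    hours: float | None
    reached: bool
    mode: str
    max_time_h: float

    def __str__(self) -> str:
        if self.reached:
            return f"DC50 = {self.hours:g} h ({self.mode})"
        return f"DC50 not reached (> {self.max_time_h:g} h)"


def dc50(series: DecaySeries, mode: str = "discrete") -> DC50Result:
    """Time for the surface signal to fall to 50% of its value at time zero.

    ``discrete`` returns the first sampled timepoint with percent remaining
    <= 50; ``interpolated`` returns the linear crossing time between the
    bracketing samples. When no sample reaches 50%, the result reports
    not-reached beyond the last timepoint.
    """
    if mode not in ("discrete", "interpolated"):
        raise ValueError(f"unknown DC50 mode {mode!r}")
    if len(series.timepoints_h) < 2:
        raise ValueError("DC50 needs >= 2 timepoints")
    pct = percent_remaining(series)
    times = series.timepoints_h
    eps = 1e-9
    for i, p in enumerate(pct):
        if p <= 50.0 + eps:
            if mode == "discrete" or i == 0:
                return DC50Result(hours=times[i], reached=True, mode=mode, max_time_h=times[-1])
            p0, p1 = pct[i - 1], p
            t0, t1 = times[i - 1], times[i]
            t_cross = t0 + (p0 - 50.0) / (p0 - p1) * (t1 - t0)
            return DC50Result(hours=t_cross, reached=True, mode=mode, max_time_h=times[-1])
    return DC50Result(hours=None, reached=False, mode=mode, max_time_h=times[-1])


def average_replicates(
    table: pd.DataFrame,
    value_col: str = "mfi",
    key_cols: Sequence[str] = ("peptide", "x"),
) -> pd.DataFrame:
    """Average replicate MFI measurements; report SEM alongside.

    ``table`` has one row per replicate measurement with ``key_cols``
    identifying the condition (peptide and concentration or timepoint).
    """
    grouped = table.groupby(list(key_cols))[value_col]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": value_col, "sem": f"{value_col}_sem", "count": "n_replicates"})


# ---------------------------------------------------------------------------
# pMHC multimer frequencies


@dataclass
class MultimerEventTable:
    """Per-event flow-cytometry intensities for one donor.

    ``events`` holds one row per event with columns ``live`` (0/1),
    ``cd3``, ``cd8``, and one intensity column per multimer channel.
    """

    donor_id: str
    group: str  # "HCC" | "healthy"
    events: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"live", "cd3", "cd8"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing column(s) {sorted(missing)}")
        channels = self.channel_names
        if len(channels) != len(set(channels)):
            raise ValueError("multimer channel names must be unique")
        numeric = self.events.drop(columns=["live"])
        if (numeric.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def channel_names(self) -> list[str]:
        return [c for c in self.events.columns if c not in ("live", "cd3", "cd8")]


@dataclass
class GatingThresholds:
    """Explicit per-channel positivity thresholds (no automated gating)."""

    cd3: float
    cd8: float
    multimer: Mapping[str, float]


@dataclass
class MultimerResult:
    donor_id: str
    group: str
    n_gated: int
    percent: dict[str, float]  # channel -> % of gated events positive
    cross_percent: dict[str, float] = field(default_factory=dict)  # pair name -> %


def multimer_frequencies(
    table: MultimerEventTable,
    thresholds: GatingThresholds,
    pairs: Mapping[str, tuple[str, str]] | None = None,
) -> MultimerResult:
    """Multimer-positive percentages out of live CD3+ CD8+ events.

    ``pairs`` names cross-reactivity pairs as (TAA channel, viral channel);
    the cross percentage counts events positive in BOTH channels.
    """
    ev = table.events
    gate = (ev["live"].astype(bool)) & (ev["cd3"] > thresholds.cd3) & (ev["cd8"] > thresholds.cd8)
    n_gated = int(gate.sum())
    if n_gated == 0:
        raise ValueError("no events pass the live/CD3/CD8 gate")
    gated = ev.loc[gate]
    percent: dict[str, float] = {}
    positive: dict[str, pd.Series] = {}
    for channel in table.channel_names:
        thr = thresholds.multimer.get(channel)
        if thr is None:
            raise ValueError(f"no threshold configured for channel {channel!r}")
        pos = gated[channel] > thr
        positive[channel] = pos
        percent[channel] = 100.0 * float(pos.sum()) / n_gated
    cross: dict[str, float] = {}
    if pairs:
        for name, (taa_ch, viral_ch) in pairs.items():
            if taa_ch not in positive or viral_ch not in positive:
                raise ValueError(f"pair {name!r} references unknown channel")
            both = positive[taa_ch] & positive[viral_ch]
            cross[name] = 100.0 * float(both.sum()) / n_gated
    return MultimerResult(
        donor_id=table.donor_id,
        group=table.group,
        n_gated=n_gated,
        percent=percent,
        cross_percent=cross,
    )


@dataclass
class GroupSummary:
    group: str
    n_donors: int
    mean_percent: dict[str, float]
    mean_cross_percent: dict[str, float]


def group_summary(results: Iterable[MultimerResult]) -> dict[str, GroupSummary]:
    """Arithmetic mean of per-donor percentages within each donor group."""
    by_group: dict[str, list[MultimerResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    out: dict[str, GroupSummary] = {}
    for group, rs in by_group.items():
        channels = rs[0].percent.keys()
        pairs = rs[0].cross_percent.keys()
        out[group] = GroupSummary(
            group=group,
            n_donors=len(rs),
            mean_percent={c: float(np.mean([r.percent[c] for r in rs])) for c in channels},
            mean_cross_percent={
                p: float(np.mean([r.cross_percent[p] for r in rs])) for p in pairs
            },
        )
    return out
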