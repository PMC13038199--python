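"""Formula-level splicing quantities: PSI, delta-PSI, pooled exon usage.

PSI (proportion spliced in) of an alternative-splicing event is the
inclusion-form share of transcript abundance,

    PSI = sum TPM(inclusion) / (sum TPM(inclusion) + sum TPM(exclusion)),

undefined — propagated as missing, never as 0 — when the denominator is 0.
Delta-PSI between two sample groups is the difference of group mean PSIs;
its significance is assessed by a label-permutation null, which is
assumption-light and self-contained.  Pooled exon usage averages normalized
exon counts over a group of exons per sample first, then over samples per
condition (mean +/- SEM), matching how constitutive exon blocks (e.g. AR
exons 1-3 and 4-8) are compared between knockdown arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, CoverageError, StructuralError, ValidationError

#: headline delta-PSI magnitude cutoffs reported alongside each event
DPSI_STRICT_CUTOFF = 0.6
DPSI_LENIENT_CUTOFF = 0.2


@dataclass(frozen=True)
class EventDefinition:
    """An alternative-splicing event as inclusion vs exclusion transcript sets."""

    event_id: str
    inclusion_transcripts: frozenset
    exclusion_transcripts: frozenset
    event_class: str = "SE"

    def __post_init__(self) -> None:
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValidationError("inclusion and exclusion sets must be non-empty")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValidationError(
                f"event {self.event_id!r}: inclusion and exclusion sets overlap"
            )

    @classmethod
    def make(cls, event_id: str, inclusion: Sequence[str], exclusion: Sequence[str],
             event_class: str = "SE") -> "EventDefinition":
        return cls(event_id, frozenset(inclusion), frozenset(exclusion), event_class)


def psi(event: EventDefinition, tpm: Mapping[str, float]) -> float | None:
    """PSI of one event from a transcript->TPM map; None when undefined."""
    missing = [t for t in (event.inclusion_transcripts | event.exclusion_transcripts)
               if t not in tpm]
    if missing:
        raise CoverageError(f"transcripts absent from TPM map: {sorted(missing)[:10]}")
    inc = sum(float(tpm[t]) for t in event.inclusion_transcripts)
    exc = sum(float(tpm[t]) for t in event.exclusion_transcripts)
    if inc < 0 or exc < 0:
        raise ValidationError("TPM values must be non-negative")
    total = inc + exc
    if total == 0:
        return None
    return inc / total


def psi_table(
    events: Sequence[EventDefinition],
    tpm_by_sample: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Events x samples PSI matrix (NaN where undefined)."""
    data = {
        sample: [psi(ev, tpm) for ev in events]
        for sample, tpm in tpm_by_sample.items()
    }
    return pd.DataFrame(data, index=[ev.event_id for ev in events], dtype=float)


def delta_psi(
    events: Sequence[EventDefinition],
    tpm_by_sample: Mapping[str, Mapping[str, float]],
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-event delta-PSI (mean B - mean A) with a label-permutation p-value.

    Events with an undefined PSI in any sample are flagged
    (``undefined=True``) and excluded from testing.  Two-sided p:
    ``(#{|null| >= |observed|} + 1) / (B + 1)``.  Threshold flags at the
    |dPSI| >= 0.6 and >= 0.2 magnitudes are reported per event.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise StructuralError("sample groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise StructuralError("need >= 2 samples per group")
    missing = [s for s in group_a + group_b if s not in tpm_by_sample]
    if missing:
        raise CoverageError(f"samples absent from TPM data: {missing}")

    table = psi_table(events, tpm_by_sample)[group_a + group_b]
    n_a = len(group_a)
    labels = np.arange(n_a + len(group_b))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(labels) for _ in range(n_permutations)])

    rows = []
    for ev in events:
        vals = table.loc[ev.event_id].to_numpy(dtype=float)
        if np.isnan(vals).any():
            rows.append((ev.event_id, ev.event_class, math.nan, math.nan,
                         True, False, False))
            continue
        observed = vals[n_a:].mean() - vals[:n_a].mean()
        null = perms_delta(vals, perms, n_a)
        p = (np.sum(np.abs(null) >= abs(observed)) + 1) / (n_permutations + 1)
        rows.append((ev.event_id, ev.event_class, observed, p, False,
                     abs(observed) >= DPSI_STRICT_CUTOFF,
                     abs(observed) >= DPSI_LENIENT_CUTOFF))
    return pd.DataFrame(
        rows,
        columns=["event_id", "event_class", "delta_psi", "p_perm",
                 "undefined", "pass_strict", "pass_lenient"],
    )


def perms_delta(values: np.ndarray, perms: np.ndarray, n_a: int) -> np.ndarray:
    """Permutation null of the group-mean difference for one event."""
    shuffled = values[perms]                       # B x n
    return shuffled[:, n_a:].mean(axis=1) - shuffled[:, :n_a].mean(axis=1)


@dataclass
class ExonCountTable:
    """Normalized exon counts (samples x exons) with a sample->condition map."""

    counts: pd.DataFrame               # index: sample ids, columns: exon ids
    conditions: pd.Series              # index: sample ids

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.conditions.index):
            raise StructuralError("counts and condition map sample ids differ")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValidationError("normalized counts must be non-negative")


def pooled_exon_usage(
    table: ExonCountTable, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Mean +/- SEM of exon-group-pooled normalized counts per condition.

    Pooling order: mean over member exons within each sample, then mean and
    SEM over the samples of each condition.
    """
    rows = []
    for group_name, exons in groups.items():
        exons = list(exons)
        if not exons:
            raise ConfigurationError(f"exon group {group_name!r} is empty")
        missing = [e for e in exons if e not in table.counts.columns]
        if missing:
            raise CoverageError(f"exons absent from table: {missing}")
        per_sample = table.counts[exons].mean(axis=1)
        for condition in pd.unique(table.conditions):
            vals = per_sample[table.conditions == condition].to_numpy(dtype=float)
            if vals.size < 2:
                raise StructuralError(
                    f"condition {condition!r} needs >= 2 samples for a SEM"
                )
            rows.append((
                condition, group_name, float(vals.mean()),
                float(vals.std(ddof=1) / math.sqrt(vals.size)), int(vals.size),
            ))
    return pd.DataFrame(rows, columns=["condition", "group", "mean", "sem", "n"])


def rank_exon_effects(effects: Mapping[str, float] | pd.Series) -> pd.Series:
    """Ordinal ranks of signed exon effects, most negative first.

    Ties are broken by exon id (ascending), so ranks are unique 1..n.
    """
    series = pd.Series(dict(effects), dtype=float)
    if not np.isfinite(series.to_numpy()).all():
        raise ValidationError("effects must be finite")
    order = sorted(series.index, key=lambda e: (series[e], e))
    return pd.Series({e: i + 1 for i, e in enumerate(order)}, name="rank")
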