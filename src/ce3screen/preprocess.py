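"""Preprocessing of protein-groups tables to an analysis-ready log2 matrix.

The chain is applied strictly in this order, mirroring the quantitative
workflow the screen uses:

1. :func:`filter_identifications` — drop contaminants, reverse-database hits
   and proteins identified by fewer than 2 unique peptides;
2. :func:`subtract_background` — subtract the paired unlabeled-control iBAQ
   value from each guide-arm measurement, clamping negatives to 0;
3. :func:`presence_filter` — keep proteins with positive values in at least
   ``min_present`` replicates of either guide arm (default 3 of 4);
4. :func:`impute_and_log` — replace remaining zeros by half the minimum
   positive value of the same sample column, then log2-transform.

Each step records its retained-row count in a provenance log, and replicate
batches are processed independently, so applying the chain to replicate
subsets and concatenating gives the same result as one joint pass.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError, StructuralError

GUIDE_ARMS = ("gNT", "gAR")
CONTROL_ARM = "control"

_SYNTH_COL = re.compile(r"^iBAQ_(?P<arm>[^_]+)_R(?P<rep>\d+)$")
_MAXQUANT_COL = re.compile(r"^iBAQ[ _](?P<arm>.+?)[ _][Rr]?(?P<rep>\d+)$")

#: MaxQuant proteinGroups column names mapped onto the internal dialect.
_MAXQUANT_META = {
    "Protein IDs": "protein_id",
    "Gene names": "gene_symbol",
    "Unique peptides": "n_unique_peptides",
    "Potential contaminant": "is_contaminant",
    "Reverse": "is_reverse",
}


def intensity_columns(table: pd.DataFrame) -> Dict[Tuple[str, int], str]:
    """Map (arm, replicate) -> column name, auto-detecting the dialect."""
    out: Dict[Tuple[str, int], str] = {}
    for col in table.columns:
        m = _SYNTH_COL.match(col) or _MAXQUANT_COL.match(col)
        if m:
            out[(m.group("arm"), int(m.group("rep")))] = col
    return out


def read_protein_groups(path: str | Path) -> pd.DataFrame:
    """Read a protein-groups TSV in the internal or MaxQuant dialect."""
    table = pd.read_csv(path, sep="\t")
    renames = {src: dst for src, dst in _MAXQUANT_META.items() if src in table.columns}
    table = table.rename(columns=renames)
    for flag in ("is_contaminant", "is_reverse"):
        if flag in table.columns and table[flag].dtype == object:
            table[flag] = table[flag].fillna("").astype(str).str.strip() == "+"
        elif flag not in table.columns:
            table[flag] = False
    if "protein_id" in table.columns:
        # standard protein-groups prefixes also mark contaminants/decoys
        pid = table["protein_id"].astype(str)
        table["is_contaminant"] |= pid.str.startswith("CON__")
        table["is_reverse"] |= pid.str.startswith("REV__")
    return table


def _replicate_indices(table: pd.DataFrame, arm: str) -> List[int]:
    return sorted(rep for (a, rep) in intensity_columns(table) if a == arm)


# ---------------------------------------------------------------------------
# chain steps
# ---------------------------------------------------------------------------

def filter_identifications(table: pd.DataFrame) -> pd.DataFrame:
    """Remove contaminants, reverse hits and <2-unique-peptide identifications."""
    keep = (
        ~table["is_contaminant"].astype(bool)
        & ~table["is_reverse"].astype(bool)
        & (table["n_unique_peptides"] >= 2)
    )
    return table.loc[keep].copy()


def subtract_background(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract the paired unlabeled-control intensity; clamp negatives to 0.

    The control arm is dropped from the output.
    """
    cols = intensity_columns(table)
    out = table.copy()
    for arm in GUIDE_ARMS:
        for rep in _replicate_indices(table, arm):
            if (CONTROL_ARM, rep) not in cols:
                raise StructuralError(
                    f"missing control replicate {rep} paired with {arm}"
                )
            guide = table[cols[(arm, rep)]].to_numpy(dtype=float)
            control = table[cols[(CONTROL_ARM, rep)]].to_numpy(dtype=float)
            out[cols[(arm, rep)]] = np.maximum(0.0, guide - control)
    drop = [cols[key] for key in cols if key[0] == CONTROL_ARM]
    return out.drop(columns=drop)


def default_min_present(n_replicates: int) -> int:
    """The 3-of-4 presence rule generalized as ceil(3n/4)."""
    return math.ceil(3 * n_replicates / 4)


def presence_filter(table: pd.DataFrame, min_present: int | None = None) -> pd.DataFrame:
    """Keep proteins positive in >= min_present replicates of either guide arm."""
    cols = intensity_columns(table)
    reps = {arm: _replicate_indices(table, arm) for arm in GUIDE_ARMS}
    n_replicates = max(len(r) for r in reps.values())
    if min_present is None:
        min_present = default_min_present(n_replicates)
    if min_present > n_replicates:
        raise ConfigurationError(
            f"min_present={min_present} exceeds n_replicates={n_replicates}"
        )
    keep = np.zeros(len(table), dtype=bool)
    for arm in GUIDE_ARMS:
        arm_cols = [cols[(arm, rep)] for rep in reps[arm]]
        positive = (table[arm_cols].to_numpy(dtype=float) > 0).sum(axis=1)
        keep |= positive >= min_present
    return table.loc[keep].copy()


@dataclass
class PreprocessedMatrix:
    """Log2 control-subtracted intensities, replicate-paired across guide arms."""

    data: pd.DataFrame  # index protein_id, columns "<arm>_R<k>"
    n_replicates: int
    provenance: List[dict] = field(default_factory=list)

    @property
    def protein_ids(self) -> List[str]:
        return list(self.data.index)

    def arm_values(self, arm: str) -> np.ndarray:
        cols = [f"{arm}_R{k}" for k in range(1, self.n_replicates + 1)]
        return self.data[cols].to_numpy(dtype=float)

    def paired_differences(self) -> np.ndarray:
        """Per-protein paired log2 differences, gAR_k - gNT_k."""
        return self.arm_values("gAR") - self.arm_values("gNT")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="protein_id")


def impute_and_log(table: pd.DataFrame, pool: str = "column") -> PreprocessedMatrix:
    """Half-minimum imputation of zeros per sample column, then log2.

    ``pool`` selects the imputation pool: ``"column"`` (the default) uses the
    minimum positive value of the same arm x replicate column; ``"replicate"``
    pools both guide arms of the same replicate index.
    """
    if pool not in ("column", "replicate"):
        raise ConfigurationError(f"unknown imputation pool {pool!r}")
    cols = intensity_columns(table)
    reps = sorted({rep for (_, rep) in cols})
    values: Dict[str, np.ndarray] = {}
    imputed_counts: Dict[str, int] = {}
    for arm in GUIDE_ARMS:
        for rep in reps:
            col = cols[(arm, rep)]
            x = table[col].to_numpy(dtype=float).copy()
            if pool == "column":
                pool_vals = x
            else:
                pool_vals = np.concatenate(
                    [table[cols[(a, rep)]].to_numpy(dtype=float) for a in GUIDE_ARMS]
                )
            positive = pool_vals[pool_vals > 0]
            zeros = x <= 0
            if positive.size == 0:
                raise DataError(f"column {col} has no positive values")
            x[zeros] = positive.min() / 2.0
            values[f"{arm}_R{rep}"] = np.log2(x)
            imputed_counts[f"{arm}_R{rep}"] = int(zeros.sum())
    data = pd.DataFrame(values, index=pd.Index(table["protein_id"], name="protein_id"))
    return PreprocessedMatrix(
        data=data,
        n_replicates=len(reps),
        provenance=[{"step": "impute_and_log", "rows": len(data),
                     "imputed": imputed_counts}],
    )


def preprocess_chain(
    table: pd.DataFrame,
    min_present: int | None = None,
    impute_pool: str = "column",
) -> PreprocessedMatrix:
    """Apply the full chain in the fixed order, with provenance."""
    provenance = [{"step": "input", "rows": len(table)}]
    t = filter_identifications(table)
    provenance.append({"step": "filter_identifications", "rows": len(t)})
    t = subtract_background(t)
    provenance.append({"step": "subtract_background", "rows": len(t)})
    t = presence_filter(t, min_present=min_present)
    provenance.append({"step": "presence_filter", "rows": len(t)})
    matrix = impute_and_log(t, pool=impute_pool)
    matrix.provenance = provenance + matrix.provenance
    return matrix
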