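"""Three-stage prioritization of interactor candidates against clinical data.

Stage 1 keeps only candidates annotated as splicing factors; stage 2 keeps
those whose cohort expression correlates positively with the target
transcript's abundance (Pearson r > 0, two-sided p < 0.05 by default);
stage 3 ranks candidates by their mean Pearson correlation with each of
several transcriptional-activity signatures and selects those "strongly"
correlated — in the top quartile of candidates, by default — in at least 2
of the 3 signatures.  The funnel shape |annotated| >= |target-correlated|
>= |selected| holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, CoverageError, StructuralError


@dataclass
class CohortMatrix:
    """Samples x genes expression (FPKM) plus per-sample target abundance (SRPM)."""

    expression: pd.DataFrame          # index: sample ids, columns: genes
    target: pd.Series                 # index: sample ids
    strata: pd.Series | None = None   # optional sample stratum labels

    def __post_init__(self) -> None:
        if len(self.expression) < 3:
            raise StructuralError("cohort needs >= 3 samples")
        if not self.expression.index.equals(self.target.index):
            raise StructuralError("expression and target sample ids differ")
        if self.target.isna().any():
            raise StructuralError("target abundance contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    def to_csv(self, path: str | Path) -> None:
        out = self.expression.copy()
        out["target_SRPM"] = self.target
        if self.strata is not None:
            out["stratum"] = self.strata
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        if "target_SRPM" not in df.columns:
            raise StructuralError("cohort CSV lacks a target_SRPM column")
        target = df.pop("target_SRPM")
        strata = df.pop("stratum") if "stratum" in df.columns else None
        return cls(expression=df, target=target, strata=strata)


def annotate_splicing_candidates(
    candidates: Sequence[str], annotation: Iterable[str]
) -> List[str]:
    """Intersect candidates with a splicing-annotation set, order preserved."""
    ann = set(annotation)
    if not ann:
        raise ConfigurationError("annotation set is empty")
    return [c for c in candidates if c in ann]


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_with_target(
    cohort: CohortMatrix,
    genes: Sequence[str],
    alpha: float = 0.05,
    require_positive: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each gene with the target abundance.

    A gene passes iff r > 0 (when ``require_positive``) and two-sided
    p < alpha.  Zero-variance genes are flagged and never pass.  When the
    cohort carries stratum labels, per-stratum correlations are reported in
    additional ``r_<stratum>`` columns (the pass decision uses all samples).
    """
    missing = [g for g in genes if g not in cohort.expression.columns]
    if missing:
        raise CoverageError(f"genes absent from cohort: {missing[:10]}")
    y = cohort.target.to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = cohort.expression[g].to_numpy(dtype=float)
        r, p = _pearson(x, y)
        zero_var = not np.isfinite(r)
        passes = (not zero_var) and p < alpha and (r > 0 or not require_positive)
        row = {"gene": g, "r_target": r, "p_target": p,
               "zero_variance": zero_var, "passes": bool(passes)}
        if cohort.strata is not None:
            for stratum in sorted(cohort.strata.unique()):
                mask = (cohort.strata == stratum).to_numpy()
                row[f"r_{stratum}"], _ = _pearson(x[mask], y[mask])
        rows.append(row)
    return pd.DataFrame(rows)


def mean_signature_correlation(
    cohort: CohortMatrix, gene: str, signature: Sequence[str]
) -> tuple[float, float]:
    """Mean Pearson r of ``gene`` with the present signature genes.

    Returns (mean r, coverage fraction of the signature found in the cohort).
    """
    present = [s for s in signature if s in cohort.expression.columns]
    if not present:
        raise CoverageError("no signature gene present in the cohort")
    x = cohort.expression[gene].to_numpy(dtype=float)
    rs = [_pearson(x, cohort.expression[s].to_numpy(dtype=float))[0] for s in present]
    return float(np.nanmean(rs)), len(present) / len(signature)


def rank_candidates(
    records: pd.DataFrame,
    signatures: Dict[str, Sequence[str]],
    support_threshold: int = 2,
    strong_quantile: float = 0.75,
) -> pd.DataFrame:
    """Apply the >=2-of-3 signature support rule and rank candidates.

    A candidate "supports" a signature iff its mean r is in the top
    ``1 - strong_quantile`` fraction of candidates for that signature.
    Selected candidates must also pass the target-correlation screen.
    Ranking is by the across-signature mean of mean r, descending; ties are
    broken by r_target descending, then gene id ascending.
    """
    if support_threshold > len(signatures):
        raise ConfigurationError(
            f"support_threshold={support_threshold} exceeds the "
            f"{len(signatures)} available signatures"
        )
    out = records.copy()
    sig_cols = [f"mean_r_{name}" for name in signatures]
    for col in sig_cols:
        if col not in out.columns:
            raise ConfigurationError(f"records lack column {col!r}")
    supported = np.zeros(len(out), dtype=int)
    for col in sig_cols:
        cutoff = np.nanquantile(out[col].to_numpy(dtype=float), strong_quantile)
        supported += (out[col] >= cutoff).to_numpy(dtype=int)
    out["n_signatures_supported"] = supported
    out["mean_r_overall"] = out[sig_cols].mean(axis=1)
    out["selected"] = (supported >= support_threshold) & out["passes"]
    out = out.sort_values(
        by=["mean_r_overall", "r_target", "gene"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class TriageResult:
    records: pd.DataFrame
    funnel: Dict[str, int]

    @property
    def selected(self) -> List[str]:
        return self.records.loc[self.records["selected"], "gene"].tolist()


def triage_pipeline(
    cohort: CohortMatrix,
    candidates: Sequence[str],
    annotation: Iterable[str],
    signatures: Dict[str, Sequence[str]],
    alpha: float = 0.05,
    support_threshold: int = 2,
    strong_quantile: float = 0.75,
) -> TriageResult:
    """Annotation filter -> target correlation -> signature support, in order."""
    annotated = annotate_splicing_candidates(candidates, annotation)
    if not annotated:
        raise CoverageError("no candidate carries the splicing annotation")
    records = correlate_with_target(cohort, annotated, alpha=alpha)
    records["is_splicing_annotated"] = True
    for name, members in signatures.items():
        vals, cov = [], []
        for g in annotated:
            mean_r, coverage = mean_signature_correlation(cohort, g, members)
            vals.append(mean_r)
            cov.append(coverage)
        records[f"mean_r_{name}"] = vals
        records[f"coverage_{name}"] = cov
    ranked = rank_candidates(
        records, signatures,
        support_threshold=support_threshold,
        strong_quantile=strong_quantile,
    )
    funnel = {
        "n_candidates": len(candidates),
        "n_annotated": len(annotated),
        "n_target_correlated": int(ranked["passes"].sum()),
        "n_selected": int(ranked["selected"].sum()),
    }
    return TriageResult(records=ranked, funnel=funnel)
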