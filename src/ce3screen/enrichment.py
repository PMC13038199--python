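"""Paired empirical-Bayes moderated-t enrichment of gAR over gNT.

Per protein, the paired log2 differences ``d_k = log2 gAR_k - log2 gNT_k``
give an effect estimate (the mean), a sample variance ``s^2`` with
``d = n_pairs - 1`` residual degrees of freedom, and a moderated statistic

    s~^2   = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod  = mean / sqrt(s~^2 / n_pairs)

with ``d0 + d`` total degrees of freedom.  The prior ``(d0, s0^2)`` is
estimated by moment-matching the log sample variances against a scaled
log-F distribution (the standard empirical-Bayes scheme for gene-wise
variances): writing ``e_g = log s_g^2 - digamma(d/2) + log(d/2)``, the
estimating equations are

    trigamma(d0/2) = var(e) - trigamma(d/2)
    log s0^2       = mean(e) + digamma(d0/2) - log(d0/2)

with ``d0 = +inf`` (no excess dispersion, s~^2 = s0^2, normal reference
distribution) whenever the empirical variance of e does not exceed the
trigamma floor.

Significance classification follows the screen's published cutoffs: a
protein is a significant interactor iff unadjusted p < 0.05 AND linear fold
enrichment > 1.5 (log2 0.585), positive direction only; significant proteins
split into high- (BH FDR < 0.25) and low-confidence tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from ._errors import ConfigurationError, EstimationError, StructuralError, ValidationError
from .preprocess import PreprocessedMatrix

HIGH_CONFIDENCE = "high_confidence"
LOW_CONFIDENCE = "low_confidence"
NOT_SIGNIFICANT = "not_significant"

_MIN_PROTEINS_FOR_EB = 20


@dataclass(frozen=True)
class ModeratedTestParams:
    """Empirical-Bayes hyperparameters of the moderated t-test."""

    d0: float      # prior degrees of freedom (may be +inf)
    s0_sq: float   # prior variance, squared log2 units
    d: int         # residual df per protein (= n_pairs - 1)

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ConfigurationError("residual df must be >= 1")
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise ConfigurationError("s0_sq must be finite and > 0")
        if self.d0 < 0:
            raise ConfigurationError("d0 must be >= 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_f_dist(s_sq: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0_sq) from sample variances with df d."""
    s_sq = np.asarray(s_sq, dtype=float)
    usable = s_sq[np.isfinite(s_sq) & (s_sq > 0)]
    if usable.size < _MIN_PROTEINS_FOR_EB:
        raise EstimationError(
            f"need >= {_MIN_PROTEINS_FOR_EB} proteins with positive finite "
            f"variance, got {usable.size}"
        )
    z = np.log(usable)
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if float(np.var(z)) < 1e-12:
        # degenerate: identical variances are taken as exactly known
        return math.inf, float(np.exp(np.mean(z)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(
            float(np.mean(e)) + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        # dispersion no larger than chi-square sampling alone: infinite prior
        # df, with the same log-scale bias correction for the location
        d0 = math.inf
        s0_sq = float(np.exp(np.mean(e)))
    return d0, s0_sq


def estimate_eb_params(matrix: PreprocessedMatrix) -> ModeratedTestParams:
    """Estimate the variance prior from the paired differences of a matrix."""
    diffs = matrix.paired_differences()
    if diffs.shape[1] < 2:
        raise StructuralError("need >= 2 replicate pairs")
    d = diffs.shape[1] - 1
    s_sq = np.var(diffs, axis=1, ddof=1)
    d0, s0_sq = fit_f_dist(s_sq, d)
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq, d=d)


def moderated_t_from_stats(
    log2_fc: np.ndarray,
    s_sq: np.ndarray,
    n_pairs: int,
    params: ModeratedTestParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s_tilde_sq, t_mod, two-sided p) from per-protein summary statistics."""
    d0, s0, d = params.d0, params.s0_sq, params.d
    if math.isinf(d0):
        s_tilde = np.full_like(np.asarray(s_sq, dtype=float), s0)
        df_total = math.inf
    else:
        s_tilde = (d0 * s0 + d * np.asarray(s_sq, dtype=float)) / (d0 + d)
        df_total = d0 + d
    t_mod = np.asarray(log2_fc, dtype=float) / np.sqrt(s_tilde / n_pairs)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return s_tilde, t_mod, p


def paired_moderated_t(
    matrix: PreprocessedMatrix, params: ModeratedTestParams
) -> pd.DataFrame:
    """Moderated paired t-test per protein; one row per protein."""
    diffs = matrix.paired_differences()
    n_pairs = diffs.shape[1]
    if n_pairs < 2:
        raise StructuralError("need >= 2 replicate pairs")
    if params.d != n_pairs - 1:
        raise StructuralError(
            f"params fitted for d={params.d} but matrix has {n_pairs - 1}"
        )
    log2_fc = diffs.mean(axis=1)
    s_sq = np.var(diffs, axis=1, ddof=1)
    s_tilde, t_mod, p = moderated_t_from_stats(log2_fc, s_sq, n_pairs, params)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "log2_fc": log2_fc,
            "s_sq": s_sq,
            "s_tilde_sq": s_tilde,
            "t_mod": t_mod,
            "p": p,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_enrichment(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    linear_fc_threshold: float = 1.5,
    fdr_split: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Assign significance and confidence tiers; return (records, summary).

    Interactor calls are one-directional: p < p_threshold AND
    log2_fc > log2(linear_fc_threshold).  Among calls, FDR < fdr_split is
    high confidence.  The summary also reports the two-directional count at
    the same cutoffs (|log2_fc| beyond the threshold in either direction).
    """
    if p_threshold <= 0 or linear_fc_threshold <= 0 or fdr_split <= 0:
        raise ConfigurationError("thresholds must be strictly positive")
    out = records.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    log2_thr = math.log2(linear_fc_threshold)
    significant = (out["p"] < p_threshold) & (out["log2_fc"] > log2_thr)
    confidence = np.where(
        significant,
        np.where(out["fdr"] < fdr_split, HIGH_CONFIDENCE, LOW_CONFIDENCE),
        NOT_SIGNIFICANT,
    )
    out["confidence"] = confidence
    two_sided = (out["p"] < p_threshold) & (np.abs(out["log2_fc"]) > log2_thr)
    summary = {
        "n_proteins": int(len(out)),
        "n_significant": int(significant.sum()),
        "n_high_confidence": int((out["confidence"] == HIGH_CONFIDENCE).sum()),
        "n_low_confidence": int((out["confidence"] == LOW_CONFIDENCE).sum()),
        "n_not_significant": int((out["confidence"] == NOT_SIGNIFICANT).sum()),
        "n_positive_fc": int((out["log2_fc"] > 0).sum()),
        "n_significant_two_sided": int(two_sided.sum()),
    }
    # deterministic ranking for reports: p asc, |log2_fc| desc, id asc
    out = out.sort_values(
        by=["p", "log2_fc", "protein_id"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "log2_fc" else s,
    ).reset_index(drop=True)
    return out, summary


def run_enrichment(
    matrix: PreprocessedMatrix,
    p_threshold: float = 0.05,
    linear_fc_threshold: float = 1.5,
    fdr_split: float = 0.25,
) -> tuple[pd.DataFrame, dict, ModeratedTestParams]:
    """Estimate the prior, test every protein, adjust and classify."""
    params = estimate_eb_params(matrix)
    records = paired_moderated_t(matrix, params)
    records["fdr"] = bh_adjust(records["p"].to_numpy())
    records, summary = classify_enrichment(
        records, p_threshold, linear_fc_threshold, fdr_split
    )
    return records, summary, params
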