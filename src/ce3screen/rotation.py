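"""Self-contained rotation gene-set testing with barcode-rank output.

The paired contrast reduces each protein to a one-sample problem on its
paired log2 differences.  An orthonormal change of basis maps the n-vector
of differences to coordinates ``u`` whose first entry is the scaled effect
(``sqrt(n) * mean``) and whose remaining ``d = n - 1`` entries are
residuals; under the null of no effect and spherical errors, ``u`` is
rotationally symmetric.  A rotation draw is a uniform random unit vector
``r`` in R^(n): the rotated effect is ``r . u`` and the rotated residual
variance is ``(|u|^2 - (r.u)^2)/d``.  The same rotation is applied to every
set member, preserving inter-protein correlation, and the rotation p-value
is ``(b + 1)/(B + 1)`` where ``b`` counts null statistics at least as
extreme as the observed one — hence p can never fall below ``1/(B + 1)``.

Per-protein scores are moderated z-values: the moderated t (using the
empirical-Bayes prior from the enrichment stage) mapped through the t CDF
to a standard normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, CoverageError, StructuralError
from .enrichment import ModeratedTestParams, bh_adjust
from .preprocess import PreprocessedMatrix

SET_STATISTICS = ("mean", "floormean", "msq", "mean50")
ALTERNATIVES = ("up", "down", "either", "mixed")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_members(cls, name: str, members: Sequence[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(members))


def read_gmt(path: str | Path) -> List[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigurationError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet.from_members(fields[0], fields[2:]))
    return sets


@dataclass(frozen=True)
class RotationConfig:
    n_rotations: int = 9999
    set_statistic: str = "msq"
    alternative: str = "up"
    seed: int = 0

    def __post_init__(self):
        if self.n_rotations < 99:
            raise ConfigurationError("n_rotations must be >= 99")
        if self.set_statistic not in SET_STATISTICS:
            raise ConfigurationError(f"unknown set statistic {self.set_statistic!r}")
        if self.alternative not in ALTERNATIVES:
            raise ConfigurationError(f"unknown alternative {self.alternative!r}")


@dataclass
class GeneSetResult:
    name: str
    n_in_universe: int
    observed_stat: float
    p: float
    fdr: float | None = None
    barcode_ranks: List[int] = field(default_factory=list)
    missing_members: List[str] = field(default_factory=list)


def _moderated_z(t: np.ndarray, df_total: float) -> np.ndarray:
    """Map moderated t (df_total df) to standard normal quantiles, tail-stable."""
    if math.isinf(df_total):
        return t
    sf = stats.t.sf(np.abs(t), df_total)
    z = stats.norm.isf(np.clip(sf, np.finfo(float).tiny, 1.0))
    return np.sign(t) * z


def _set_statistic(z: np.ndarray, statistic: str, directional: bool) -> np.ndarray:
    """Set statistic over member scores; z has members on the first axis."""
    if statistic == "mean":
        return z.mean(axis=0) if directional else np.abs(z).mean(axis=0)
    if statistic == "floormean":
        base = z if directional else np.abs(z)
        return np.maximum(base, 0.0).mean(axis=0)
    if statistic == "msq":
        base = np.maximum(z, 0.0) if directional else np.abs(z)
        return (base ** 2).mean(axis=0)
    if statistic == "mean50":
        base = z if directional else np.abs(z)
        m = base.shape[0]
        top = max(1, math.ceil(m / 2))
        return np.sort(base, axis=0)[m - top:, :].mean(axis=0)
    raise ConfigurationError(f"unknown set statistic {statistic!r}")


def _one_sided_p(matrix: PreprocessedMatrix, params: ModeratedTestParams,
                 member_idx: np.ndarray, config: RotationConfig,
                 sign: float, directional: bool,
                 statistic: str) -> tuple[float, float]:
    """Rotation p for one directional reading; returns (observed_stat, p)."""
    diffs = matrix.paired_differences()[member_idx] * sign
    m, n = diffs.shape
    d = n - 1
    d0, s0 = params.d0, params.s0_sq
    df_total = d0 + d

    # orthonormal basis with first column 1/sqrt(n)
    basis = np.linalg.qr(
        np.column_stack([np.full(n, 1.0 / math.sqrt(n)), np.eye(n)[:, : n - 1]])
    )[0]
    if basis[0, 0] < 0:
        basis = -basis
    u = diffs @ basis                       # m x n coordinates
    norms_sq = (u ** 2).sum(axis=1)

    def scores(effect: np.ndarray) -> np.ndarray:
        s_sq = (norms_sq[:, None] - effect ** 2) / d
        s_sq = np.maximum(s_sq, 0.0)
        if math.isinf(d0):
            s_tilde = np.full_like(s_sq, s0)
        else:
            s_tilde = (d0 * s0 + d * s_sq) / (d0 + d)
        t = effect / np.sqrt(s_tilde)
        return _moderated_z(t, df_total)

    observed = float(
        _set_statistic(scores(u[:, :1]), statistic, directional)[0]
    )

    rng = np.random.default_rng(config.seed)
    B = config.n_rotations
    r = rng.standard_normal((B, n))
    r /= np.linalg.norm(r, axis=1, keepdims=True)
    effects = u @ r.T                       # m x B rotated effect coordinates
    null_stats = _set_statistic(scores(effects), statistic, directional)
    b = int(np.sum(null_stats >= observed))
    return observed, (b + 1) / (B + 1)


def roast_test(
    matrix: PreprocessedMatrix,
    params: ModeratedTestParams,
    gene_set: GeneSet,
    config: RotationConfig = RotationConfig(),
) -> GeneSetResult:
    """Rotation test of one gene set against the paired enrichment contrast."""
    ids = matrix.protein_ids
    id_to_idx = {pid: i for i, pid in enumerate(ids)}
    present = sorted(m for m in gene_set.members if m in id_to_idx)
    missing = sorted(m for m in gene_set.members if m not in id_to_idx)
    if len(present) < 2:
        raise CoverageError(
            f"gene set {gene_set.name!r} has {len(present)} measured members "
            f"(need >= 2); missing: {missing[:10]}"
        )
    if matrix.paired_differences().shape[1] < 2:
        raise StructuralError("need >= 2 replicate pairs")
    member_idx = np.array([id_to_idx[m] for m in present])

    alt = config.alternative
    if alt in ("up", "down"):
        sign = 1.0 if alt == "up" else -1.0
        observed, p = _one_sided_p(
            matrix, params, member_idx, config, sign, True, config.set_statistic
        )
    elif alt == "either":
        obs_up, p_up = _one_sided_p(
            matrix, params, member_idx, config, 1.0, True, config.set_statistic
        )
        obs_dn, p_dn = _one_sided_p(
            matrix, params, member_idx, config, -1.0, True, config.set_statistic
        )
        observed = obs_up if p_up <= p_dn else obs_dn
        p = min(1.0, 2.0 * min(p_up, p_dn))
    else:  # mixed: magnitude only
        observed, p = _one_sided_p(
            matrix, params, member_idx, config, 1.0, False, config.set_statistic
        )
    return GeneSetResult(
        name=gene_set.name,
        n_in_universe=len(present),
        observed_stat=observed,
        p=float(p),
        missing_members=missing,
    )


def roast_multi(
    matrix: PreprocessedMatrix,
    params: ModeratedTestParams,
    gene_sets: Sequence[GeneSet],
    config: RotationConfig = RotationConfig(),
    records: pd.DataFrame | None = None,
) -> List[GeneSetResult]:
    """Test several sets, BH-adjust across them, attach barcode ranks."""
    results = [roast_test(matrix, params, gs, config) for gs in gene_sets]
    fdrs = bh_adjust([r.p for r in results])
    for r, fdr in zip(results, fdrs):
        r.fdr = float(fdr)
    if records is not None:
        for r, gs in zip(results, gene_sets):
            r.barcode_ranks = barcode_ranks(records, gs)[0]
    return results


def barcode_ranks(
    records: pd.DataFrame, gene_set: GeneSet
) -> tuple[List[int], List[str]]:
    """1-based positions of set members in the -log10(FDR) ranking.

    The universe is sorted by -log10(fdr) descending (i.e. fdr ascending),
    ties broken by |log2_fc| descending then protein_id ascending.  Members
    absent from the records are reported separately, not ranked.
    """
    if records.empty:
        raise CoverageError("no records to rank")
    ordered = records.sort_values(
        by=["fdr", "log2_fc", "protein_id"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "log2_fc" else s,
    )["protein_id"].tolist()
    positions = {pid: i + 1 for i, pid in enumerate(ordered)}
    ranks = sorted(positions[m] for m in gene_set.members if m in positions)
    missing = sorted(m for m in gene_set.members if m not in positions)
    if not ranks:
        raise CoverageError(f"no member of {gene_set.name!r} present in records")
    return ranks, missing


def barcode_table(records: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    """Barcode export: (rank, member id, -log10 fdr) per present member."""
    ranks, _ = barcode_ranks(records, gene_set)
    ordered = records.sort_values(
        by=["fdr", "log2_fc", "protein_id"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "log2_fc" else s,
    ).reset_index(drop=True)
    rows = []
    for rank in ranks:
        row = ordered.iloc[rank - 1]
        rows.append((rank, row["protein_id"], -math.log10(max(row["fdr"], 1e-300))))
    return pd.DataFrame(rows, columns=["rank", "member", "neg_log10_fdr"])
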