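"""Synthetic-data generators with planted ground truth.

Every pipeline input — protein-level iBAQ quantification tables, a patient
cohort expression matrix with per-sample target-transcript abundance,
annotated transcript sequences, and qPCR Ct tables — can be simulated with
known planted truth, so each downstream stage is testable end to end without
any external data.

The experimental design mirrored by :func:`simulate_ibaq_experiment` is a
proximity-biotinylation proteomics screen with three arms (an unlabeled
control, a non-targeting guide ``gNT`` and a cryptic-exon-targeting guide
``gAR``) measured in paired replicates.  Intensities are log-normal:
each protein has a log2 baseline abundance, arm effects are additive on the
log2 scale, and stochastic dropout zeroes individual measurements.

Cohort correlations are induced through a shared latent factor: the target
transcript abundance is an affine function of the latent, and each planted
gene is ``r * latent + sqrt(1 - r^2) * noise``, which fixes the population
Pearson correlation with the target at exactly ``r``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._errors import ConfigurationError

ARMS = ("control", "gNT", "gAR")

#: fraction of rows flagged as contaminant / reverse / single-peptide, to
#: exercise the identification filters.  These rows are never planted binders.
_CONTAMINANT_FRACTION = 0.02
_REVERSE_FRACTION = 0.02
_SINGLE_PEPTIDE_FRACTION = 0.03

#: planted qPCR fold changes (condition -> linear fold vs the calibrator).
QPCR_PLANTED_FOLDS = {"siScr": 1.0, "siTRA2AB": 0.25}
QPCR_REFERENCE_GENE = "RPL13A"
QPCR_TARGET_GENE = "ARV7"

_MOTIF = "AGAA"
_ESE = "GAAGAA"


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable knobs of the synthetic study, in one frozen record.

    Defaults are the study conditions of the emulated screen: 4 paired
    replicates, 5% planted binders at a log2 effect of 2 over a replicate
    noise sd of 0.5, a 208-sample cohort, 25-gene activity signatures and a
    2.4-fold planted AGAA density on the cryptic exon.
    """

    seed: int = 0
    # proteomics arm
    n_proteins: int = 2000
    n_replicates: int = 4
    planted_binder_fraction: float = 0.05
    planted_log2_effect: float = 2.0
    background_log_mean: float = 23.0
    background_log_sd: float = 0.5
    abundance_log_sd: float = 1.5
    dropout_rate: float = 0.05
    endogenous_biotin_fraction: float = 0.02
    control_log2_offset: float = 3.0
    # cohort arm
    cohort_n_samples: int = 208
    cohort_n_genes: int = 200
    n_correlated_genes: int = 10
    cohort_planted_r: float = 0.6
    signature_size: int = 25
    n_signatures: int = 3
    # transcript arm
    transcript_length: int = 2000
    planted_motif_rate_multiplier: float = 2.4

    def validate(self) -> None:
        for name in ("n_proteins", "n_replicates", "cohort_n_samples",
                     "cohort_n_genes", "signature_size", "n_signatures",
                     "transcript_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("planted_binder_fraction", "dropout_rate",
                     "endogenous_biotin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.background_log_sd <= 0:
            raise ConfigurationError("background_log_sd must be > 0")
        if abs(self.cohort_planted_r) >= 1:
            raise ConfigurationError("cohort_planted_r must lie in (-1, 1)")
        if self.planted_motif_rate_multiplier < 0:
            raise ConfigurationError("planted_motif_rate_multiplier must be >= 0")
        if self.n_correlated_genes > self.cohort_n_genes:
            raise ConfigurationError("n_correlated_genes exceeds cohort_n_genes")


@dataclass
class SyntheticTruth:
    """Bookkeeping of everything that was planted."""

    binder_ids: Set[str] = field(default_factory=set)
    endogenous_biotin_ids: Set[str] = field(default_factory=set)
    correlated_gene_ids: Set[str] = field(default_factory=set)
    driver_gene: str | None = None
    signatures: Dict[str, List[str]] = field(default_factory=dict)
    motif_positions: List[Tuple[str, int]] = field(default_factory=list)
    ese_positions: List[Tuple[str, int]] = field(default_factory=list)
    qpcr_true_folds: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["binder_ids"] = sorted(self.binder_ids)
        payload["endogenous_biotin_ids"] = sorted(self.endogenous_biotin_ids)
        payload["correlated_gene_ids"] = sorted(self.correlated_gene_ids)
        payload["motif_positions"] = [list(t) for t in self.motif_positions]
        payload["ese_positions"] = [list(t) for t in self.ese_positions]
        Path(path).write_text(json.dumps(payload, indent=2))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one independent stream per generator, both derived from the config seed
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# iBAQ proteomics experiment
# ---------------------------------------------------------------------------

def intensity_column(arm: str, replicate: int) -> str:
    return f"iBAQ_{arm}_R{replicate}"


def simulate_ibaq_experiment(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a 3-arm x n-replicate protein-groups table.

    Planted binders carry an expected gAR/gNT log2 ratio of
    ``planted_log2_effect``; endogenous-biotin proteins are elevated in all
    arms including the unlabeled control (so control subtraction removes
    them); all other proteins have a true ratio of 0.  Dropout zeroes each
    (protein, sample) measurement independently.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    gene_symbols = [f"GENE{i:05d}" for i in range(n)]

    n_con = int(round(_CONTAMINANT_FRACTION * n))
    n_rev = int(round(_REVERSE_FRACTION * n))
    n_single = int(round(_SINGLE_PEPTIDE_FRACTION * n))
    flagged = rng.choice(n, size=min(n_con + n_rev + n_single, n), replace=False)
    con_idx = set(flagged[:n_con].tolist())
    rev_idx = set(flagged[n_con:n_con + n_rev].tolist())
    single_idx = set(flagged[n_con + n_rev:].tolist())

    clean = np.array(sorted(set(range(n)) - con_idx - rev_idx - single_idx))
    n_binders = int(round(config.planted_binder_fraction * n))
    n_endo = int(round(config.endogenous_biotin_fraction * n))
    picked = rng.choice(clean, size=min(n_binders + n_endo, clean.size), replace=False)
    binder_idx = picked[:n_binders]
    endo_idx = picked[n_binders:n_binders + n_endo]

    baseline = rng.normal(config.background_log_mean, config.abundance_log_sd, size=n)
    effect = np.zeros(n)
    effect[binder_idx] = config.planted_log2_effect
    is_endo = np.zeros(n, dtype=bool)
    is_endo[endo_idx] = True

    cols: Dict[str, np.ndarray] = {}
    for arm in ARMS:
        for k in range(1, config.n_replicates + 1):
            mu = baseline.copy()
            if arm == "gAR":
                mu = mu + effect
            if arm == "control":
                # unlabeled control: only endogenously biotinylated proteins
                # are recovered at full level
                mu = np.where(is_endo, mu, mu - config.control_log2_offset)
            log2 = mu + rng.normal(0.0, config.background_log_sd, size=n)
            linear = np.exp2(log2)
            dropped = rng.random(n) < config.dropout_rate
            linear[dropped] = 0.0
            cols[intensity_column(arm, k)] = linear

    peptides = rng.integers(2, 30, size=n)
    peptides[list(single_idx)] = 1
    table = pd.DataFrame({
        "protein_id": protein_ids,
        "gene_symbol": gene_symbols,
        "n_unique_peptides": peptides,
        "is_contaminant": [i in con_idx for i in range(n)],
        "is_reverse": [i in rev_idx for i in range(n)],
        **cols,
    })
    truth = SyntheticTruth(
        binder_ids={protein_ids[i] for i in binder_idx},
        endogenous_biotin_ids={protein_ids[i] for i in endo_idx},
    )
    return table, truth


# ---------------------------------------------------------------------------
# patient cohort expression matrix
# ---------------------------------------------------------------------------

def simulate_cohort_expression(
    config: SimulationConfig,
) -> Tuple["CohortMatrix", SyntheticTruth]:
    """Simulate a samples x genes FPKM matrix plus target-transcript SRPM.

    A shared standard-normal latent factor drives the target abundance and
    every planted gene, so the population Pearson correlation of each planted
    gene with the target is exactly ``cohort_planted_r``.  The first planted
    gene is recorded as the driver for recovery experiments.  Three activity
    signatures are generated the same way.  Samples carry a two-level
    treatment stratum label emulating exposure status.
    """
    from .triage import CohortMatrix  # local import to avoid a cycle

    config.validate()
    if config.cohort_n_samples < 3:
        raise ConfigurationError("cohort_n_samples must be >= 3")
    rng = _rng(config, 2)
    n_s = config.cohort_n_samples
    r = config.cohort_planted_r
    latent = rng.normal(size=n_s)

    sample_ids = [f"S{i:04d}" for i in range(n_s)]
    target = 50.0 + 10.0 * latent
    np.clip(target, 0.0, None, out=target)

    def planted(n_genes: int) -> np.ndarray:
        noise = rng.normal(size=(n_s, n_genes))
        scores = r * latent[:, None] + math.sqrt(max(0.0, 1 - r * r)) * noise
        return 30.0 + 6.0 * scores

    genes: Dict[str, np.ndarray] = {}
    corr_names = [f"CORR{i:03d}" for i in range(config.n_correlated_genes)]
    corr_vals = planted(config.n_correlated_genes)
    for j, g in enumerate(corr_names):
        genes[g] = corr_vals[:, j]
    n_bg = config.cohort_n_genes - config.n_correlated_genes
    bg_names = [f"BG{i:04d}" for i in range(n_bg)]
    bg_vals = 30.0 + 6.0 * rng.normal(size=(n_s, n_bg))
    for j, g in enumerate(bg_names):
        genes[g] = bg_vals[:, j]

    signatures: Dict[str, List[str]] = {}
    for s in range(1, config.n_signatures + 1):
        names = [f"SIG{s}_G{i:03d}" for i in range(config.signature_size)]
        vals = planted(config.signature_size)
        for j, g in enumerate(names):
            genes[g] = vals[:, j]
        signatures[f"ARV7_SIG{s}"] = names

    expression = pd.DataFrame(genes, index=sample_ids).clip(lower=0.0)
    strata = pd.Series(
        np.where(np.arange(n_s) < n_s // 2, "naive", "exposed"),
        index=sample_ids, name="stratum",
    )
    cohort = CohortMatrix(
        expression=expression,
        target=pd.Series(target, index=sample_ids, name="target_SRPM"),
        strata=strata,
    )
    truth = SyntheticTruth(
        correlated_gene_ids=set(corr_names),
        driver_gene=corr_names[0] if corr_names else None,
        signatures=signatures,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# transcript sequences with planted motif density
# ---------------------------------------------------------------------------

def _plant_motifs(seq: List[str], start: int, end: int, n_extra: int,
                  rng: np.random.Generator, taken: Set[int]) -> List[int]:
    """Overwrite ``n_extra`` random non-overlapping windows with the tetramer."""
    placed: List[int] = []
    k = len(_MOTIF)
    candidates = np.arange(start, end - k + 1)
    rng.shuffle(candidates)
    for pos in candidates:
        if len(placed) == n_extra:
            break
        if any(p in taken for p in range(pos - k + 1, pos + k)):
            continue
        seq[pos:pos + k] = list(_MOTIF)
        taken.update(range(pos, pos + k))
        placed.append(int(pos))
    return placed


def _thin_motifs(seq: List[str], start: int, end: int, keep_prob: float,
                 rng: np.random.Generator) -> None:
    """Destroy background tetramer occurrences with probability 1 - keep_prob."""
    s = "".join(seq[start:end])
    pos = s.find(_MOTIF)
    while pos != -1:
        if rng.random() > keep_prob:
            seq[start + pos + 2] = rng.choice(["C", "T"])
        pos = s.find(_MOTIF, pos + 1)


def simulate_transcript_sequences(
    config: SimulationConfig,
) -> Tuple[List["AnnotatedTranscript"], SyntheticTruth]:
    """Simulate one annotated transcript with planted enhancer-motif density.

    The sequence is uniform over {A,C,G,T}; within the CE3 and 3'-UTR
    features the AGAA window rate is raised to ``multiplier / 256`` by
    planting extra tetramers (one of which, in CE3, is realized as the
    GAAGAA hexameric splicing enhancer whenever multiplier > 1), or lowered
    by thinning background occurrences when multiplier < 1.  The number of
    extra plants is floor+Bernoulli so the expected planted count is exact.
    """
    from .motifs import AnnotatedTranscript  # local import to avoid a cycle

    config.validate()
    L = config.transcript_length
    if L < 100:
        raise ConfigurationError("transcript_length must be >= 100")
    mult = config.planted_motif_rate_multiplier
    rng = _rng(config, 3)

    seq = list(rng.choice(list("ACGT"), size=L))
    ce3 = (int(0.70 * L), int(0.85 * L))
    utr3 = (int(0.85 * L), L)
    tid = "SYNTH_ARV7"
    truth = SyntheticTruth()

    if mult < 1.0:
        for (a, b) in (ce3, utr3):
            _thin_motifs(seq, a, b, keep_prob=mult, rng=rng)
    elif mult > 1.0:
        taken: Set[int] = set()
        for region_i, (a, b) in enumerate((ce3, utr3)):
            windows = (b - a) - len(_MOTIF) + 1
            target_extra = (mult - 1.0) * windows / 256.0
            if region_i == 0:
                # the hexamer carries exactly one embedded tetramer window
                ese_pos = int(rng.integers(a, b - len(_ESE) + 1))
                seq[ese_pos:ese_pos + len(_ESE)] = list(_ESE)
                taken.update(range(ese_pos, ese_pos + len(_ESE)))
                truth.ese_positions.append((tid, ese_pos))
                target_extra = max(0.0, target_extra - 1.0)
            n_extra = int(math.floor(target_extra))
            if rng.random() < (target_extra - n_extra):
                n_extra += 1
            placed = _plant_motifs(seq, a, b, n_extra, rng, taken)
            truth.motif_positions.extend((tid, p) for p in placed)

    transcript = AnnotatedTranscript(
        id=tid,
        sequence="".join(seq),
        features={"CE3": ce3, "UTR3": utr3},
    )
    return [transcript], truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_qpcr_table(
    config: SimulationConfig,
    planted_folds: Dict[str, float] | None = None,
    ct_noise_sd: float = 0.12,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a long-format Ct table with known fold changes.

    The first condition in ``planted_folds`` is the calibrator (fold 1 by
    convention); the target gene's Ct in each other condition is shifted by
    ``-log2(fold)`` cycles relative to it.
    """
    config.validate()
    folds = dict(planted_folds or QPCR_PLANTED_FOLDS)
    rng = _rng(config, 4)
    rows = []
    for condition, fold in folds.items():
        if fold <= 0:
            raise ConfigurationError("planted folds must be strictly positive")
        for rep in range(1, config.n_replicates + 1):
            ct_ref = 18.0 + rng.normal(0.0, ct_noise_sd)
            ct_tgt = 24.0 - math.log2(fold) + rng.normal(0.0, ct_noise_sd)
            rows.append((QPCR_REFERENCE_GENE, condition, rep, ct_ref))
            rows.append((QPCR_TARGET_GENE, condition, rep, ct_tgt))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "Ct"])
    truth = SyntheticTruth(qpcr_true_folds=folds)
    return table, truth


# ---------------------------------------------------------------------------
# writers (plain-text interchange formats)
# ---------------------------------------------------------------------------

def write_protein_groups(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_transcripts(transcripts: Sequence["AnnotatedTranscript"],
                      fasta_path: str | Path, bed_path: str | Path) -> None:
    from .motifs import write_fasta, write_bed
    write_fasta(transcripts, fasta_path)
    write_bed(transcripts, bed_path)


def write_gmt(signatures: Dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in signatures.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
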