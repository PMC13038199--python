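"""Splicing-enhancer k-mer scanning over annotated transcript features.

A motif of length k has 4^-k expected frequency per window under uniform
base composition — for a tetramer such as the TRA2-binding AGAA, once every
256 positions.  Fold enrichment of a region is the observed overlapping
occurrence rate per window, ``c / (L - k + 1)``, divided by that
expectation; folds above 1.5 have been used in the field to call binding
regions, and the cryptic exon plus 3'-UTR of the AR-V7 transcript shows a
2.4-fold elevation.  Occurrences are counted overlapping, since e.g. the
GAAGAA splicing enhancer embeds AGAA in a distinct binding register.

Multi-feature regions (e.g. ``CE3`` union ``UTR3``) are scored on the
concatenated subsequences with junction windows excluded, so no spurious
occurrence spanning two features is ever counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import RegionError, ValidationError

ALPHABET = frozenset("ACGT")
DEFAULT_MOTIF = "AGAA"
DEFAULT_ESE = "GAAGAA"
SELECTION_FOLD_THRESHOLD = 1.5


@dataclass(frozen=True)
class AnnotatedTranscript:
    """A transcript sequence plus named 0-based half-open feature intervals."""

    id: str
    sequence: str
    features: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        for name, (start, end) in self.features.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValidationError(
                    f"feature {name!r} interval [{start}, {end}) outside "
                    f"[0, {len(self.sequence)})"
                )

    def region_sequences(self, region: str | Sequence[str]) -> List[str]:
        """Subsequences of one feature, a list/comma-join of features, or 'full'."""
        if isinstance(region, str):
            names = [r.strip() for r in region.split(",")] if region != "full" else ["full"]
        else:
            names = list(region)
        if names == ["full"]:
            return [self.sequence]
        segments = []
        for name in names:
            if name not in self.features:
                raise RegionError(f"feature {name!r} not annotated on {self.id}")
            start, end = self.features[name]
            segments.append(self.sequence[start:end])
        return segments


def _validate_sequence(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in ALPHABET:
            raise ValidationError(f"invalid character {base!r} at position {i}")


def normalize_rna(sequence: str) -> str:
    """Uppercase and map U -> T (mRNA read as DNA alphabet, sense strand)."""
    return sequence.upper().replace("U", "T")


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_bed(path: str | Path) -> Dict[str, Dict[str, Tuple[int, int]]]:
    """BED4 (chrom, start, end, name), 0-based half-open."""
    features: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValidationError(f"BED line needs 4 fields: {line[:60]!r}")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        features.setdefault(chrom, {})[name] = (start, end)
    return features


def read_transcripts(fasta_path: str | Path, bed_path: str | Path) -> List[AnnotatedTranscript]:
    sequences = read_fasta(fasta_path)
    features = read_bed(bed_path)
    return [
        AnnotatedTranscript(id=tid, sequence=seq, features=features.get(tid, {}))
        for tid, seq in sequences.items()
    ]


def write_fasta(transcripts: Sequence[AnnotatedTranscript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(transcripts: Sequence[AnnotatedTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for name, (start, end) in sorted(t.features.items(), key=lambda kv: kv[1]):
                fh.write(f"{t.id}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def count_motif_overlapping(sequence: str, motif: str) -> int:
    """Number of (overlapping) start positions of ``motif`` in ``sequence``."""
    _validate_sequence(sequence)
    _validate_sequence(motif)
    if len(motif) > len(sequence):
        raise ValidationError("motif longer than sequence")
    count = 0
    pos = sequence.find(motif)
    while pos != -1:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count


def find_ese(sequence: str, hexamer: str = DEFAULT_ESE) -> List[int]:
    """Sorted 0-based start positions of the splicing-enhancer hexamer."""
    _validate_sequence(sequence)
    _validate_sequence(hexamer)
    positions = []
    pos = sequence.find(hexamer)
    while pos != -1:
        positions.append(pos)
        pos = sequence.find(hexamer, pos + 1)
    return positions


@dataclass(frozen=True)
class MotifReport:
    motif: str
    region: str
    region_length: int
    window_count: int
    observed_count: int
    observed_rate: float
    expected_rate: float
    fold: float
    exceeds_selection_threshold: bool


def _expected_rate_uniform(k: int) -> float:
    return 4.0 ** (-k)


def _expected_rate_composition(segments: Sequence[str], motif: str) -> float:
    pooled = "".join(segments)
    freqs = {b: pooled.count(b) / len(pooled) for b in ALPHABET}
    rate = 1.0
    for base in motif:
        rate *= freqs[base]
    return rate


def motif_fold_enrichment(
    transcript: AnnotatedTranscript,
    region: str | Sequence[str],
    motif: str = DEFAULT_MOTIF,
    composition_adjusted: bool = False,
    selection_threshold: float = SELECTION_FOLD_THRESHOLD,
) -> MotifReport:
    """Observed-over-expected motif rate for a feature (or union of features).

    The default expectation is the uniform-composition baseline 4^-k (1/256
    for a tetramer); ``composition_adjusted=True`` instead uses the region's
    observed mononucleotide frequencies.
    """
    k = len(motif)
    segments = transcript.region_sequences(region)
    region_name = region if isinstance(region, str) else ",".join(region)
    for seg in segments:
        if len(seg) < k:
            raise RegionError(
                f"region {region_name!r} segment shorter than motif ({len(seg)} < {k})"
            )
    observed = sum(count_motif_overlapping(seg, motif) for seg in segments)
    windows = sum(len(seg) - k + 1 for seg in segments)
    length = sum(len(seg) for seg in segments)
    observed_rate = observed / windows
    expected = (
        _expected_rate_composition(segments, motif)
        if composition_adjusted
        else _expected_rate_uniform(k)
    )
    fold = observed_rate / expected
    return MotifReport(
        motif=motif,
        region=region_name,
        region_length=length,
        window_count=windows,
        observed_count=observed,
        observed_rate=observed_rate,
        expected_rate=expected,
        fold=fold,
        exceeds_selection_threshold=fold > selection_threshold,
    )


def occurrence_track(
    transcript: AnnotatedTranscript, motif: str = DEFAULT_MOTIF
) -> List[Tuple[str, int, int, str]]:
    """BED-style rows (id, start, end, motif) for every overlapping occurrence."""
    rows = []
    pos = transcript.sequence.find(motif)
    while pos != -1:
        rows.append((transcript.id, pos, pos + len(motif), motif))
        pos = transcript.sequence.find(motif, pos + 1)
    return rows
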