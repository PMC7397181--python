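"""Core data model shared by every stage of the pipeline.

All coordinates are 0-based half-open after parsing; conversion to/from the
1-based closed GTF convention happens only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FRACTIONS = ("cytoplasm", "nucleus")
EVENT_KINDS = ("A3", "A5", "AF", "AL", "MX", "RI", "SE")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(genome: Mapping[str, str], chrom: str, start: int, end: int,
                     strand: str = "+") -> str:
    """Strand-aware sequence extraction (0-based half-open genomic interval).

    Minus-strand intervals are reverse-complemented so callers always see the
    transcribed strand.
    """
    seq = genome[chrom][start:end]
    return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a single transcript variant.

    exons are (start, end) 0-based half-open genomic intervals, sorted by
    start and non-overlapping. Introns are the gaps between consecutive
    exons; a mono-exonic transcript has none.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) has end <= start")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted")
            prev_end = e
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    # junction == intron boundary pair; kept as an alias for readability in
    # the event-classification code.
    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return self.introns

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def group_by_gene(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    for tx in genes.values():
        tx.sort(key=lambda t: t.transcript_id)
    return genes


@dataclass
class ExpressionTable:
    """Transcript x sample TPM matrix with fraction/replicate sample labels.

    values: DataFrame indexed by transcript_id, columns are sample ids.
    meta:   DataFrame indexed by sample_id with columns 'fraction' and
            'replicate'.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression table contains negative TPM values")
        missing = [c for c in self.values.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        bad = set(self.meta["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fractions in metadata: {sorted(bad)}")
        for fr in FRACTIONS:
            if len(self.samples(fr)) < 1:
                raise ValueError(f"no replicates for fraction {fr!r}")

    def samples(self, fraction: str) -> list[str]:
        keep = self.meta.index[self.meta["fraction"] == fraction]
        return [c for c in self.values.columns if c in set(keep)]

    def n_replicates(self, fraction: str) -> int:
        return len(self.samples(fraction))

    def fraction_values(self, fraction: str) -> pd.DataFrame:
        return self.values[self.samples(fraction)]

    def fraction_mean(self, fraction: str) -> pd.Series:
        return self.fraction_values(fraction).mean(axis=1)

    def swap_fractions(self) -> "ExpressionTable":
        """Relabel cytoplasm<->nucleus (used by antisymmetry checks)."""
        meta = self.meta.copy()
        meta["fraction"] = meta["fraction"].map(
            {"cytoplasm": "nucleus", "nucleus": "cytoplasm"})
        return ExpressionTable(self.values.copy(), meta)


@dataclass
class RepeatAnnotation:
    """Repeat intervals in BED convention (0-based half-open) with a class
    label drawn from the controlled vocabulary."""

    intervals: pd.DataFrame  # columns: chrom, start, end, repeat_class

    def __post_init__(self):
        df = self.intervals
        required = ["chrom", "start", "end", "repeat_class"]
        if list(df.columns[:4]) != required:
            df = df.rename(columns=dict(zip(df.columns[:4], required)))
            self.intervals = df
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"repeat interval with start >= end: "
                             f"{bad['chrom']}:{bad['start']}-{bad['end']}")
        unknown = set(df["repeat_class"]) - set(REPEAT_CLASSES)
        if unknown:
            raise ValueError(f"unknown repeat classes: {sorted(unknown)}")

    def by_class(self) -> dict[str, pd.DataFrame]:
        return {c: g for c, g in self.intervals.groupby("repeat_class")}


RNA_ALPHABET = "ACGU"


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over the RNA alphabet (A, C, G, U).

    matrix has one row per motif position; each row sums to 1.
    """

    motif_id: str
    rbp_name: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError(f"PWM {self.motif_id}: length must be >= 4")
        if (m < 0).any():
            raise ValueError(f"PWM {self.motif_id}: negative probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_ALPHABET[i] for i in self.matrix.argmax(axis=1))
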