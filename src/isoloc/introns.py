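"""Characterization of retained-intron sets: splice-boundary composition,
length, mean stem probability, and dinucleotide enrichment.

The comparisons mirror the nuclear-RI analysis: nuclear RIs (retained
introns with ΔΨ < 0 and p < alpha) are compared against the all-RI
background on each feature.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as ist
from .models import TranscriptModel, extract_sequence
from .structure import DEFAULT_PAIR_WEIGHT, stem_probabilities

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class IntronProfile:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # transcribed strand, DNA alphabet
    mean_stem_probability: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dinucleotide_counts(self) -> np.ndarray:
        return _dinuc_counts(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / max(1, len(s))


def _dinuc_counts(seq: str) -> np.ndarray:
    counts = np.zeros(16)
    for i in range(len(seq) - 1):
        a = _BASE_IDX.get(seq[i])
        b = _BASE_IDX.get(seq[i + 1])
        if a is not None and b is not None:
            counts[a * 4 + b] += 1
    return counts


def ri_intron_intervals(psi_subset: pd.DataFrame,
                        events_by_id: Mapping[str, "SpliceEvent"]
                        ) -> list[tuple[str, int, int, str]]:
    """Genomic (chrom, start, end, strand) intervals of RI events in a
    ΔΨ-result subset."""
    out = []
    for eid in psi_subset["event_id"]:
        ev = events_by_id[eid]
        s, e = ev.coords
        out.append((ev.chrom, s, e, ev.strand))
    return out


def profile_introns(introns: Sequence[tuple[str, int, int, str]],
                    genome: Mapping[str, str],
                    structure_max_len: int = 400,
                    pair_weight: float = DEFAULT_PAIR_WEIGHT) -> list[IntronProfile]:
    """Build IntronProfiles (sequence on the transcribed strand, mean stem
    probability on a centered window of ``structure_max_len``)."""
    profiles = []
    for chrom, s, e, strand in introns:
        seq = extract_sequence(genome, chrom, s, e, strand)
        _, mean_p = stem_probabilities(seq.replace("T", "U"),
                                       pair_weight=pair_weight,
                                       max_len=structure_max_len)
        profiles.append(IntronProfile(chrom, s, e, strand, seq, mean_p))
    return profiles


def profiles_table(profiles: Sequence[IntronProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.chrom, p.start, p.end, p.strand, p.length, p.gc,
          p.mean_stem_probability) for p in profiles],
        columns=["chrom", "start", "end", "strand", "length", "gc",
                 "mean_stem_probability"])


# --- splice-site boundary matrices -------------------------------------

def boundary_matrices(introns: Sequence[tuple[str, int, int, str]],
                      genome: Mapping[str, str],
                      donor_window: tuple[int, int] = (3, 9),
                      acceptor_window: tuple[int, int] = (9, 3)
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-position base-frequency matrices of the donor (exon|intron) and
    acceptor (intron|exon) boundary windows, on the transcribed strand.

    donor_window = (exonic, intronic) nt; acceptor_window = (intronic,
    exonic) nt. Introns shorter than the combined intronic windows are
    excluded; the count of exclusions is returned.
    """
    dl = sum(donor_window)
    al = sum(acceptor_window)
    donor = np.zeros((dl, 4))
    acceptor = np.zeros((al, 4))
    excluded = 0
    for chrom, s, e, strand in introns:
        if e - s < donor_window[1] + acceptor_window[0]:
            excluded += 1
            continue
        if strand == "+":
            dseq = genome[chrom][s - donor_window[0]:s + donor_window[1]]
            aseq = genome[chrom][e - acceptor_window[0]:e + acceptor_window[1]]
        else:
            dseq = extract_sequence(genome, chrom, e - donor_window[1],
                                    e + donor_window[0], "-")
            aseq = extract_sequence(genome, chrom, s - acceptor_window[1],
                                    s + acceptor_window[0], "-")
        for mat, seq in ((donor, dseq), (acceptor, aseq)):
            for i, c in enumerate(seq):
                j = _BASE_IDX.get(c)
                if j is not None:
                    mat[i, j] += 1
    donor /= np.maximum(donor.sum(axis=1, keepdims=True), 1)
    acceptor /= np.maximum(acceptor.sum(axis=1, keepdims=True), 1)
    return donor, acceptor, excluded


def tv_distance(mat_a: np.ndarray, mat_b: np.ndarray) -> np.ndarray:
    """Per-position total-variation distance between two frequency
    matrices."""
    return 0.5 * np.abs(mat_a - mat_b).sum(axis=1)


# --- feature comparisons ------------------------------------------------

def compare_feature(nuclear: pd.DataFrame, background: pd.DataFrame,
                    feature: str) -> ist.TestResult:
    """Welch two-tailed t-test of a feature between the nuclear-RI set and
    the all-RI background; intron length is compared on log10 scale
    (lengths are heavy-tailed)."""
    if feature not in ("length", "mean_stem_probability"):
        raise ValueError(f"unsupported feature {feature!r}")
    x = nuclear[feature].to_numpy(dtype=float)
    y = background[feature].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 introns in each set")
    if feature == "length":
        x, y = np.log10(x), np.log10(y)
    res = ist.welch_t_test(x, y)
    res.effect["feature"] = feature
    res.effect["scale"] = "log10" if feature == "length" else "linear"
    return res


def dinucleotide_enrichment(target: Sequence[IntronProfile],
                            background: Sequence[IntronProfile]) -> pd.Series:
    """Normalized dinucleotide frequencies: for each of the 16
    dinucleotides, freq_target / freq_background with frequencies computed
    over the concatenated counts of each set (not per-intron means). A
    ratio of 1 means no preference; ratios with a zero background frequency
    are reported missing (NaN)."""
    if not len(target) or not len(background):
        raise ValueError("both intron sets must be non-empty")
    ct = np.sum([p.dinucleotide_counts for p in target], axis=0)
    cb = np.sum([p.dinucleotide_counts for p in background], axis=0)
    ft = ct / ct.sum()
    fb = cb / cb.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fb > 0, ft / fb, np.nan)
    return pd.Series(ratio, index=DINUCLEOTIDES, name="normalized_frequency")
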