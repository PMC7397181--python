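"""PWM motif scanning on intron sequences and repeat-class overlap
enrichment, each with permutation significance.

Scanning uses log-odds scores against a uniform background on the sense
(transcribed) strand only — the binding substrate is RNA. The hit
threshold is the exact upper-quantile of the PWM's score distribution over
all k-mers, computed by dynamic programming over positions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as ist
from .models import PWM, RepeatAnnotation

_RNA_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    intron_id: str
    position: int  # 0-based on the sense strand
    score: float


def _log_odds(pwm: PWM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(pwm.matrix / 0.25)


def score_distribution(pwm: PWM, decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score of a uniform random k-mer.

    Dynamic programming over positions, merging equal partial sums (rounded
    to ``decimals``); returns (scores, probabilities) sorted ascending.
    -inf scores (zero-probability PWM cells) are kept as an atom.
    """
    lo = _log_odds(pwm)
    dist = {0.0: 1.0}
    for row in lo:
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for v in row:
                key = round(s + v, decimals) if np.isfinite(s + v) else -np.inf
                nxt[key] = nxt.get(key, 0.0) + p * 0.25
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def score_threshold(pwm: PWM, threshold_quantile: float = 0.95) -> float:
    """Smallest achieved score whose upper-tail probability is at most
    1 - threshold_quantile (so the chance hit rate per position never
    exceeds 1 - quantile)."""
    scores, probs = score_distribution(pwm)
    tail = np.cumsum(probs[::-1])[::-1]  # P(S >= scores[i])
    ok = np.isfinite(scores) & (tail <= 1 - threshold_quantile + 1e-12)
    if not ok.any():
        return np.inf
    return float(scores[ok].min())


def scan_pwm(pwm: PWM, sequence: str, threshold_quantile: float = 0.95,
             intron_id: str = "", threshold: float | None = None) -> list[MotifHit]:
    """Hits of one PWM on one sense-strand RNA sequence."""
    k = len(pwm)
    idx = np.array([_RNA_IDX[c] for c in sequence.upper()], dtype=np.int64) \
        if sequence else np.empty(0, dtype=np.int64)
    n = idx.size
    if n < k:
        return []
    if threshold is None:
        threshold = score_threshold(pwm, threshold_quantile)
    lo = _log_odds(pwm)
    scores = np.zeros(n - k + 1)
    for j in range(k):
        scores += lo[j, idx[j:j + n - k + 1]]
    hits = np.flatnonzero(scores >= threshold)
    return [MotifHit(pwm.motif_id, intron_id, int(p), float(scores[p]))
            for p in hits]


def _hit_counts(pwm: PWM, seqs: Sequence[str], threshold: float) -> np.ndarray:
    return np.array([len(scan_pwm(pwm, s, threshold=threshold)) for s in seqs])


def rbp_enrichment(pwms: Sequence[PWM], target_seqs: Sequence[str],
                   background_seqs: Sequence[str], n_shuffles: int = 1000,
                   seed: int = 0, threshold_quantile: float = 0.95) -> pd.DataFrame:
    """Motif-density (hits/kb) enrichment of a target intron set over a
    background set.

    Significance by permutation: introns are reassigned to the two sets
    preserving set sizes, n_shuffles times; the two-sided p-value compares
    |density difference|. q-values are BH-adjusted across motifs.
    """
    if not len(target_seqs) or not len(background_seqs):
        raise ValueError("both intron sets must be non-empty")
    rng = np.random.default_rng(seed)
    nt, nb = len(target_seqs), len(background_seqs)
    lens = np.array([len(s) for s in list(target_seqs) + list(background_seqs)],
                    dtype=float)
    perm = np.array([rng.permutation(nt + nb) for _ in range(n_shuffles)])
    rows = []
    for pwm in pwms:
        thr = score_threshold(pwm, threshold_quantile)
        counts = np.concatenate([
            _hit_counts(pwm, target_seqs, thr),
            _hit_counts(pwm, background_seqs, thr)]).astype(float)
        # density per scannable position (L - k + 1), so intron sets of
        # different length distributions compare without edge bias
        eff = np.maximum(lens - (len(pwm) - 1), 0.0)
        dt = counts[:nt].sum() / (eff[:nt].sum() / 1e3)
        db = counts[nt:].sum() / (eff[nt:].sum() / 1e3)
        obs = dt - db
        pc = counts[perm]
        pl = eff[perm]
        pdt = pc[:, :nt].sum(axis=1) / (pl[:, :nt].sum(axis=1) / 1e3)
        pdb = pc[:, nt:].sum(axis=1) / (pl[:, nt:].sum(axis=1) / 1e3)
        p = (1.0 + (np.abs(pdt - pdb) >= abs(obs)).sum()) / (1.0 + n_shuffles)
        ratio = dt / db if db > 0 else np.nan
        rows.append((pwm.motif_id, pwm.rbp_name, dt, db, ratio, p))
    df = pd.DataFrame(rows, columns=["motif_id", "rbp_name", "density_target",
                                     "density_background", "ratio", "p_value"])
    df["q_value"] = ist.bh_fdr(df["p_value"].to_numpy())
    return df


# --- repeat overlap -----------------------------------------------------

def overlap_bases(intron: tuple[str, int, int], intervals: pd.DataFrame) -> int:
    """Total bases of ``intervals`` (chrom/start/end rows) overlapping one
    intron; exact interval arithmetic."""
    chrom, s, e = intron[0], intron[1], intron[2]
    sub = intervals[intervals["chrom"] == chrom]
    if sub.empty:
        return 0
    ov = (np.minimum(sub["end"].to_numpy(), e)
          - np.maximum(sub["start"].to_numpy(), s))
    return int(np.clip(ov, 0, None).sum())


def repeat_enrichment(repeats: RepeatAnnotation,
                      target_introns: Sequence[tuple],
                      background_introns: Sequence[tuple],
                      n_shuffles: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per repeat-class enrichment of the overlapped-base fraction in a
    target intron set over a background set, with permutation p-values and
    BH q-values (same label-permutation scheme as the motif scan)."""
    rng = np.random.default_rng(seed)
    nt, nb = len(target_introns), len(background_introns)
    all_introns = list(target_introns) + list(background_introns)
    lens = np.array([i[2] - i[1] for i in all_introns], dtype=float)
    perm = np.array([rng.permutation(nt + nb) for _ in range(n_shuffles)])
    rows = []
    for cls, sub in sorted(repeats.by_class().items()):
        ov = np.array([overlap_bases(i, sub) for i in all_introns], dtype=float)
        ft = ov[:nt].sum() / lens[:nt].sum()
        fb = ov[nt:].sum() / lens[nt:].sum()
        obs = ft - fb
        po = ov[perm]
        pl = lens[perm]
        pft = po[:, :nt].sum(axis=1) / pl[:, :nt].sum(axis=1)
        pfb = po[:, nt:].sum(axis=1) / pl[:, nt:].sum(axis=1)
        p = (1.0 + (np.abs(pft - pfb) >= abs(obs)).sum()) / (1.0 + n_shuffles)
        ratio = ft / fb if fb > 0 else np.nan
        rows.append((cls, ft, fb, ratio, p,
                     int(ov[:nt].sum()), int(ov[nt:].sum())))
    df = pd.DataFrame(rows, columns=["repeat_class", "fraction_target",
                                     "fraction_background", "ratio", "p_value",
                                     "bases_target", "bases_background"])
    df["q_value"] = ist.bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


def consistency_report(tables: Sequence[pd.DataFrame],
                       min_fraction: float = 0.8,
                       q_threshold: float = 0.05,
                       feature_col: str | None = None) -> pd.DataFrame:
    """Features (motifs or repeat classes) enriched (ratio > 1, q below
    threshold) in at least ``min_fraction`` of the supplied result tables
    — the cross-dataset consistency criterion."""
    if not tables:
        raise ValueError("no result tables supplied")
    if feature_col is None:
        feature_col = ("motif_id" if "motif_id" in tables[0].columns
                       else "repeat_class")
    counts: dict[str, int] = {}
    for t in tables:
        sig = t[(t["q_value"] < q_threshold) & (t["ratio"] > 1)]
        for f in sig[feature_col]:
            counts[f] = counts.get(f, 0) + 1
    rows = [(f, c, c / len(tables)) for f, c in sorted(counts.items())
            if c / len(tables) >= min_fraction]
    return pd.DataFrame(rows, columns=[feature_col, "n_significant",
                                       "fraction_significant"])
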