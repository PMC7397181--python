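"""Seven-way local alternative-splicing event classification and Ψ/ΔΨ
quantification.

Events are detected by pairwise comparison of exon chains within a gene
and then given gene-wide inclusion/exclusion transcript sets by coordinate
test, so Ψ uses all isoform evidence. Kinds: A3/A5 (alternative 3'/5'
splice site), AF/AL (alternative first/last exon), MX (mutually exclusive
exons), RI (retained intron), SE (skipped exon). ΔΨ = Ψ_cytoplasm −
Ψ_nucleus: the smaller the ΔΨ, the more the inclusion form prefers the
nucleus.

Inclusion conventions (documented, strand-resolved): RI — the
intron-retaining form; SE — the exon-containing form; A3/A5 — the
shorter-intron (longer-exon) form; MX — the form using the 5'-proximal
exon; AF/AL — the form using the 5'-/3'-distal terminal exon.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as ist
from .models import ExpressionTable, TranscriptModel, group_by_gene

log = logging.getLogger(__name__)

DEFAULT_PSI_FLOOR = 1.0  # TPM over inclusion+exclusion forms, per fraction


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    kind: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    inclusion_transcripts: frozenset
    exclusion_transcripts: frozenset

    def __post_init__(self):
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty inclusion/exclusion set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: overlapping sets")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# --- candidate generation from one transcript pair ---------------------

def _candidates(a: TranscriptModel, b: TranscriptModel) -> list[tuple]:
    """(kind, coords) candidates from an unordered transcript pair.

    Rules are mutually exclusive by construction: shared-boundary junction
    pairs only yield A3/A5 when the neighbouring exons overlap, which
    excludes SE (skipped exon between the junctions) and MX (disjoint
    alternative exons)."""
    out = []
    strand = a.strand
    for x, y in ((a, b), (b, a)):
        jx, jy = set(x.junctions), set(y.junctions)
        # RI: an intron of y spanned by an exon of x
        for d, e in y.introns:
            if any(s < d and e < t for s, t in x.exons):
                out.append(("RI", (d, e)))
        # SE: internal exon of x with both flanking junctions, absent from y
        for k in range(1, x.n_exons - 1):
            d1 = x.exons[k - 1][1]
            s, e = x.exons[k]
            a2 = x.exons[k + 1][0]
            if (d1, a2) in jy:
                out.append(("SE", (d1, s, e, a2)))
        # A3/A5: junction pairs sharing one boundary, neighbouring exons
        # overlapping
        for (d1, a1), (d2, a2) in itertools.product(jx, jy):
            if (d1, a1) == (d2, a2):
                continue
            if d1 == d2 and a1 != a2:
                ex1 = next(e for e in x.exons if e[0] == a1)
                ex2 = next(e for e in y.exons if e[0] == a2)
                if _overlap(ex1, ex2):
                    kind = "A3" if strand == "+" else "A5"
                    out.append((kind, (d1, min(a1, a2), max(a1, a2))))
            elif a1 == a2 and d1 != d2:
                ex1 = next(e for e in x.exons if e[1] == d1)
                ex2 = next(e for e in y.exons if e[1] == d2)
                if _overlap(ex1, ex2):
                    kind = "A5" if strand == "+" else "A3"
                    out.append((kind, (min(d1, d2), max(d1, d2), a1)))
        # MX: disjoint cassette exons sharing both outer boundaries
        for k in range(1, x.n_exons - 1):
            s1, e1 = x.exons[k]
            D, A = x.exons[k - 1][1], x.exons[k + 1][0]
            for m in range(1, y.n_exons - 1):
                s2, e2 = y.exons[m]
                if (y.exons[m - 1][1] == D and y.exons[m + 1][0] == A
                        and not _overlap((s1, e1), (s2, e2))
                        and (s1, e1) != (s2, e2)):
                    lo, hi = sorted([(s1, e1), (s2, e2)])
                    out.append(("MX", (D, *lo, *hi, A)))
    # AF/AL: differing non-overlapping terminal exons with a shared
    # junction boundary into/out of the gene body
    if a.n_exons >= 2 and b.n_exons >= 2:
        fa, fb = a.exons[0], b.exons[0]
        if fa != fb and not _overlap(fa, fb) \
                and a.junctions[0][1] == b.junctions[0][1]:
            kind = "AF" if strand == "+" else "AL"
            lo, hi = sorted([fa, fb])
            out.append((kind, (*lo, *hi, a.junctions[0][1])))
        la, lb = a.exons[-1], b.exons[-1]
        if la != lb and not _overlap(la, lb) \
                and a.junctions[-1][0] == b.junctions[-1][0]:
            kind = "AL" if strand == "+" else "AF"
            lo, hi = sorted([la, lb])
            out.append((kind, (a.junctions[-1][0], *lo, *hi)))
    return out


# --- gene-wide membership ----------------------------------------------

def _membership(kind: str, coords: tuple, t: TranscriptModel) -> str | None:
    """'inclusion', 'exclusion', 'both' or None for one transcript."""
    exons, junctions = t.exons, set(t.junctions)
    incl = excl = False
    if kind == "RI":
        d, e = coords
        incl = any(s < d and e < tt for s, tt in exons)
        excl = (d, e) in junctions
    elif kind == "SE":
        d1, s, e, a2 = coords
        incl = (s, e) in exons and (d1, s) in junctions and (e, a2) in junctions
        excl = (d1, a2) in junctions
    elif kind in ("A3", "A5"):
        # a shared genomic-left boundary yields A3 on + / A5 on -, so the
        # coordinate layout is recoverable from kind + strand:
        # shared-left coords are (d, a1, a2), shared-right are (d1, d2, a)
        shared_left = (kind == "A3") == (t.strand == "+")
        if shared_left:
            d, a1, a2 = coords
            j_short, j_long = (d, a1), (d, a2)
        else:
            d1, d2, a = coords
            j_short, j_long = (d2, a), (d1, a)
        incl = j_short in junctions
        excl = j_long in junctions
    elif kind == "MX":
        D, s1, e1, s2, e2, A = coords
        first = (s1, e1) if t.strand == "+" else (s2, e2)
        second = (s2, e2) if t.strand == "+" else (s1, e1)
        incl = ((D, first[0]) in junctions and (first[1], A) in junctions)
        excl = ((D, second[0]) in junctions and (second[1], A) in junctions)
    elif kind in ("AF", "AL"):
        # the terminal exon farther from the gene body is the distal
        # (inclusion) form on either strand
        left_terminal = (kind == "AF") == (t.strand == "+")
        if left_terminal:
            s1, e1, s2, e2, acc = coords
            distal, proximal = (s1, e1), (s2, e2)
            incl = exons[0] == distal and (distal[1], acc) in junctions
            excl = exons[0] == proximal and (proximal[1], acc) in junctions
        else:
            don, s1, e1, s2, e2 = coords
            distal, proximal = (s2, e2), (s1, e1)
            incl = exons[-1] == distal and (don, distal[0]) in junctions
            excl = exons[-1] == proximal and (don, proximal[0]) in junctions
    if incl and excl:
        return "both"
    if incl:
        return "inclusion"
    if excl:
        return "exclusion"
    return None


def extract_events(models: Sequence[TranscriptModel]) -> tuple[list[SpliceEvent], pd.DataFrame]:
    """Classify local events for every gene with >= 2 isoforms.

    Returns (events, residual) where residual lists transcript pairs whose
    exon chains differ but contributed no classified event, plus events
    discarded because a transcript matched both sides.
    """
    events: list[SpliceEvent] = []
    residual_rows = []
    for gene_id, txs in sorted(group_by_gene(models).items()):
        if len(txs) < 2:
            continue
        chrom, strand = txs[0].chrom, txs[0].strand
        seen: dict[tuple, tuple] = {}
        pair_hits = {t.transcript_id: set() for t in txs}
        for a, b in itertools.combinations(txs, 2):
            cands = _candidates(a, b)
            if a.exons != b.exons and not cands:
                residual_rows.append((gene_id, a.transcript_id,
                                      b.transcript_id, "unclassified"))
            for kind, coords in cands:
                seen[(kind, coords)] = (kind, coords)
        for kind, coords in sorted(seen.values()):
            incl, excl, both = set(), set(), set()
            for t in txs:
                m = _membership(kind, coords, t)
                if m == "inclusion":
                    incl.add(t.transcript_id)
                elif m == "exclusion":
                    excl.add(t.transcript_id)
                elif m == "both":
                    both.add(t.transcript_id)
            if both:
                residual_rows.append((gene_id, ";".join(sorted(both)), "",
                                      f"discarded_{kind}_ambiguous"))
                continue
            if not incl or not excl:
                continue
            event_id = (f"{gene_id};{kind}:{chrom}:"
                        + "-".join(map(str, coords)) + f":{strand}")
            events.append(SpliceEvent(event_id, gene_id, kind, chrom, strand,
                                      coords, frozenset(incl), frozenset(excl)))
    residual = pd.DataFrame(residual_rows, columns=["gene_id", "transcript_a",
                                                    "transcript_b", "reason"])
    return events, residual


def events_table(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.event_id, e.gene_id, e.kind, e.chrom, e.strand,
          "-".join(map(str, e.coords)),
          ",".join(sorted(e.inclusion_transcripts)),
          ",".join(sorted(e.exclusion_transcripts))) for e in events],
        columns=["event_id", "gene_id", "kind", "chrom", "strand",
                 "coordinates", "inclusion_transcripts",
                 "exclusion_transcripts"])


# --- Ψ quantification ---------------------------------------------------

def compute_psi(event: SpliceEvent, expr: ExpressionTable, fraction: str,
                floor: float = DEFAULT_PSI_FLOOR) -> float:
    """Inclusion ratio Ψ = ΣTPM_incl / (ΣTPM_incl + ΣTPM_excl) on
    replicate-mean TPM; NaN when the denominator is below the floor."""
    mean = expr.fraction_mean(fraction)
    inc = float(mean.reindex(sorted(event.inclusion_transcripts)).fillna(0).sum())
    exc = float(mean.reindex(sorted(event.exclusion_transcripts)).fillna(0).sum())
    tot = inc + exc
    if tot < floor or tot == 0:
        return float("nan")
    return inc / tot


def compute_delta_psi(events: Sequence[SpliceEvent], expr: ExpressionTable,
                      floor: float = DEFAULT_PSI_FLOOR,
                      n_bins: int = 5, seed: int = 0) -> pd.DataFrame:
    """Ψ per fraction, ΔΨ = Ψ_cyto − Ψ_nuc, and empirical p-values from the
    between-replicate null (same scheme and variance rescaling as ΔTU).

    Events whose inclusion+exclusion TPM falls below the floor in either
    fraction are skipped; the count is logged.
    """
    rc = expr.n_replicates("cytoplasm")
    rn = expr.n_replicates("nucleus")
    rows, null_vals, null_cov = [], [], []
    scale = np.sqrt((1.0 / rc + 1.0 / rn) / 2.0) if min(rc, rn) >= 2 else None
    mean_c = expr.fraction_mean("cytoplasm")
    mean_n = expr.fraction_mean("nucleus")
    n_skipped = 0
    for ev in events:
        inc_ids = sorted(ev.inclusion_transcripts)
        exc_ids = sorted(ev.exclusion_transcripts)
        ic = float(mean_c.reindex(inc_ids).fillna(0).sum())
        ec = float(mean_c.reindex(exc_ids).fillna(0).sum())
        inn = float(mean_n.reindex(inc_ids).fillna(0).sum())
        en = float(mean_n.reindex(exc_ids).fillna(0).sum())
        if ic + ec < floor or inn + en < floor or ic + ec == 0 or inn + en == 0:
            n_skipped += 1
            continue
        psi_c = ic / (ic + ec)
        psi_n = inn / (inn + en)
        tot = (ic + ec + inn + en) / 2
        rows.append((ev.event_id, ev.gene_id, ev.kind, psi_c, psi_n,
                     psi_c - psi_n, np.log10(tot + 1e-9)))
        if scale is not None:
            for fraction in ("cytoplasm", "nucleus"):
                vals = expr.fraction_values(fraction)
                inc_r = vals.reindex(inc_ids).fillna(0).sum(axis=0)
                exc_r = vals.reindex(exc_ids).fillna(0).sum(axis=0)
                tot_r = inc_r + exc_r
                psi_r = (inc_r / tot_r).to_numpy()
                for a, b in itertools.combinations(range(len(psi_r)), 2):
                    if np.isfinite(psi_r[a]) and np.isfinite(psi_r[b]):
                        null_vals.append((psi_r[a] - psi_r[b]) * scale)
                        null_cov.append(np.log10(tot + 1e-9))
    if n_skipped:
        log.info("skipped %d events below the %.3g TPM floor", n_skipped, floor)
    df = pd.DataFrame(rows, columns=["event_id", "gene_id", "kind",
                                     "psi_cyto", "psi_nuc", "delta_psi",
                                     "log10_tpm"])
    if scale is not None and len(df) and null_vals:
        df["p_value"] = ist.empirical_tail_p(
            df["delta_psi"].to_numpy(), df["log10_tpm"].to_numpy(),
            np.asarray(null_vals), np.asarray(null_cov),
            n_bins=n_bins, seed=seed)
    else:
        df["p_value"] = np.nan
    return df.drop(columns=["log10_tpm"])


def select_nuclear_ris(psi: pd.DataFrame, alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nuclear RIs (ΔΨ < 0, p < alpha) and the all-RI background."""
    all_ri = psi[psi["kind"] == "RI"]
    nuclear = all_ri[(all_ri["delta_psi"] < 0) & (all_ri["p_value"] < alpha)]
    return nuclear, all_ri


def psi_by_kind(psi: pd.DataFrame, min_n: int = 5) -> pd.DataFrame:
    """Per-kind ΔΨ summary: n, median ΔΨ, and Mood's median test of each
    kind against all other kinds pooled. Kinds with n < min_n are flagged
    low-power."""
    rows = []
    for kind, sub in psi.groupby("kind"):
        others = psi.loc[psi["kind"] != kind, "delta_psi"]
        if len(sub) >= 2 and len(others) >= 2:
            res = ist.moods_median_test(sub["delta_psi"].to_numpy(),
                                        others.to_numpy())
            p = res.p_value
        else:
            p = np.nan
        rows.append((kind, len(sub), float(sub["delta_psi"].median()), p,
                     len(sub) < min_n))
    return pd.DataFrame(rows, columns=["kind", "n", "median_delta_psi",
                                       "p_value", "low_power"])
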