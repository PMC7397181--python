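"""Transcript usage (TU), ΔTU with empirical significance, switch-pair
calling, and the downstream switch-pair comparisons.

TU is a transcript's share of its gene's summed TPM; ΔTU = TU_cytoplasm −
TU_nucleus, so positive values mark cytoplasm-enriched isoforms. A switch
pair is a gene's most cytoplasm-shifted and most nucleus-shifted
significant isoforms (ΔTU beyond ±threshold, empirical p < alpha).
"""
from __future__ import annotations

import itertools
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as ist
from .models import ExpressionTable, TranscriptModel, group_by_gene

log = logging.getLogger(__name__)

DEFAULT_TU_THRESHOLD = 0.2
DEFAULT_ALPHA = 0.05
DEFAULT_EXPRESSION_FLOOR = 1.0  # TPM; genes below it in a fraction are excluded


def _gene_map(models: Sequence[TranscriptModel]) -> pd.Series:
    return pd.Series({m.transcript_id: m.gene_id for m in models})


def compute_usage(expr: ExpressionTable, models: Sequence[TranscriptModel],
                  expression_floor: float = DEFAULT_EXPRESSION_FLOOR) -> pd.DataFrame:
    """Per-transcript TU in each fraction and ΔTU (point estimates).

    Uses replicate-mean TPM. Genes whose summed TPM falls below
    ``expression_floor`` in either fraction are excluded (their usage is
    unreliable); the excluded count is logged. Returns a DataFrame indexed
    by transcript_id with columns gene_id, tu_cyto, tu_nuc, delta_tu and an
    unset p_value column.
    """
    genes = _gene_map(models)
    unknown = expr.values.index.difference(genes.index)
    if len(unknown):
        raise ValueError(f"transcripts absent from annotation: "
                         f"{sorted(unknown)[:5]}")
    mean_c = expr.fraction_mean("cytoplasm")
    mean_n = expr.fraction_mean("nucleus")
    df = pd.DataFrame({"gene_id": genes.reindex(expr.values.index),
                       "tpm_cyto": mean_c, "tpm_nuc": mean_n})
    gene_c = df.groupby("gene_id")["tpm_cyto"].transform("sum")
    gene_n = df.groupby("gene_id")["tpm_nuc"].transform("sum")
    keep = (gene_c >= expression_floor) & (gene_n >= expression_floor)
    n_excluded = df.loc[~keep, "gene_id"].nunique()
    if n_excluded:
        log.info("excluded %d genes below the %.3g TPM expression floor",
                 n_excluded, expression_floor)
    df = df[keep]
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "tu_cyto": df["tpm_cyto"] / gene_c[keep],
        "tu_nuc": df["tpm_nuc"] / gene_n[keep],
    })
    out["delta_tu"] = out["tu_cyto"] - out["tu_nuc"]
    out["p_value"] = np.nan
    out.index.name = "transcript_id"
    return out


def _replicate_tu(expr: ExpressionTable, genes: pd.Series, fraction: str) -> pd.DataFrame:
    """Per-replicate TU values (transcript x replicate)."""
    vals = expr.fraction_values(fraction)
    gid = genes.reindex(vals.index)
    gene_tot = vals.groupby(gid.to_numpy()).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        tu = vals / gene_tot
    return tu


def empirical_pvalues(expr: ExpressionTable, models: Sequence[TranscriptModel],
                      usage: pd.DataFrame | None = None,
                      n_bins: int = 5, seed: int = 0,
                      expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
                      max_null: int = 100_000) -> pd.DataFrame:
    """Attach empirical two-sided p-values to ΔTU point estimates.

    The null distribution is built from between-replicate TU differences
    computed within each fraction (all replicate pairs, both fractions),
    pooled across transcripts binned by log10 gene TPM. Null differences
    are single-replicate contrasts while the observed ΔTU contrasts
    replicate means, so null values are rescaled by
    sqrt((1/R_c + 1/R_n) / 2) to put both on the same variance scale.
    p = (1 + #{|null| >= |obs|}) / (1 + N). Deterministic given the seed.
    """
    rc = expr.n_replicates("cytoplasm")
    rn = expr.n_replicates("nucleus")
    if rc < 2 or rn < 2:
        raise ValueError(
            "empirical significance requires >= 2 replicates per fraction; "
            f"got {rc} (cytoplasm) and {rn} (nucleus)")
    if usage is None:
        usage = compute_usage(expr, models, expression_floor)
    genes = _gene_map(models)
    gene_tpm = (expr.values.groupby(genes.reindex(expr.values.index).to_numpy())
                .transform("sum").mean(axis=1))
    covariate = np.log10(gene_tpm + 1e-9)

    scale = np.sqrt((1.0 / rc + 1.0 / rn) / 2.0)
    null_vals, null_cov = [], []
    for fraction in ("cytoplasm", "nucleus"):
        tu = _replicate_tu(expr, genes, fraction)
        cols = tu.columns
        for a, b in itertools.combinations(range(len(cols)), 2):
            d = (tu.iloc[:, a] - tu.iloc[:, b]).dropna()
            d = d.loc[d.index.intersection(usage.index)]
            null_vals.append(d.to_numpy() * scale)
            null_cov.append(covariate.reindex(d.index).to_numpy())
    null_vals = np.concatenate(null_vals)
    null_cov = np.concatenate(null_cov)

    out = usage.copy()
    out["p_value"] = ist.empirical_tail_p(
        out["delta_tu"].to_numpy(),
        covariate.reindex(out.index).to_numpy(),
        null_vals, null_cov, n_bins=n_bins, seed=seed,
        max_null_per_bin=max_null)
    return out


def call_switches(usage: pd.DataFrame, models: Sequence[TranscriptModel],
                  threshold: float = DEFAULT_TU_THRESHOLD,
                  alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-gene switch pairs: Tc = argmax ΔTU among significant ΔTU >
    threshold, Tn = argmin among significant ΔTU < −threshold; a pair is
    emitted only when both exist. Ties break by transcript_id."""
    if usage["p_value"].isna().any():
        raise ValueError("usage table lacks p-values; run empirical_pvalues")
    lengths = {m.transcript_id: m.length for m in models}
    rows = []
    for gene_id, sub in usage.groupby("gene_id", sort=True):
        sub = sub.sort_index()  # lexicographic tie-break
        up = sub[(sub["delta_tu"] > threshold) & (sub["p_value"] < alpha)]
        dn = sub[(sub["delta_tu"] < -threshold) & (sub["p_value"] < alpha)]
        if up.empty or dn.empty:
            continue
        tc = up["delta_tu"].idxmax()
        tn = dn["delta_tu"].idxmin()
        len_c, len_n = lengths[tc], lengths[tn]
        if len_c == 0 or len_n == 0:
            raise ValueError(f"zero-length transcript in gene {gene_id}")
        ratio = float(np.log2(len_c / len_n))
        category = ("positive" if ratio > 1
                    else "negative" if ratio < -1 else "neutral")
        rows.append((gene_id, tc, tn, float(up.loc[tc, "delta_tu"]),
                     float(dn.loc[tn, "delta_tu"]), ratio, category))
    return pd.DataFrame(rows, columns=["gene_id", "tc_id", "tn_id",
                                       "delta_tu_c", "delta_tu_n",
                                       "length_ratio_log2", "category"])


def classify_length_ratio(pairs: pd.DataFrame) -> tuple[pd.Series, ist.TestResult]:
    """Category counts of the Tc/Tn length ratio plus a two-sided binomial
    test of positive vs negative counts (p0 = 0.5)."""
    counts = pairs["category"].value_counts().reindex(
        ["positive", "negative", "neutral"], fill_value=0)
    n_pos, n_neg = int(counts["positive"]), int(counts["negative"])
    if n_pos + n_neg == 0:
        raise ValueError("no positive or negative category pairs to test")
    test = ist.binomial_test(n_pos, n_pos + n_neg, 0.5)
    return counts, test


def compare_exon_counts(pairs: pd.DataFrame, models: Sequence[TranscriptModel],
                        category: str) -> ist.TestResult:
    """Mood's median test on exon counts of Tc vs Tn within one length-ratio
    category (tests whether splicing frequency tracks cytoplasmic export)."""
    n_exons = {m.transcript_id: m.n_exons for m in models}
    sub = pairs[pairs["category"] == category]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 pairs in category {category!r}")
    x = sub["tc_id"].map(n_exons).to_numpy(dtype=float)
    y = sub["tn_id"].map(n_exons).to_numpy(dtype=float)
    return ist.moods_median_test(x, y)


def compare_mono_multi(usage: pd.DataFrame, pairs: pd.DataFrame,
                       models: Sequence[TranscriptModel]) -> ist.TestResult:
    """Welch two-tailed t-test on ΔTU of mono- vs multi-exonic switch-pair
    members. Returns (multi − mono) direction in the effect summary."""
    n_exons = {m.transcript_id: m.n_exons for m in models}
    members = pd.unique(pd.concat([pairs["tc_id"], pairs["tn_id"]]))
    sub = usage.loc[usage.index.intersection(members)]
    mono = sub[[n_exons[t] == 1 for t in sub.index]]["delta_tu"].to_numpy()
    multi = sub[[n_exons[t] > 1 for t in sub.index]]["delta_tu"].to_numpy()
    if mono.size < 2 or multi.size < 2:
        raise ValueError("need >= 2 mono-exonic and >= 2 multi-exonic "
                         "switch-pair members")
    res = ist.welch_t_test(multi, mono)
    res.effect.update({"mean_multi": float(multi.mean()),
                       "mean_mono": float(mono.mean())})
    return res


def compare_biotype(usage: pd.DataFrame,
                    models: Sequence[TranscriptModel]) -> ist.TestResult | None:
    """Mood's median test on ΔTU, coding vs noncoding transcripts."""
    biotype = {m.transcript_id: m.biotype for m in models}
    groups = usage.groupby([biotype[t] for t in usage.index])["delta_tu"]
    present = dict(list(groups))
    if "coding" not in present or "noncoding" not in present:
        warnings.warn("only one biotype present; comparison skipped")
        return None
    res = ist.moods_median_test(present["coding"].to_numpy(),
                                present["noncoding"].to_numpy())
    res.effect["groups"] = ("coding", "noncoding")
    return res


def nmd_sensitivity(expr_control: ExpressionTable, expr_kd: ExpressionTable,
                    pseudocount: float = 0.01) -> pd.Series:
    """Per-transcript NMD sensitivity: log2 fold-change of mean TPM after
    knockdown of NMD factors, with a small pseudo-count."""
    if not expr_control.values.index.equals(expr_kd.values.index):
        raise ValueError("control and knockdown tables cover different "
                         "transcript sets")
    ctrl = expr_control.values.mean(axis=1)
    kd = expr_kd.values.mean(axis=1)
    sens = np.log2((kd + pseudocount) / (ctrl + pseudocount))
    sens.name = "nmd_sensitivity"
    return sens


def compare_nmd(sens: pd.Series, pairs: pd.DataFrame) -> ist.TestResult:
    """Mood's median test of NMD sensitivity between cytoplasmic (Tc) and
    nuclear (Tn) switch-pair members."""
    x = sens.reindex(pairs["tc_id"]).dropna().to_numpy()
    y = sens.reindex(pairs["tn_id"]).dropna().to_numpy()
    return ist.moods_median_test(x, y)


def shared_switching_genes(switch_tables: Sequence[pd.DataFrame],
                           min_runs: int = 5) -> pd.Series:
    """Genes called as switching in at least ``min_runs`` of the supplied
    result tables (e.g., one per cell line)."""
    counts = pd.concat([t["gene_id"].drop_duplicates()
                        for t in switch_tables]).value_counts()
    return counts[counts >= min_runs]
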