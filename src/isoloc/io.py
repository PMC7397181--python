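"""Readers and writers for every external format the pipeline touches.

GTF is read from exon features only (attributes gene_id, transcript_id and
optionally transcript_type); coordinates are converted from the 1-based
closed GTF convention to the internal 0-based half-open convention at this
boundary and nowhere else. All readers reject malformed input rather than
silently repairing it.
"""
from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (PWM, ExpressionTable, RepeatAnnotation, TranscriptModel)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into TranscriptModels.

    Exons are grouped by transcript_id and sorted by start; biotype is taken
    from the transcript_type attribute when present ('coding' otherwise,
    with any value other than 'protein_coding'/'coding' mapped to
    'noncoding').
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-delimited fields, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: non-integer "
                    f"coordinates") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: malformed GTF line {lineno}: "
                                 f"invalid strand {strand!r}")
            a = _parse_attributes(attrs)
            if "transcript_id" not in a or "gene_id" not in a:
                raise ValueError(f"{path}: exon at line {lineno} lacks "
                                 f"gene_id/transcript_id attributes")
            tid = a["transcript_id"]
            biotype_raw = a.get("transcript_type", "coding")
            biotype = "coding" if biotype_raw in ("coding", "protein_coding") \
                else "noncoding"
            # GTF 1-based closed -> 0-based half-open
            exons.setdefault(tid, []).append((start_i - 1, end_i))
            info[tid] = (a["gene_id"], chrom, strand, biotype)
    models = []
    for tid, ex in exons.items():
        gene_id, chrom, strand, biotype = info[tid]
        models.append(TranscriptModel(tid, gene_id, chrom, strand,
                                      tuple(sorted(ex)), biotype))
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            btype = "protein_coding" if m.biotype == "coding" else "lncRNA"
            for s, e in m.exons:
                attrs = (f'gene_id "{m.gene_id}"; transcript_id '
                         f'"{m.transcript_id}"; transcript_type "{btype}";')
                fh.write("\t".join([m.chrom, "isoloc", "exon", str(s + 1),
                                    str(e), ".", m.strand, ".", attrs]) + "\n")


def read_expression(path, meta: pd.DataFrame | Mapping) -> ExpressionTable:
    """Read a TSV TPM matrix (first column transcript_id) with sample
    metadata mapping every column to a fraction/replicate."""
    if not isinstance(meta, pd.DataFrame):
        meta = pd.DataFrame.from_dict(meta, orient="index")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing TPM values")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return ExpressionTable(df, meta)


def read_sample_meta(path) -> pd.DataFrame:
    """TSV with columns sample_id, fraction, replicate."""
    meta = pd.read_csv(path, sep="\t")
    return meta.set_index("sample_id")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> RepeatAnnotation:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "repeat_class"],
                     usecols=[0, 1, 2, 3])
    return RepeatAnnotation(df)


def write_bed(repeats: RepeatAnnotation, path) -> None:
    repeats.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_pwms(path) -> list[PWM]:
    """Read PWMs from a TSV block format::

        >motif_id<TAB>rbp_name
        pA<TAB>pC<TAB>pG<TAB>pU      (one line per motif position)
    """
    pwms: list[PWM] = []
    motif_id = rbp = None
    rows: list[list[float]] = []

    def _flush():
        if motif_id is not None:
            pwms.append(PWM(motif_id, rbp, np.array(rows, dtype=float)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split("\t")
                motif_id = parts[0].strip()
                rbp = parts[1].strip() if len(parts) > 1 else motif_id
                rows = []
            else:
                vals = line.split("\t")
                if len(vals) != 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 "
                                     f"probabilities (A C G U)")
                rows.append([float(v) for v in vals])
    _flush()
    return pwms


def write_pwms(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\t{p.rbp_name}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result table as <name>.tsv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def load_config(path) -> dict:
    """Key-value run configuration (YAML).

    Recognized keys: gtf, expression, sample_meta, genome_fasta, repeats_bed,
    pwms (paths); tu_threshold, alpha, expression_floor, n_shuffles, seed,
    min_transcript_length (optional analysis parameters; the length filter
    defaults to off).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def apply_length_filter(models: list[TranscriptModel],
                        min_length: int | None) -> list[TranscriptModel]:
    if not min_length:
        return models
    return [m for m in models if m.length >= min_length]
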