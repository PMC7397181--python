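"""Synthetic study generator with planted, parameterized effects.

Produces a gene annotation in which every multi-isoform gene embeds one of
the seven local splicing-event kinds by explicit exon-structure edit, a
genome sequence with canonical GT..AG splice sites, fraction-labelled
replicate TPM tables with planted transcript-usage switches and
nucleus-biased retained introns, repeat intervals, and NMD-knockdown
tables. Every planted effect is recorded in a GroundTruth object so each
downstream stage can be tested for parameter recovery.

Nuclear retained introns are planted short, GC-rich, with an exact
inverted-repeat stem and optional motif instances — the sequence features
the analysis stages are designed to detect.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from .models import (PWM, EVENT_KINDS, ExpressionTable, RepeatAnnotation,
                     TranscriptModel, reverse_complement)

_BASES = np.frombuffer(b"ACGU", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the fractionation-study setting the pipeline targets:
    two isoforms per gene, three replicates per fraction, ~10% replicate
    noise, usage switches of |ΔTU| 0.5, nuclear retained introns that are
    short (mean 150 nt vs 1500 nt background), GC-boosted (+0.15) and
    stem-bearing, with a nucleus-ward inclusion shift of 0.4.
    """

    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 2)
    event_mix: dict | None = None            # kind -> proportion; uniform if None
    frac_switching_genes: float = 0.5
    switch_effect: float = 0.5               # planted |ΔTU|
    n_replicates: int = 3
    noise_cv: float = 0.1
    ri_nuclear_frac: float = 0.5             # RI events planted nucleus-biased
    psi_effect: float = 0.4                  # planted Ψ_nuc - Ψ_cyto for nuclear RIs
    ri_short_len: int = 150                  # mean nuclear-RI intron length (nt)
    ri_bg_len: int = 1500                    # mean background intron length (nt)
    ri_gc_boost: float = 0.15                # GC excess of nuclear-RI introns
    base_gc: float = 0.45
    min_intron_len: int = 60
    exon_len_range: tuple[int, int] = (80, 250)
    n_exons_range: tuple[int, int] = (4, 7)
    stem_len: int = 30                       # planted inverted-repeat arm
    stem_loop: int = 4
    planted_motifs: tuple[PWM, ...] = ()
    motif_copies: int = 2                    # instances per nuclear RI
    repeat_nuclear_rate: float = 0.5         # P(SINE | nuclear RI intron)
    repeat_bg_rate: float = 0.1
    repeat_length: int = 100
    mono_nuclear_frac: float = 0.2           # switching genes whose Tn is unspliced
    noncoding_nuclear_prob: float = 0.5      # P(noncoding | Tn)
    noncoding_bg_prob: float = 0.1
    expr_tpm_range: tuple[float, float] = (1.0, 1000.0)
    nmd_decay_range: tuple[float, float] = (0.5, 4.0)
    expression_floor_pad: int = 0            # reserved
    seed: int = 0

    def __post_init__(self):
        if self.event_mix is None:
            self.event_mix = {k: 1.0 / len(EVENT_KINDS) for k in EVENT_KINDS}
        unknown = set(self.event_mix) - set(EVENT_KINDS)
        if unknown:
            raise ValueError(f"unknown event kinds in event_mix: {sorted(unknown)}")
        tot = sum(self.event_mix.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError("event_mix proportions must sum to 1")
        for name in ("frac_switching_genes", "ri_nuclear_frac", "ri_gc_boost",
                     "noise_cv", "mono_nuclear_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.switch_effect <= 1 and 0 <= self.psi_effect <= 1):
            raise ValueError("effect sizes are proportions in [0, 1]")
        if min(self.ri_short_len, self.ri_bg_len, self.min_intron_len) < 60:
            raise ValueError("intron lengths must be >= 60 nt")
        needs_internal = {"SE", "MX"} & {k for k, v in self.event_mix.items() if v > 0}
        if needs_internal and self.n_exons_range[1] < 3:
            raise ValueError(f"event kinds {sorted(needs_internal)} need "
                             f"genes with >= 3 exons")


@dataclass
class PlantedEvent:
    gene_id: str
    kind: str
    inclusion_tx: str
    exclusion_tx: str
    chrom: str
    strand: str
    intron: tuple[int, int] | None = None    # genomic, RI only
    nuclear: bool = False


@dataclass
class GroundTruth:
    """Planted effects, keyed by generated annotation ids."""

    switching: dict = field(default_factory=dict)  # gene -> (tc, tn, effect)
    events: list = field(default_factory=list)     # PlantedEvent
    nuclear_ri_introns: list = field(default_factory=list)  # (chrom,s,e,strand)
    motif_positions: list = field(default_factory=list)
    stem_positions: list = field(default_factory=list)
    mono_genes: set = field(default_factory=set)
    nmd_multipliers: dict = field(default_factory=dict)

    @property
    def switching_genes(self) -> set:
        return set(self.switching)

    def nuclear_ri_set(self) -> set:
        return {(c, s, e, st) for c, s, e, st in self.nuclear_ri_introns}


def _consensus_dissimilar(a: np.ndarray, b: np.ndarray, min_mismatch: int = 3,
                          min_overlap: int = 5) -> bool:
    """True when no offset alignment of the two consensi with >=
    min_overlap shared positions has fewer than min_mismatch mismatches
    (keeps one planted motif from registering hits for another)."""
    la, lb = a.size, b.size
    for off in range(-(la - min_overlap), lb - min_overlap + 1):
        i0, i1 = max(0, -off), min(la, lb - off)
        if i1 - i0 < min_overlap:
            continue
        if int((a[i0:i1] != b[i0 + off:i1 + off]).sum()) < min_mismatch:
            return False
    return True


def make_test_pwms(n: int = 5, length: int = 7, sharpness: float = 0.91,
                   seed: int = 0) -> list[PWM]:
    """Sharp synthetic PWMs standing in for an RBP motif collection.

    Consensi are rejection-sampled to be mutually dissimilar in every
    offset alignment, so the motifs behave independently when planted."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    while len(chosen) < n:
        cons = rng.integers(0, 4, size=length)
        if all(_consensus_dissimilar(cons, c) for c in chosen):
            chosen.append(cons)
    pwms = []
    for i, cons in enumerate(chosen):
        m = np.full((length, 4), (1 - sharpness) / 3)
        m[np.arange(length), cons] = sharpness
        pwms.append(PWM(f"M{i + 1}", f"RBP{i + 1}", m))
    return pwms


# ----------------------------------------------------------------------
# annotation

def _geom_len(rng, mean: int, minimum: int) -> int:
    p = 1.0 / max(1.0, mean - minimum + 1)
    return minimum + int(rng.geometric(p))


def _build_gene(rng, cfg: SimulationConfig, gene_id: str, chrom: str,
                offset: int, strand: str, kind: str, role: str,
                mono: bool) -> tuple[list, dict, int]:
    """Lay one gene out in local transcription coordinates, apply the event
    edit, then map to genomic coordinates. Returns (transcripts as
    (tid, exons_genomic), meta about the planted event, genomic span)."""
    lo, hi = cfg.n_exons_range
    if kind in ("SE", "MX"):
        lo = max(lo, 3)
    n_ex = int(rng.integers(lo, hi + 1))
    exon_lens = rng.integers(*cfg.exon_len_range, size=n_ex)
    intron_lens = [_geom_len(rng, cfg.ri_bg_len, cfg.min_intron_len)
                   for _ in range(n_ex - 1)]

    # choose the edited position
    nuclear = False
    if kind == "RI":
        k = int(rng.integers(0, n_ex - 1))
        nuclear = role == "nuclear_ri"
        mean = cfg.ri_short_len if nuclear else cfg.ri_bg_len
        intron_lens[k] = _geom_len(rng, mean, cfg.min_intron_len)
    elif kind in ("SE", "MX"):
        k = int(rng.integers(1, n_ex - 1))
    elif kind in ("A3", "A5"):
        k = int(rng.integers(0, n_ex - 1))
    else:  # AF / AL use the terminal exons
        k = 0
    mx_len = int(rng.integers(*cfg.exon_len_range))
    if kind == "MX":
        intron_lens[k] = max(intron_lens[k],
                             mx_len + 2 * cfg.min_intron_len + 20)

    alt_term_len = int(rng.integers(*cfg.exon_len_range))
    pad_left = 50 + (alt_term_len + 80 if kind == "AF" else 0)
    pad_right = 50 + (alt_term_len + 80 if kind == "AL" else 0)

    # iso1 local exons (transcription order)
    exons1 = []
    cur = pad_left
    for i in range(n_ex):
        exons1.append((cur, cur + int(exon_lens[i])))
        cur += int(exon_lens[i])
        if i < n_ex - 1:
            cur += intron_lens[i]
    span = cur + pad_right

    # iso2 per event kind
    if mono:
        exons2 = [(exons1[0][0], exons1[-1][1])]
        kind = None
    elif kind == "SE":
        exons2 = exons1[:k] + exons1[k + 1:]
    elif kind == "RI":
        exons2 = (exons1[:k] + [(exons1[k][0], exons1[k + 1][1])]
                  + exons1[k + 2:])
    elif kind == "A3":
        d = int(rng.integers(12, 41))
        s, e = exons1[k + 1]
        exons2 = exons1[:k + 1] + [(s + d, e)] + exons1[k + 2:]
    elif kind == "A5":
        d = int(rng.integers(12, 41))
        s, e = exons1[k]
        exons2 = exons1[:k] + [(s, e - d)] + exons1[k + 1:]
    elif kind == "AF":
        e1s = exons1[0][0]
        alt = (e1s - 80 - alt_term_len, e1s - 80)
        exons2 = [alt] + exons1[1:]
    elif kind == "AL":
        le = exons1[-1][1]
        alt = (le + 80, le + 80 + alt_term_len)
        exons2 = exons1[:-1] + [alt]
    elif kind == "MX":
        s = exons1[k][1] + cfg.min_intron_len
        exons2 = exons1[:k] + [(s, s + mx_len)] + exons1[k + 1:]
    else:
        raise ValueError(f"unknown event kind {kind!r}")

    def to_genomic(local_exons):
        if strand == "+":
            g = [(offset + s, offset + e) for s, e in local_exons]
        else:
            g = [(offset + span - e, offset + span - s) for s, e in local_exons]
        return tuple(sorted(g))

    t1, t2 = f"{gene_id}.t1", f"{gene_id}.t2"
    txs = [(t1, to_genomic(exons1)), (t2, to_genomic(exons2))]

    # inclusion/exclusion identities for the planted event (see events
    # module conventions): RI inclusion retains the intron; SE inclusion has
    # the exon; A3/A5 inclusion is the shorter-intron form; MX inclusion
    # uses the 5'-proximal exon; AF/AL inclusion uses the 5'/3'-distal
    # terminal exon.
    meta = {"kind": kind, "nuclear": nuclear, "mono": mono}
    if kind == "RI":
        gi = to_genomic([(exons1[k][1], exons1[k + 1][0])])[0]
        meta["intron"] = gi
        meta["inclusion"], meta["exclusion"] = t2, t1
    elif kind in ("SE",):
        meta["inclusion"], meta["exclusion"] = t1, t2
    elif kind in ("A3", "A5"):
        meta["inclusion"], meta["exclusion"] = t1, t2  # iso2 intron longer
    elif kind == "MX":
        meta["inclusion"], meta["exclusion"] = t1, t2  # exon k is 5' of alt
    elif kind == "AF":
        meta["inclusion"], meta["exclusion"] = t2, t1  # alt first exon is 5'-distal
    elif kind == "AL":
        meta["inclusion"], meta["exclusion"] = t2, t1  # alt last exon is 3'-distal
    return txs, meta, span


def simulate_annotation(config: SimulationConfig) -> tuple[list[TranscriptModel], GroundTruth]:
    """Generate the annotation and the ground-truth skeleton."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    models: list[TranscriptModel] = []
    kinds = sorted(config.event_mix)
    probs = np.array([config.event_mix[k] for k in kinds])
    chrom_cursor = {f"chr{i}": 0 for i in range(1, 5)}
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:05d}"
        chrom = f"chr{g % 4 + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        if kind == "RI" and rng.random() < config.ri_nuclear_frac:
            role = "nuclear_ri"
        elif rng.random() < config.frac_switching_genes:
            role = "switching"
        else:
            role = "neutral"
        mono = role == "switching" and rng.random() < config.mono_nuclear_frac
        offset = chrom_cursor[chrom] + 500
        txs, meta, span = _build_gene(rng, config, gene_id, chrom, offset,
                                      strand, kind, role, mono)
        chrom_cursor[chrom] = offset + span

        if mono:
            truth.mono_genes.add(gene_id)
        elif meta["kind"] is not None:
            ev = PlantedEvent(gene_id, meta["kind"], meta["inclusion"],
                              meta["exclusion"], chrom, strand,
                              meta.get("intron"), meta["nuclear"])
            truth.events.append(ev)
            if ev.nuclear:
                s, e = ev.intron
                truth.nuclear_ri_introns.append((chrom, s, e, strand))

        # fraction-effect roles
        t1, t2 = txs[0][0], txs[1][0]
        if role == "switching":
            if mono:
                tc, tn = t1, t2  # the unspliced isoform stays nuclear
            else:
                tc, tn = (t1, t2) if rng.random() < 0.5 else (t2, t1)
            truth.switching[gene_id] = (tc, tn, config.switch_effect)
        elif role == "nuclear_ri":
            truth.switching[gene_id] = (meta["exclusion"], meta["inclusion"],
                                        config.psi_effect)

        # biotypes: nuclear-side isoforms of switch pairs are more often
        # noncoding, mirroring the nuclear preference of noncoding RNAs
        tc_tn = truth.switching.get(gene_id)
        for tid, exons in txs:
            if tc_tn is not None and tid == tc_tn[1]:
                p_nc = config.noncoding_nuclear_prob
            elif tc_tn is not None and tid == tc_tn[0]:
                p_nc = 0.05
            else:
                p_nc = config.noncoding_bg_prob
            biotype = "noncoding" if rng.random() < p_nc else "coding"
            models.append(TranscriptModel(tid, gene_id, chrom, strand,
                                          exons, biotype))
    return models, truth


# ----------------------------------------------------------------------
# sequences

def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _write_sense(chroms: dict, chrom: str, start: int, end: int, strand: str,
                 seq: str) -> None:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if strand == "-":
        arr = np.frombuffer(reverse_complement(seq).encode(), dtype="S1")
    chroms[chrom][start:end] = arr


def simulate_sequences(models: Sequence[TranscriptModel], truth: GroundTruth,
                       config: SimulationConfig) -> dict[str, str]:
    """Genome sequences (DNA alphabet, T not U) for the generated
    annotation: random background, GC-boosted stem- and motif-bearing
    nuclear-RI introns, and canonical GT..AG at every splice junction of
    every isoform (transcribed strand)."""
    rng = np.random.default_rng(config.seed + 101)
    lengths: dict[str, int] = {}
    for m in models:
        lengths[m.chrom] = max(lengths.get(m.chrom, 0), m.end + 500)
    chroms = {c: _random_seq(rng, n, config.base_gc).copy()
              for c, n in lengths.items()}

    nuclear = truth.nuclear_ri_set()
    for chrom, s, e, strand in sorted(nuclear):
        n = e - s
        body_gc = min(0.95, config.base_gc + config.ri_gc_boost)
        body = _random_seq(rng, n, body_gc).tobytes().decode()
        # plant an exact inverted repeat (stem) with a >= 4 nt loop; the arm
        # is drawn at the intron's own composition so the stem adds a
        # structure signal without a composition signal. stem_len=0 turns
        # structure planting off (motif-only fixtures).
        occupied = []
        if config.stem_len > 0:
            arm_len = min(config.stem_len,
                          max(6, (n - config.stem_loop - 12) // 2))
            total = 2 * arm_len + config.stem_loop
            pos = int(rng.integers(4, max(5, n - total - 4)))
            arm = _random_seq(rng, arm_len, body_gc).tobytes().decode()
            stem = (arm
                    + _random_seq(rng, config.stem_loop, body_gc).tobytes().decode()
                    + reverse_complement(arm.replace("U", "T")).replace("T", "U"))
            body = body[:pos] + stem + body[pos + total:]
            truth.stem_positions.append((chrom, s, e, strand, pos, arm_len,
                                         config.stem_loop))
            occupied.append((pos, pos + total))
        for pwm in config.planted_motifs:
            L = len(pwm)
            for _ in range(config.motif_copies):
                for _try in range(20):
                    off = int(rng.integers(4, max(5, n - L - 4)))
                    if all(off + L <= a or off >= b for a, b in occupied):
                        break
                else:
                    continue
                occupied.append((off, off + L))
                inst = "".join("ACGU"[rng.choice(4, p=row)]
                               for row in pwm.matrix)
                body = body[:off] + inst + body[off + L:]
                truth.motif_positions.append((chrom, s, e, strand,
                                              pwm.motif_id, off))
        _write_sense(chroms, chrom, s, e, strand,
                     body.replace("U", "T"))

    # canonical splice sites on the transcribed strand, for every isoform
    for m in models:
        for s, e in m.introns:
            arr = chroms[m.chrom]
            if m.strand == "+":
                arr[s:s + 2] = np.frombuffer(b"GT", dtype="S1")
                arr[e - 2:e] = np.frombuffer(b"AG", dtype="S1")
            else:
                arr[e - 2:e] = np.frombuffer(b"AC", dtype="S1")
                arr[s:s + 2] = np.frombuffer(b"CT", dtype="S1")
    return {c: a.tobytes().decode().replace("U", "T")
            for c, a in chroms.items()}


# ----------------------------------------------------------------------
# expression

def _tpm_table(rng, means: pd.DataFrame, cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate TPM draws around fraction means with multiplicative
    lognormal noise of the configured CV (mean-preserving)."""
    cols, meta_rows = [], []
    data = {}
    sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
    for fraction in ("cytoplasm", "nucleus"):
        for r in range(cfg.n_replicates):
            sid = f"{fraction}_{r + 1}"
            mu = means[fraction].to_numpy()
            if sigma > 0:
                factor = rng.lognormal(-sigma ** 2 / 2, sigma, size=mu.size)
            else:
                factor = 1.0
            data[sid] = mu * factor
            meta_rows.append((sid, fraction, r + 1))
            cols.append(sid)
    values = pd.DataFrame(data, index=means.index)[cols]
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "fraction",
                                            "replicate"]).set_index("sample_id")
    return values, meta


def _fraction_means(models, truth, config, rng) -> pd.DataFrame:
    genes: dict[str, list[str]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m.transcript_id)
    lo, hi = config.expr_tpm_range
    rows = []
    for gene_id in sorted(genes):
        tids = sorted(genes[gene_id])
        expr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        base = np.full(len(tids), 1.0 / len(tids))
        tu_c, tu_n = base.copy(), base.copy()
        if gene_id in truth.switching:
            tc, tn, eff = truth.switching[gene_id]
            ic, iq = tids.index(tc), tids.index(tn)
            tu_c[ic] += eff / 2
            tu_c[iq] -= eff / 2
            tu_n[ic] -= eff / 2
            tu_n[iq] += eff / 2
        for i, tid in enumerate(tids):
            rows.append((tid, expr * tu_c[i], expr * tu_n[i]))
    return pd.DataFrame(rows, columns=["transcript_id", "cytoplasm",
                                       "nucleus"]).set_index("transcript_id")


def simulate_expression(models: Sequence[TranscriptModel], truth: GroundTruth,
                        config: SimulationConfig) -> ExpressionTable:
    rng = np.random.default_rng(config.seed + 202)
    means = _fraction_means(models, truth, config, rng)
    values, meta = _tpm_table(rng, means, config)
    return ExpressionTable(values, meta)


def simulate_nmd(models: Sequence[TranscriptModel], truth: GroundTruth,
                 config: SimulationConfig) -> tuple[ExpressionTable, ExpressionTable]:
    """Control and NMD-factor-knockdown expression tables.

    Per-transcript decay multipliers are drawn independently of
    localization (log-uniform), so NMD sensitivity carries no nuclear or
    cytoplasmic signal — the null the study's comparison is tested against.
    """
    rng = np.random.default_rng(config.seed + 303)
    means = _fraction_means(models, truth, config, rng)
    lo, hi = config.nmd_decay_range
    mult = np.exp(rng.uniform(np.log(lo), np.log(hi), size=means.shape[0]))
    truth.nmd_multipliers = dict(zip(means.index, mult))
    ctrl_vals, meta = _tpm_table(rng, means, config)
    kd_vals, _ = _tpm_table(rng, means.mul(mult, axis=0), config)
    return ExpressionTable(ctrl_vals, meta), ExpressionTable(kd_vals, meta)


# ----------------------------------------------------------------------
# repeats

def simulate_repeats(models: Sequence[TranscriptModel], truth: GroundTruth,
                     config: SimulationConfig) -> RepeatAnnotation:
    """SINE intervals planted inside nuclear-RI introns at
    ``repeat_nuclear_rate`` and inside background RI introns at
    ``repeat_bg_rate``; LINE/DNA/LTR placed at the background rate in both
    sets."""
    rng = np.random.default_rng(config.seed + 404)
    nuclear = truth.nuclear_ri_set()
    rows = []
    for ev in truth.events:
        if ev.kind != "RI":
            continue
        chrom, (s, e), strand = ev.chrom, ev.intron, ev.strand
        n = e - s
        rate = (config.repeat_nuclear_rate if (chrom, s, e, strand) in nuclear
                else config.repeat_bg_rate)
        for cls, r in (("SINE", rate), ("LINE", config.repeat_bg_rate),
                       ("DNA", config.repeat_bg_rate),
                       ("LTR", config.repeat_bg_rate)):
            if rng.random() < r:
                L = min(config.repeat_length, n - 10)
                off = int(rng.integers(0, n - L + 1))
                rows.append((chrom, s + off, s + off + L, cls))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return RepeatAnnotation(df)


# ----------------------------------------------------------------------
# fixture bundle

def bundle_fixture(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate everything and write a file bundle readable by the io
    module: GTF, genome FASTA, expression + sample-metadata TSVs, repeat
    BED, PWM file, and ground-truth tables. Byte-identical for identical
    config + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models, truth = simulate_annotation(config)
    genome = simulate_sequences(models, truth, config)
    expr = simulate_expression(models, truth, config)
    repeats = simulate_repeats(models, truth, config)
    paths = {
        "gtf": out / "annotation.gtf",
        "fasta": out / "genome.fa",
        "expression": out / "expression.tsv",
        "sample_meta": out / "sample_meta.tsv",
        "bed": out / "repeats.bed",
        "pwms": out / "pwms.tsv",
        "truth_switching": out / "ground_truth.tsv",
        "truth_events": out / "ground_truth_events.tsv",
        "config": out / "config.yaml",
    }
    iio.write_gtf(models, paths["gtf"])
    iio.write_fasta(genome, paths["fasta"])
    expr.values.rename_axis("transcript_id").to_csv(paths["expression"], sep="\t")
    expr.meta.reset_index().to_csv(paths["sample_meta"], sep="\t", index=False)
    iio.write_bed(repeats, paths["bed"])
    iio.write_pwms(config.planted_motifs, paths["pwms"])
    sw = pd.DataFrame([(g, tc, tn, eff) for g, (tc, tn, eff)
                       in sorted(truth.switching.items())],
                      columns=["gene_id", "tc_id", "tn_id", "effect"])
    sw.to_csv(paths["truth_switching"], sep="\t", index=False)
    ev = pd.DataFrame([(e.gene_id, e.kind, e.inclusion_tx, e.exclusion_tx,
                        e.chrom, e.strand,
                        e.intron[0] if e.intron else "",
                        e.intron[1] if e.intron else "", e.nuclear)
                       for e in truth.events],
                      columns=["gene_id", "kind", "inclusion_tx",
                               "exclusion_tx", "chrom", "strand",
                               "intron_start", "intron_end", "nuclear"])
    ev.to_csv(paths["truth_events"], sep="\t", index=False)
    cfg = asdict(config)
    cfg["planted_motifs"] = [p.motif_id for p in config.planted_motifs]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
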