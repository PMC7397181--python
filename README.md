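# isoloc

Analysis of transcript localization between the nucleus and the cytoplasm
from subcellular-fraction RNA-seq quantifications, for researchers studying
how alternative splicing shapes where an RNA ends up. Different isoforms of
one gene can sit in different compartments: spliced, protein-coding
isoforms are exported to the cytoplasm while unspliced or
intron-retaining variants stay nuclear. `isoloc` implements the full
quantitative workflow on transcript-level TPM tables, together with a
synthetic-data generator that plants every effect the pipeline is designed
to detect, so each stage is testable against a known ground truth.

## The statistics at the core

**Transcript usage switching.** For transcript *T* of gene *G* with TPM
abundances per fraction,

    ΔTU = T_cyto / G_cyto − T_nuc / G_nuc,

where gene TPM is the sum of its transcripts' TPM. ΔTU > 0 marks
cytoplasm-enriched isoforms. Significance is an empirical two-sided tail
p-value against a between-replicate null (within-fraction replicate
differences of TU, pooled over transcripts binned by gene expression, and
variance-rescaled to the replicate-mean scale). A gene's switch pair is

    Tc = argmax { ΔTU_i | ΔTU_i > 0.2, p_i < 0.05 },
    Tn = argmin { ΔTU_i | ΔTU_i < −0.2, p_i < 0.05 },

emitted only when both exist. Downstream comparisons: length-ratio
categories with a binomial test, exon counts (Mood's median test),
mono- vs multi-exonic ΔTU (Welch's t), coding vs noncoding ΔTU, and NMD
sensitivity (log2 fold-change under NMD-factor knockdown) between Tc and
Tn members.

**Splicing-event inclusion.** Local events of seven kinds — A3, A5
(alternative 3′/5′ splice site), AF, AL (alternative first/last exon), MX
(mutually exclusive exons), RI (retained intron), SE (skipped exon) — are
classified from the annotation by pairwise exon-chain comparison. Per
event,

    Ψ = ΣTPM_inclusion / (ΣTPM_inclusion + ΣTPM_exclusion),
    ΔΨ = Ψ_cyto − Ψ_nuc,

so negative ΔΨ means the inclusion form prefers the nucleus. Nuclear RIs
are retained introns with ΔΨ < 0 and p < 0.05.

**Intron characterization.** Nuclear RIs are compared with the all-RI
background on splice-boundary base composition (per-position
total-variation distance), length (Welch's t on log10), mean stem
probability from a uniform-energy McCaskill partition function over nested
RNA secondary structures (validated against exhaustive enumeration), and
normalized dinucleotide frequencies. PWM motif scanning (exact
score-quantile thresholds via dynamic programming) and repeat-class
overlap, both with label-permutation significance and BH FDR, quantify
RBP-binding and transposable-element enrichment.

## Worked example

```sh
python examples/02_call_switches.py
```

```
switch pairs called: 98 (recall 0.99, precision 1.00 vs ground truth)
length-ratio categories: {'positive': 0, 'negative': 7, 'neutral': 91} (binomial p = 0.0156)
mono- vs multi-exonic ΔTU: means -0.50 vs +0.02, Welch p = 1.09e-32
```

On a 200-gene synthetic study with ~100 planted switches (|ΔTU| = 0.5,
10% replicate noise, 3 replicates per fraction), the caller recovers 99%
of planted switching genes with no false pairs. The mono-exonic group mean
of −0.50 against +0.02 for spliced isoforms reproduces the planted
pattern that unspliced transcripts stay nuclear. The other examples cover
fixture generation (`01`), the kind-specific ΔΨ pattern with nuclear bias
planted only in retained introns (`03`), nuclear-RI length/structure/GC
signatures (`04`), and motif plus repeat enrichment (`05`).

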