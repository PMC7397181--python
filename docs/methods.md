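# Methods

## Scope and data model

The pipeline starts from transcript-level TPM quantifications of
subcellular-fraction RNA-seq (cytoplasm and nucleus, replicated) plus a
gene annotation; read mapping and abundance estimation are upstream and
out of scope. Internally all coordinates are 0-based half-open; the GTF
convention (1-based closed) is converted exactly once at the I/O boundary.
Minus-strand sequence extraction reverse-complements, so every sequence
analysis sees the transcribed strand; T is mapped to U only for PWM
scanning and structure, while stored genomic sequence keeps the DNA
alphabet.

Gene-level TPM is the sum of the gene's transcript TPMs. This makes
transcript usage (TU) sum to exactly 1 per gene and fraction and ΔTU sum
to 0, which the tests assert to 1e-9.

## ΔTU, empirical significance, and switch pairs

TU point estimates use replicate-mean TPM per fraction. Genes below an
expression floor (default 1 TPM summed over isoforms, in either fraction)
are excluded from usage calling rather than producing NaNs; the count is
logged. A documented discrepancy in the source conventions for the switch
threshold (0.2 in the selection rule, 0.25 in one figure) is resolved by
making it a parameter with default 0.2.

The empirical null for ΔTU is built from within-fraction between-replicate
TU differences, all replicate pairs in both fractions, pooled across
transcripts binned by log10 gene TPM (5 quantile bins by default). Because
the observed ΔTU contrasts means of R_c and R_n replicates while each null
value contrasts two single replicates, null values are rescaled by
sqrt((1/R_c + 1/R_n)/2), which equates the two variances under the
delta-method approximation. p = (1 + #{|null| ≥ |obs|}) / (1 + N). The
rescaling is what makes null p-values uniform (KS-tested in the
acceptance suite) instead of conservative; with 3+3 replicates and 10%
TPM noise the realized false-positive rate at nominal 0.05 stays within
[0.04, 0.07] across seeds. The same scheme, binned by event expression,
provides ΔΨ p-values.

Ties in Tc/Tn selection break by lexicographic transcript id. NMD
sensitivity is the direct pseudo-counted log2 fold-change
log2((TPM_kd + 0.01)/(TPM_ctrl + 0.01)) on replicate means; no posterior
fold-change machinery is used, since only the Tc-vs-Tn location contrast
matters here.

## Event classification

Events are generated from unordered transcript pairs within a gene and
deduplicated by (kind, coordinates). The rules are mutually exclusive by
construction: A3/A5 require the alternative exons downstream/upstream of
the shared boundary to overlap, which excludes SE (skipped exon between
junctions) and MX (disjoint exons) from misclassifying as splice-site
shifts; RI requires an exon strictly containing another isoform's intron;
AF/AL require differing, non-overlapping terminal exons sharing their
junction into the gene body. 3′/5′ polarity is strand-resolved.

Inclusion/exclusion sets are then assigned gene-wide by coordinate test,
so Ψ uses all isoform evidence, with conventions: RI — the retaining form
is inclusion; SE — the exon-containing form; A3/A5 — the shorter-intron
form; MX — the form using the 5′-proximal exon; AF/AL — the form using
the 5′-/3′-distal terminal exon. A transcript matching both sides of an
event discards that event (counted in the residual table), as do pairs
whose differing junctions yield no classified event. The classifier is
checked two ways: against a definition-level junction-set oracle on all
two-isoform genes with ≤ 6 exons, and by ≥ 99% planted-kind recovery on
1,000+ generator-planted events.

Ψ uses replicate-mean TPM with a 1-TPM floor on inclusion+exclusion
abundance per fraction; under-floor events are skipped and counted.

## RNA structure model

Stem probabilities come from a McCaskill-style inside–outside computation
over nested secondary structures with a uniform pairing model:
Watson–Crick plus GU wobble, minimum hairpin loop 3 nt, no pseudoknots,
and one Boltzmann weight q per pair. q = e² by design: with that weight a
single planted ~30-bp helix dominates its local ensemble (a 12-nt
GGGG/CCCC hairpin reaches mean pairedness > 0.5) while unstructured
sequence stays near 0.5, giving the comparative statistic headroom in both
directions. The statistic is only ever used relatively (one intron set vs
another), so no thermodynamic (Turner-rule) accuracy is claimed; the
partition function is validated to 1e-9 against exhaustive enumeration of
all nested structures for sequences up to 12 nt, where enumeration is
exact. Numerics: per-base rescaling of the inside/outside matrices with an
adaptive scale factor retried on overflow/underflow; O(n³) time via
running outside sums; numba-compiled.

Long sequences are scored on a centered window (cap 2,000 nt by default;
set-comparison profiling uses 400 nt), which also keeps long and short
intron sets on one scale — per-base pairedness grows with the number of
available partners, so a fixed window avoids a length artifact in the
nuclear-vs-background comparison. Intron length comparisons use log10
scale (lengths are heavy-tailed, roughly geometric here and log-normal-ish
in real annotation).

## Motif and repeat enrichment

PWM scanning is a log-odds scan against a uniform background on the sense
strand only (RBPs bind RNA). The hit threshold is the smallest achieved
score whose exact upper-tail mass, computed by dynamic programming over
the score distribution of a uniform random k-mer, is ≤ 1 − quantile
(default quantile 0.95); the DP is validated against full 4^k enumeration.
Motif density is hits per kilobase of scannable positions (L − k + 1), so
intron sets with different length distributions compare without edge bias.

Significance for both motif density and repeat overlapped-base fraction is
by label permutation preserving set sizes, two-sided on the density
difference, with BH adjustment across features. Permutation assumes
exchangeability: when the two intron sets have very different length
distributions the permutation variance misstates the observed one, so the
enrichment fixtures use matched length distributions and the report should
be read with that caveat for strongly length-confounded inputs. A
consistency report lists features enriched (ratio > 1, q below threshold)
in at least a configurable fraction (default 0.8) of several result sets.

## Statistical tests

Mood's median test dichotomizes at the pooled grand median with ties
assigned to the ≤ row, then uses chi-square with continuity correction
when all expected counts are ≥ 5 and Fisher's exact test otherwise;
degenerate inputs (all values at the median) return p = 1 with a warning.
The binomial test is the exact two-sided sum of point probabilities ≤ the
observed one; gene-set enrichment is the hypergeometric upper tail with BH
FDR (default 0.001), over user-supplied sets only. All tests are
oracle-checked against closed forms or enumeration, and their type-I
error is simulation-checked at ≤ 1.5× nominal.

## Synthetic studies

The generator is first-class, tested code; its defaults are the study
conditions. Each gene gets 4–7 exons (80–250 nt), introns from a shifted
geometric distribution (background mean 1,500 nt, minimum 60 nt), a random
strand, and one planted local event built by explicit exon-structure edit
(RI fuses two exons; SE drops an internal exon; A3/A5 shift an
acceptor/donor by 12–40 nt; AF/AL add a non-overlapping terminal exon; MX
places an alternative internal exon inside a widened intron). Every intron
of every isoform carries GT..AG on the transcribed strand.

Gene expression is log-uniform over [1, 1000] TPM; replicate TPMs are
mean-preserving lognormal draws at CV = noise_cv (default 0.1, 3
replicates per fraction), so the noiseless limit recovers planted ΔTU and
ΔΨ exactly. Each gene takes exactly one role: TU-switching (default half
of genes, |ΔTU| 0.5, with 20% of those carrying an unspliced nuclear
isoform and nuclear-side isoforms enriched for the noncoding biotype),
nucleus-biased RI (Ψ_nuc − Ψ_cyto = 0.4; these genes are genuine switches
too and are recorded as such), or neutral. Nuclear-RI introns are planted
short (mean 150 nt), GC-boosted (+0.15), with an exact inverted-repeat
stem (30-bp arm, ≥ 4 nt loop) drawn at the intron's own composition so the
stem adds structure without a composition signal, and optional PWM
instances (default 3 copies per intron, motifs rejection-sampled to be
mutually dissimilar so planting one cannot enrich another). SINE repeats
are planted at 50% of nuclear RIs vs 10% of background introns; LINE, DNA
and LTR stay at the background rate.

What the generator does not emulate: read-level sampling noise and
coverage bias, realistic splice-site and branch-point sequence beyond the
GT..AG consensus, ORF/codon structure, real intron length and composition
distributions, correlated isoform structures across genes, and any NMD
signal (knockdown fold-changes are drawn independently of localization —
a planted null). Passing tests therefore demonstrate that the estimators
recover their own model's planted parameters at realistic noise levels,
not that real-data preprocessing artifacts are handled.

Fixture conventions used by the test and acceptance suites, chosen to
isolate each planted signal: switch-recovery and null-calibration runs set
ri_nuclear_frac = 0 so the planted switch count equals
n_genes × frac_switching_genes; boundary-composition comparisons set
ri_gc_boost = 0 (a GC shift is a composition signal, not a splice-signal
difference); motif- and repeat-enrichment runs use equal intron-length
distributions (ri_short_len = ri_bg_len = 500) because a fixed-length
repeat occupies a larger fraction of a shorter intron and permutation
exchangeability needs comparable lengths; the motif run also sets
ri_gc_boost = 0 so composition-driven chance-hit-rate differences do not
masquerade as binding preference. Problem sizes (90–1,100 genes, 20-seed
replications, 300–1,000 permutations) keep every suite run to seconds
while leaving the measured rates comfortably inside their acceptance
margins.

## Known limitations

Empirical p-values share a null pool across transcripts within expression
bins and are duplicated between a gene's two isoforms (ΔTU of a
two-isoform gene is antisymmetric), so calibration diagnostics use one
transcript per gene. The event classifier targets the seven local kinds;
nested or combinatorial differences beyond them land in the residual
table. The structure model ignores stacking context and loop-type
energies. The config-file interface covers paths, sample metadata and the
documented analysis parameters; an optional minimum-transcript-length
input filter exists and defaults to off.
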