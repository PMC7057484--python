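# Methods

## Genome and karyotype model

The hexaploid genome is 21 chromosomes `1A`..`7D` (plus `Un` for
unplaced scaffolds), each 600 Mb in the synthetic coordinate system.
Internal coordinates are 0-based half-open; GFF3 I/O is 1-based
inclusive and BED 0-based half-open, converted at the boundary, so
interval arithmetic inside the package is unambiguous. Strand is parsed
where present but ignored: no analysis here is strand-dependent.

A `Karyotype` is a baseline copy number (2 for a disomic hexaploid)
plus non-overlapping overrides on chromosomes or intervals. A gene's
dosage is resolved by its interval **midpoint**: a gene straddling a
segment boundary belongs to the segment iff its midpoint does. This is
a deliberate design choice — midpoint assignment is deterministic,
order-free and independent of gene length; the alternative
(any-overlap) inflates segment membership by partial genes. The five
built-in genotypes are euploid, M4B (4B×1), Tri4B (4B×3), SegT2A (the
first 30% of 2A at ×4, standing in for a short-arm segment) and
N7B+SegT2A (7B×0 plus the segment).

## Synthetic data generator

The simulator emulates a bulk RNA-seq experiment on sibling plants of
the five karyotypes. Per gene:

* euploid expected count `base ~ LogNormal(meanlog 5.0, sdlog 1.5)`
  (median ≈ 150 counts; over ~42k genes this corresponds to ≈ 10⁷
  fragments per library, a realistic bulk depth and consistent with the
  "power ≈ 1" regime the recovery analyses assume);
* gene length `~ LogNormal(7.6, 0.45)` nt (median ≈ 2 kb), floor 150;
* a **responding** flag (default Bernoulli 0.85, reflecting that most
  genes on an aneuploid chromosome track copy number; exact per-
  chromosome counts can be pinned via `responding_counts`);
* observed counts `NB(mu = lib × expected, var = mu + α mu²)` with a
  single dispersion α = 0.05 by default (optionally per-gene
  log-normal); α = 0 degenerates to Poisson. Library factors are
  log-normal with sdlog 0.15.

A responding gene's expected count under dosage *d* is
`base × d/2`. Triads are built by pairing equal-rank genes across the
three chromosomes of each homeologous group (default: half of all
genes), sharing a triad-level base mean times a per-member log-normal
jitter (sdlog 0.25; 0 gives perfectly balanced triads). The
`compensation` coefficient c ∈ [0,1] models *active* buffering: the
unaffected sisters of a cis-affected member are scaled by
`1 + c × deficit / sister_base_sum`, so at c = 1 the triad's expected
total is genotype-invariant, and at c = 0 buffering is purely passive
(a balanced triad under monosomy of one member keeps 5/6 of its
total). Trans-effects (multiplicative log-normal perturbations of genes
*off* the varied chromosome in aneuploid genotypes) are available but
default to none — no magnitude for them is established, and the
downstream analyses are cleaner to validate without them.

All draws flow from one `numpy.random.Generator(seed)`; a config + seed
pair is bit-reproducible. The simulator does **not** emulate read-level
artifacts (mapping bias, multi-mapping between homeologs, GC effects,
isoforms) or correlated biological replicate structure; passing
recovery tests therefore demonstrates correctness of the statistical
pipeline under the stated generative model, not robustness to alignment
artifacts in real data.

## Quantification

FPKM = `1e9 × count / (sample_total × length_nt)`, with the per-sample
grand total as denominator (no effective-length correction — gene-level
counting is assumed). Genotype averages are arithmetic means over
replicates. The expression filter keeps genes with genotype-averaged
FPKM **strictly** greater than 1 in at least one genotype; the strict
inequality follows the "greater than unity" rule, and boundary cases
are measure-zero in float data. Replicate QC reports pairwise Pearson r
and R² on log₂(FPKM+1).

## Ratio profiles and loess

Ratios are log₂ of genotype-averaged FPKM (not per-replicate), computed
only for filtered genes; non-finite ratios (zero numerator or
denominator, e.g. silenced genes under nullisomy) are excluded with a
logged count. The smoother is loess with tri-cube weights, local
degree 2 (configurable), span 0.1 and no robustness iterations,
evaluated at every gene position. Each local fit uses the
`ceil(span·n)` nearest points (stable argsort tie-break), x centred at
the target and scaled by the window radius for conditioning, solved by
weighted least squares. A span is a *fraction of points*, not a
physical bin width. With fewer than degree+2 points the fit falls back
to a global polynomial with a warning. Degree-1 fits are convex
combinations of the data, hence bounded by the raw ratio range; the
degree-2 default can locally overshoot, which is the usual loess
behaviour.

## Dosage correlation

Per gene, Pearson r between per-replicate FPKM and the replicate's
genotype dosage, every replicate an independent unit; two-sided p from
`t = r√(n−2)/√(1−r²)` with n−2 df; BH adjustment across all *testable*
genes. Genes with constant dosage across the included genotypes (i.e.
genes off the varied chromosome) or constant FPKM are untestable and
excluded from the adjustment — so in a single-chromosome panel the FDR
is controlled over the varied chromosome's genes. "Positively
dosage-correlated" means r > 0 **and** padj < 0.05: significance is
two-sided, the sign filter applied afterwards.

## Differential transcription (NB Wald)

A transparent reimplementation of the standard NB count test:

* **Size factors**: median-of-ratios over genes with nonzero counts in
  all samples (optional pseudo-reference fallback for sparse data).
* **Dispersion**: per-gene method-of-moments `(s² − m)/m²` pooled over
  replicate groups (weights n−1), floored at 1e-8, then shrunk in log
  space (weight 0.5) toward a mean–dispersion trend `a₀ + a₁/μ` fitted
  by least squares over informative genes. The shrinkage stabilises the
  3–4-replicate estimates enough for the Wald test to hold its size
  (verified empirically on null simulations in the suite).
* **Wald test**: LFC = log₂ of normalized group means with a ½
  pseudocount (so one-sided zeros stay finite);
  `SE = (1/ln2)·√((1/m₁+α)/n₁ + (1/m₂+α)/n₂)` by the delta method;
  two-sided normal p; BH over tested genes (zero-in-both-groups genes
  excluded), restricted to the expression-filtered set when one is
  supplied. A DTG has padj < 0.05.

Exact numerical parity with DESeq2 is *not* claimed — no GLM fitting,
no Cox–Reid adjustment, no outlier handling — but the test is unbiased
under the null and directionally faithful, which is what the
chromosome-level Down/Up asymmetry analyses require.

## Triad analysis

Triad totals are per-sample sums of member FPKM (missing members
contribute zero). A triad is *expressed* when its euploid genotype-mean
total exceeds 1 — the euploid is the reference state of every
contrast, so expression status does not flip between contrasts.
Relative contributions (a,b,d) divide genotype-mean member FPKM by the
genotype-mean total. Classification assigns the nearest of seven
centroids in Euclidean distance — balanced (⅓,⅓,⅓), dominant corners,
suppressed edge-midpoints — with ties broken in the fixed order
balanced, A/B/D-dominant, A/B/D-suppressed. Categories are called on
**euploid** contributions (the reference state); aneuploid
contributions are reported alongside. DTTs come from a one-way ANOVA
on per-replicate triad totals across the contrast's genotypes, BH-
adjusted over expressed triads, flagged at padj < 0.05. (Applying the
0.05 threshold to adjusted rather than raw p is the stricter of the
two conventions in circulation; both values are reported.)

## Problem sizes and numerical choices

The recovery analyses in the test suite and the acceptance script use
2000–2171 genes per chromosome with 4 replicates (the dosage-ratio and
dosage-correlation panels) and 1000 balanced triads per homeologous
group with 3 replicates (the buffering panel); the property suites use
~5000 genes/triads over 10–20 seeds. These sizes give medians and
fractions with Monte-Carlo error well inside the tolerances being
checked while keeping a full run under a minute. Note that because
FPKM normalizes by the sample total, an aneuploid chromosome shifts
every gene's FPKM slightly (by ≈ log₂(21.5/21) ≈ 0.03 for one trisomic
chromosome in 21); this is a property of the measure itself, visible in
real data too, and is why recovered medians sit at e.g. 0.55 rather
than exactly 0.585.

## Known limitations

* Two-group contrasts only in the DE stage; no multi-factor designs.
* No confidence bands on loess curves; no changepoint detection of
  dosage boundaries.
* Dyads (1:1:0 homeolog groups) and nonsyntenic triads get no special
  handling beyond the syntenic flag.
* The simulator's independence assumptions (genes, replicates) make
  FDR behave ideally; correlated real data will be less clean.
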