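# Methods

## Scope and data model

The package analyses probe-level, log2-scale ChIP signal on ~250 bp
tiling arrays over a compact, yeast-like genome. All coordinates are
0-based half-open; a probe is represented by the integer floor of its
interval midpoint everywhere (binning, classification, end windows).
Genes are stranded coding-region intervals; the translation start (ATG)
anchors all upstream distances, and "upstream of a − strand gene" lies
genomically rightward of it.

## Turnover signal

Turnover is log2(Flag-H3 / total-H3) per probe. Whether the input
channels are linear or already log2 is an explicit argument to
`log2_turnover`, never guessed.

**Normalization** is per-track median centering of the log2 values: the
minimal location correction for two-colour log-ratio data, chosen
because the package deliberately excludes image-level and spatial
normalization (see Limitations). It is idempotent and leaves the median
exactly 0 (to one floating rounding when the probe count is even).
Replicates are averaged probe-wise on the log2 scale — the scale on
which profiles are displayed — and the averaged track is re-centered so
the emitted track keeps a zero median.

## Element classes

Each probe midpoint receives exactly one class (a partition, verified by
a counting invariant):

| class | rule |
|---|---|
| 5′/3′ CDS | within the first/last 500 bp of a coding region |
| midCDS | any other in-gene probe |
| TSS | ≤500 bp upstream of an ATG (strand-aware) |
| Promoter | further upstream |
| ARS | ≤200 bp from a replication origin, outside the above |
| Null | everything else (mostly between convergent genes) |

Three rules the class definitions leave open are fixed deterministically:
precedence is CDS ≻ TSS ≻ Promoter ≻ ARS ≻ Null; inside a CDS shorter
than 1 kb the nearer end wins with exact-center ties going 5′; a probe
upstream of two divergent genes belongs to the nearer ATG. All three are
package conventions, not measured facts; the window sizes (500/500/200
bp) are the field's standard definitions and are arguments.

## Metagene profiles

The 30-bin frame is 10 fixed 50 bp bins upstream of the coding start
(bin 0 farthest) plus 20 body bins of 5% increments, so gene bodies of
any length align. The canonical anchor in the field is the +1 nucleosome;
lacking a nucleosome map, the annotated coding start is used as its
proxy — profiles near the TSS therefore mix a small amount of what a
nucleosome-anchored frame would split. Bins are half-open; a probe on a
boundary joins the higher-index (downstream) bin. A bin with no probe is
absent (NaN), never zero, and contributes nothing to aggregation.
Aggregation averages per gene first and then across genes, so every gene
weighs equally regardless of probe count; the alternative (per-probe
pooling) overweights long genes in fixed-width upstream bins.

## Gene-end length scans and the crossover estimator

The end statistic is the mean signal over the terminal 500 bp of the
CDS (clamped to the whole CDS for shorter genes; absent, not zero, when
no probe falls inside). Genes are ordered by length with ties broken by
gene id, and k-gene sliding windows (step 1, k = 80 by default) trace
the statistic per genotype; each window reports its median gene length.

`estimate_crossover` returns the median gene length of the first window
whose mutant−wild-type difference exceeds a threshold for m consecutive
windows. Two numerical choices matter and were set after explicit
null-behaviour analysis:

- **Threshold.** By default the difference is measured relative to its
  mean over the shortest quartile of windows and must exceed twice that
  quartile's window SD. The baseline subtraction is essential: per-track
  median centering leaves a small constant genotype offset in the
  difference series which must not count as divergence.
- **Persistence.** Adjacent windows share k−1 genes, so window noise is
  strongly autocorrelated and isolated threshold excursions come in long
  runs; a short persistence requirement misfires on null data in a
  large fraction of seeds. The pipeline therefore requires the
  excursion to persist for one full window of genes (m = k). Monte-Carlo
  at the working scale (3000 genes, 20 seed pairs of independent
  wild-type data): ≥18/20 null runs yield no call; with the default
  divergent model, 20/20 runs recover the injected 1 kb crossover within
  one window's gene-length span (~60–80 bp at 1 kb).

Stratified scans split genes into tertiles of a wild-type covariate
(typically mean Pol2 enrichment as a transcription proxy; ties break by
gene id, group sizes differ by at most one) and trace the per-tertile
difference series. A generic k-gene moving average (k = 20 for
expression-versus-length checks, k = 50 for mark-versus-length) serves
the remaining smoothing needs.

## Mark and Pol2 statistics

The 3′ mark gain is the per-gene mutant−wild-type difference over the
3′-terminal 500 bp, averaged within gene-length classes (short <1 kb,
long 1–2 kb, extremely long >2 kb — conventional boundaries, exposed as
configuration). Pol2 summaries reduce each gene to mean enrichment and
a 5′ bias = (5′-end enrichment)/(3′-end enrichment) computed on the
linear scale (log2 tracks are exponentiated first), so a uniform track
has bias exactly 1; genes shorter than 500 bp have identical end
windows and bias 1 by construction. Concordance between genotypes is
ordinary least squares of mutant on wild type (slope, intercept,
Pearson r); OLS is the convention here because the wild-type axis is
treated as the reference condition, not an error-free covariate.

## qPCR arithmetic

IP/Input = E^(InputCt − IPCt) with amplification efficiency E defaulting
to 2 (perfect doubling); a turnover ratio divides the enrichments of two
channels of the same amplicon. Both are exact closed forms; the
generator's `simulate_qpcr` inverts the formula, so a zero-noise
round trip recovers the injected IP fraction to machine precision.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume;
it is the package's test bed, not a microarray simulator.

**Genome.** 8 chromosomes × 1.25 Mb holding 3000 non-overlapping
stranded genes with ≥800 bp intergenic spacing; lengths log-uniform on
0.25–5 kb so long genes are densely represented across the whole length
axis. 40 replication-origin intervals sit in intergenic gaps. Probes
tile every chromosome end to end at 250 bp (length 51 bp, so probe
midpoints mirror exactly under coordinate reflection — convenient for
strand-symmetry tests). Packing that cannot fit raises an error naming
the violated constraint.

**Turnover field.** Expected log2 turnover is built per gene:
upstream, an exponential rise toward the promoter peak
(`promoter_level` 1.2, decay 400 bp, intergenic far-field 0.2); inside
the body, a floor (−0.6) plus the larger of a 5′ exponential tail
(entry level promoter −0.25, decay 300 bp) and a 3′ exponential tail
(decay 400 bp) toward a 3′-end level that falls linearly with
log2(gene length) (slope −1.8 per log2, capped at 1.0). The mutant
applies a 5′/promoter deficit (−1.0) and freezes the 3′-end level at
its 1 kb value (0.6) for genes longer than the 1 kb crossover; below
the crossover the genotypes' 3′ ends are identical probe by probe (the
5′ deficit is excluded from the terminal 500 bp to keep that exact).
Gaussian noise (SD 0.3 log2) is added independently per probe and
replicate; three replicates per genotype. Gene bodies are assigned
directly (genes never overlap); intergenic probes take the maximum over
neighbouring promoters' contributions, so divergent promoters merge and
a promoter tail never dilutes a neighbouring gene body.

The magnitudes are free parameters of a stylized model. The 3′ slope is
deliberately steep: it was fixed once, from a power analysis of the
detection rule the package itself uses (2×SD threshold, 80-gene
windows, 3 replicates at noise 0.3), so that the injected crossover is
recoverable within one window span — with a field-realistic slope
(~0.2–0.3 per log2) this detector's bias and jitter exceed that
tolerance, which is worth knowing when applying the estimator to real
data.

**Marks.** H3K4me3 and H3K36me3 are Gaussian bumps in the 30-bin
metagene coordinate (peaks at bins 11.5 and 24, i.e. 5′- and 3′-biased;
wild-type K4 always peaks 5′ of K36). The mutant shifts the K36 peak 2
bins toward 5′ and additionally depletes the 3′-terminal signal by
0.25 × (1 + log2(L/250)) log2 units — length-coupled, so the loss is
strictly ordered short < long < extremely long. A larger peak shift
would break that ordering: the 3′ 500 bp window overlaps the peak
region only at mid-length genes, making shift-induced loss
non-monotone in length.

**Pol2.** Each gene draws a log2 mean enrichment (N(1.0, 1.2²)) and a
log2 5′/3′ tilt (N(0.4, 0.6²)) once; the body profile is linear in
position with that tilt, intergenic level −1. In null mode the mutant
reuses the wild-type draws, so only probe noise (SD 0.06) differs. The
spread/noise ratio is deliberately large because the model encodes a
*tight* concordance null: errors-in-variables attenuation pulls the OLS
slope to Var(T)/(Var(T)+Var(N)), and heavy lognormal tails inflate
slope sampling variance, so a noisy generator would make slope ≈ 1
unattainable regardless of the analysis code.

**Expression.** Per-gene log2(mut/wt) expression changes are pure noise
around zero — the scenario in which expression changes correlate with
neither length nor transcription.

**What the generator does not emulate** (and hence what green tests do
not demonstrate about real arrays): dye bias, spatial/print-tip
artifacts, probe GC/affinity effects, amplification bias, MNase
digestion bias, correlated noise along chromosomes, replicate batch
effects, overlapping or nested transcription units, and UTRs (the
"TSS" is the ATG). Results on real data additionally depend on the
upstream normalization these tracks are assumed to have received.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline derives
per-stage substreams from the master seed by hashing, so stages are
independently reproducible and any derived seed stays below 2^31. Two
runs with the same config and seed are byte-identical. The default
problem sizes (3000 genes, ~40 k probes, 20-seed Monte-Carlo for the
crossover check) are the package's working scale: large enough that
window statistics are in their asymptotic regime, small enough that the
full pipeline runs in seconds and the complete test suite in well under
a minute of compute per heavy test.

## Known limitations

- The crossover estimator reports the first window exceeding a
  threshold, so its estimate carries a positive bias of roughly
  (threshold)/(divergence rate); it is a change-point *detector*, not an
  unbiased change-point estimator.
- Median centering cannot remove intensity-dependent (loess-type) or
  spatial artifacts; tracks from real arrays should arrive already
  normalized at that level.
- The ARS class is rarely populated when origins sit near promoters,
  because upstream classes take precedence; with the default toy genome
  only a handful of probes classify as ARS.
- `three_prime_level` treats gene length through log2(L/crossover);
  lengths equal to 0 are impossible by construction (BED validation
  rejects empty intervals).
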