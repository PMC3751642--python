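# Methods

This note documents the models, algorithms, defaults and design choices
behind `acgh_cnv`, and what the synthetic test bed does and does not show
about real array data.

## Measurement model

A two-color CGH array reports, per probe, y = log2(test/reference). For a
locus at integer copy number c against a diploid reference the expected
value is log2(c/2); c = 0 is floored at −4 log2 units because real arrays
saturate rather than report −∞. The simulator generates

y_i = μ(c_i) + b·(z_i² − E z²) + w_i + ε_i,

where μ is the dosage term over the probes overlapping an implanted CNV
(a probe belongs to a CNV if its interval overlaps it by ≥ 1 bp), z_i is a
per-probe mean-signal covariate (standard normal), b a dye-bias amplitude
(default 0.05 log2 units in the default scenario), w an optional AR(1)
"genomic wave" (off by default, marginal SD `wave_sd`, lag-1 correlation
0.98) and ε i.i.d. Gaussian with per-array SD `noise_sd`. No per-array
noise magnitude is dictated by the data model, so `noise_sd` is a scenario
parameter; the default 0.10 sits in the range typical of good-quality
two-color arrays, and 0.05/0.15 variants are used in tests for
easier/harder regimes.

Coordinates are 1-based inclusive everywhere except BED export (0-based
half-open). Printed interval sizes use the boundary convention
size = end − start, which is what makes the worked catalog coordinates
(e.g. 144,185,960–144,403,060 → 217.1 kb) reproduce their printed sizes;
overlap tests use inclusive overlap, min(ends) − max(starts) + 1 ≥ 1.
Keeping a single coordinate convention through the whole library, and
converting only at the BED boundary, was a deliberate simplification over
mixing 0-based internals with 1-based I/O.

## Default cohort

The default scenario mirrors a 15-line, 64-animal resource population
(four Red Jungle Fowl, five-animal experimental layer lines, small
commercial broiler/layer groups, three Silkies) on a chicken-like
karyotype — 31 chromosomes from 201 Mb macrochromosomes down to sub-Mb
microchromosomes plus Z and W — scaled to 1/20 length (~52 Mb, ~13,000
probes at 4 kb target spacing with 20% start jitter). The scale keeps the
full pipeline, including per-array lowess fits and threshold-grid
calibration, at interactive run times; all size-like statistics remain at
realistic per-CNV magnitudes because CNV sizes are *not* scaled.

Implanted variants per line: 2 line-fixed templates drawn at positions
disjoint across lines (this is what makes line identity recoverable), 6
segregating loci carried per sample with probability 0.5, and per-sample
private CNVs (binomial over 5 candidates at rate 0.3). Sizes are
log-uniform on 12–200 kb, giving a mean of ~50 kb, the scale typical of
array-resolution CNV catalogs. 75% of drawn variants are losses (losses
mostly 1 copy, occasionally 0; gains mostly 3, occasionally 4), matching
the loss-dominance such catalogs report relative to an inbred reference.
W-chromosome dosage is only meaningful for female samples; the reference
is modeled as matched-sex by default, with `reference_sex="F"|"M"` to
simulate a sex-mismatched reference (whole-Z/W offsets), which the
normalizer's per-sex-chromosome centering flag can remove.

## Normalization

Dye bias is removed by a robust locally-weighted (lowess) fit of y against
the covariate, followed by genome-wide median centering. Defaults: span
0.3, 3 robustifying iterations; the `delta` interpolation parameter is set
to 1% of the covariate range so the fit stays near linear-time on dense
grids. Robust iterations exist because CNV-bearing probes (a few percent
of the genome) would otherwise drag the trend toward their shifted values.
A constant covariate degenerates to the median. Per-chromosome centering
is restricted to Z and W and must be requested explicitly: centering
autosomes would erase genuine whole-chromosome dosage signal.

Two honest limitations, both visible in the tests: the local fit lags in
the sparse tails of the covariate distribution (beyond roughly the 97.5%
quantile), and normalization is only *approximately* idempotent — a second
pass refits a small part of the residual noise (measured at ~5% of the
first-pass change), which is inherent to any stochastic smoother rather
than a defect of this one.

## Noise estimation and calling

Per-array noise is estimated as sd = median(|y_{i+1} − y_i|)/(0.6745·√2).
Differencing removes regional shifts (a CNV of k probes perturbs only 2 of
its k+1 differences), and the scaled median gives a high-breakdown SD
estimate: 5% contaminated probes move it by well under 10%.

Calling is run-based: probes with y > +t·sd are gain candidates, y < −t·sd
loss candidates; maximal same-sign runs separated by at most
`max_gap_probes` sub-threshold probes are merged (a gap containing an
opposite-sign supra-threshold probe is never bridged, so one sample's
calls can never overlap); runs with fewer than `min_probes` member probes
are dropped; a call spans from its first probe's start to its last probe's
end. Boundaries therefore never extend beyond probe extents, making all
size statistics conservative and exactly reproducible. `min_probes = 2`
and `max_gap_probes = 1` are the defaults: two probes is the natural floor
on a 4 kb grid (it is exactly why a 3.2 kb variant — smaller than the
spacing — is structurally undetectable, covering at most one probe), and
single-probe dropouts inside real CNVs are common. sd is re-estimated on
each array at call time so thresholds track per-array quality.

The multiple t is not assumed: it is calibrated on self-self replicate
hybridizations (reference DNA in both channels), where every call is by
construction false. The calibrator scans an ascending grid (default 2.0
to 6.0 in 0.5 steps) and returns the smallest multiple whose mean
self-self call count is at most `target_false_calls_per_array` (default
1.0); if none qualifies it returns the largest grid value with a warning
flag rather than failing. At the default scenario's scale this lands at
t = 3.0 with zero residual self-self calls.

Deduplication across samples uses exact (chromosome, start, end, class)
identity — the same interval called gain in one sample and loss in
another stays two records — with overall and per-line occurrence counts.

## CNVR catalog

CNVRs are the transitive union of unique CNVs overlapping by ≥ 1 bp
(shared endpoints count, under inclusive coordinates), class-blind for
extent; a region whose members include both classes is typed "both".
Region extents clip to member extremes rather than extending to probe
boundaries. No reciprocal-overlap fraction is imposed — the 1 bp criterion
is the catalog-union convention this construction follows. Catalog
statistics: mean sizes over all and over recurrent (occurrence ≥ 2) CNVs,
summed region extent as coverage, coverage/genome length as percent, loss
fraction, and per-line mean call counts. The genome length is a parameter
(defaulting to the probe map's genome) because coverage percentages are
only meaningful against a stated assembly length. Gene annotation assigns
a gene to a region on any ≥ 1 bp overlap, complete or partial, and counts
each gene once in the unique total however many regions it straddles.

## Fixation and clustering

Carrier status for fixation is *region-level*: a sample carries a CNVR if
it carries any member CNV, because members of one region differ in exact
extent across samples and exact-coordinate identity would undercount
carriers. A region is fixed in a line iff every sampled animal of that
line is a carrier; line-specific iff fixed in exactly one line and — in
the default strict mode — carried by nobody outside that line. A lenient
mode (`strict_specific=False`) drops the outside-carrier condition, since
the operational rule behind published "line-specific" labels is usually
not printed; the strict reading is the default because it is the one the
word "specific" implies. With small per-line sample counts (2–8 here),
fixation is an observation about the sampled animals, not a population
allele-frequency statement.

Clustering uses Jaccard distance on carrier (non-none) indicators by
default — two samples sharing no CNV at all are defined to be at distance
0, not NaN — with average linkage; Hamming on the three-valued states and
complete linkage are available. Samples are sorted lexicographically
before distance computation so the dendrogram is reproducible under ties.
The tree exports to Newick with non-negative branch lengths.

## Comparative overlap and qPCR

An external interval overlaps the catalog if any CNVR overlaps it by
≥ `min_overlap_bp` (default 1). When the probed chromosome set is given,
intervals on unprobed chromosomes are excluded from the denominator and
reported (the analogue of dropping a chromosome absent from the array
design); a probed chromosome without regions simply contributes misses.
Chromosome names are harmonized by stripping chr/GGA-style prefixes plus a
user alias table; cross-assembly liftover is out of scope and left to the
user.

qPCR copy numbers use the standard ΔΔCt arithmetic at perfect efficiency:
ΔΔCt = (Ct_target − Ct_refgene)_test − (Ct_target − Ct_refgene)_calibrator,
ratio = 2^(−ΔΔCt), copies = 2·ratio (the calibrator is taken as diploid),
reported both unrounded and rounded. Reference-gene normalization against
a single-copy gene follows Ct + (N't − C't)·S/S' with the standard-curve
slopes S, S'; a zero target slope passes Ct through with a warning, a zero
reference slope is an error. Slope-based efficiency correction beyond that
formula is deliberately not applied to the ΔΔCt step. Replicate wells are
averaged to mean Ct before any ratio.

## What the synthetic test bed does and does not show

The generator gives exact ground truth, which is what makes sensitivity,
false-call, fixation and clustering claims checkable at all. It does not
emulate: spatial array artifacts, probe GC/sequence effects, segmental-
duplication cross-hybridization, correlated waves beyond AR(1), population
relatedness within lines, or partial (mosaic) copy states. Passing tests
therefore demonstrate algorithmic correctness and calibration behavior
under the stated noise model — not expected performance on any particular
real array batch. Catalog-level percentages from the default scenario
(e.g. genome coverage) reflect the scenario's scaled genome and implant
rates and are internal-consistency quantities, not predictions.

## Numerical and degenerate-input choices

* sd = 0 (constant array) makes the threshold 0; every nonzero run is then
  called — documented degenerate behavior, not an error.
* An empty CNV catalog yields all-zero statistics with a warning.
* Occurrence matrices resolve a sample carrying both classes in one region
  to the largest member (ties: leftmost, then loss).
* Lowess trend values at non-finite probes fall back to the profile
  median; profiles with > 20% non-finite values are rejected.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical cohorts, catalogs and artifacts (verified down
  to file bytes in the tests).
* Problem sizes in the shipped tests and the acceptance script (1/20-scale
  genome for the cohort, one 80 Mb chromosome / 20,000 probes for the
  sensitivity experiment, 200 implants, 1,000-instance oracle batches)
  were chosen to keep a full run interactive on one CPU while leaving
  every statistical bound comfortably estimable.
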