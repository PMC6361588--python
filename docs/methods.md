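# Methods

## Enrichment model

The caller scores fixed windows (default 1000 bp, stepped by 200 bp; the
terminal window is truncated at the chromosome end, not dropped) by an
upper-tail test of the ChIP tag count against a negative-binomial null.
The null mean is the input window count scaled by the library-size ratio,
μ = (k_input + c) · N_chip / N_input, with pseudocount c (default 0.5)
guarding zero-input windows. The NB is parameterized by (mean μ, size r),
Var = μ + μ²/r. The reported statistic is z = Φ⁻¹(1 − p_upper) with
p_upper = P(X ≥ k); it is computed through the complementary normal
quantile so precision survives into the far tail, falls back to the moment
approximation (k − μ)/√(μ + μ²/r) when p underflows, and is clamped to
±38 (the double-precision limit of the quantile). Windows with z ≥ 6 are
merged into peaks when their gap is ≤ 1 kb (inclusive); a peak keeps the
maximum member z. The z threshold applies per window; a merged region's
z_max is reported but not re-tested. Significance is defined on the NB
tail rather than the moment statistic because the procedure couples an
explicit NB significance model with a z cutoff; the moment form is only
the documented underflow fallback.

The size parameter r is a free, data-dependent choice (in the original
procedure it was picked by inspecting calls). On synthetic data the
matched value is known analytically: a sum of n i.i.d. per-bp NB(m, s)
counts is NB(n·m, n·s), so the bench calls with
`window_nb_size(s, window_bp)` = s·window/resolution. The config default
r = 10 at window scale is deliberately conservative for external data
(heavier tail than most real window counts), which biases toward fewer
false peaks rather than calibrated p-values; the calibration experiments
always use the matched size.

## Synthetic bench

The generators define the study conditions rather than adjustable fits:

- Background depths 0.5 (ChIP) and 2.0 (input) tags/bp — an input library
  sequenced several-fold deeper than the ChIP, as is standard practice;
  the deeper input keeps the noise of the estimated μ small enough that
  the null z distribution stays close to standard normal (the calibration
  contract is agreement within 10× at z ∈ {2, 3}).
- Per-bp NB dispersion size 10. No dispersion estimate exists for real
  capture data of this kind at per-bp scale, so this is a simulation
  convention, exposed in `SimulationConfig`.
- Planted sites: 400 bp footprints, affinities uniform on (8, 15) —
  matching the recovery design's "affinity ≥ 8" condition — with the
  phospho subset taken from the top of the affinity distribution and given
  at least the median motif count of the rest. This mirrors the observed
  structure (the phospho-bound subset sits at stronger, multi-motif
  sites); it is a construction, not a causal model.
- Contact maps: E[i,j] = depth·(|i−j|+1)^(−α) with α = 1, times a
  depletion factor per crossed boundary, Poisson-sampled. Poisson (not NB)
  keeps the oracles analytic; capture Hi-C overdispersion is not modeled.
  A boundary index b separates bins b−1 and b, so both flanking insulation
  squares are fully cross-boundary and detection is exact only to that
  half-bin: tests accept {b−1, b}.
- Codon reads: a deterministic round(n·fraction) of reads carry GAG
  (glutamate), the rest TCC (serine), each base independently flipped at
  the error rate. The default mutant fraction 0.14 is the midpoint of the
  12–16% range the report stage reproduces; codons are configurable since
  the transgene spelling is a convention.
- The DE generator plants exactly 118 up / 257 down significant rows by
  default (the printed tally consumed by the report stage) among ~12,000
  null genes; only thresholding is in scope, never model fitting.

What the bench does *not* emulate: mappability and repeat structure, GC
bias, fragment-length effects, strand asymmetry, chromatin-state
covariates, or Hi-C matrix artifacts. Passing recovery tests therefore
demonstrates correctness of the computations under the stated stochastic
model, not robustness to real-library artifacts.

## Peak features

- Interval semantics are single-overlap (`-u`): a query peak is shared if
  it overlaps ≥ 1 bp of any subject peak, counted once; no reciprocal
  fraction. Motifs overlapping two peaks count for both. Per-peak coverage
  counts tags with any overlap of the peak interval.
- The PWM score threshold is the minimal t with background tail
  P(score ≥ t) ≤ p (default 3×10⁻⁵), computed exactly by dynamic
  programming after rounding per-cell log2-odds to a 1e-3 grid
  (configurable). Scanning uses unrounded scores, so hits near the
  threshold can differ from the grid by at most w·5e-4. PWM probabilities
  are floored at 1e-6 when forming log-odds so impossible bases score
  finitely; N scores −∞. For a PWM indistinguishable from background the
  cutoff is unreachable and a warning threshold above the maximal score is
  returned (zero hits).
- Wilcoxon rank-sum: exact enumeration (via scipy's exact method) when
  n₁+n₂ ≤ 20 and no ties; otherwise the normal approximation with tie and
  continuity correction. The result records the path taken.
- Annotation assigns each peak by its midpoint with priority
  promoter > 5′UTR > 3′UTR > exon > intron > downstream > intergenic;
  promoter is ±1000 bp of the TSS by default (the original annotation
  tool's setting is unknown; this is configurable), downstream the same
  width past the TES. A multi-category tool can report percentages that
  sum above 1; the midpoint rule cannot — a documented divergence.
- Metagene profiles rescale each gene body to a fixed number of bins with
  fixed-width flank bins, reverse minus-strand genes, and average with NaN
  masking at chromosome edges; genes shorter than the body bin count are
  skipped and counted.

## Insulation and TAD score

Only pairs with both ends inside the capture region are used.
Sqrt-coverage normalization divides M[i,j] by √(cov_i·cov_j) (row sums),
masks zero-coverage bins, and rescales to preserve the unmasked mean; the
downstream log2-ratio insulation is invariant to any global factor, which
is the reliable surface (the external viewer's exact scaling constant is
not reproducible from its description). Insulation at bin i sums the
square of contacts between the w bins strictly upstream and strictly
downstream (w = 125 kb / 25 kb = 5; the diagonal bin itself is excluded),
and values are log2 ratios to the mean over valid bins; bins within w of
an edge or with empty squares are masked. Raw square sums can additionally
be scaled per million capture-region reads for cross-sample comparison;
the log2 track is unchanged by that scaling.

Boundary detection uses the delta vector with d = 75 kb / 25 kb = 3:
delta(i) = mean(value[i+1..i+d]) − mean(value[i−d..i−1]); a boundary sits
at the smaller-valued of two consecutive bins where delta swings from
negative to non-negative, provided it is a local minimum. Its strength is
the mean of the flanking d-span maxima minus the value at the bin, clamped
at zero, with a configurable floor (default 0.1). The TAD score of a
domain is the mean strength evaluated at its two given boundary bins,
whether or not they were auto-detected. The upstream description defers
boundary/TAD scoring to an external script's defaults, so these formulas
are documented stand-ins; the validated contract is geometric (toy-matrix
minima at constructed boundaries) and monotone (score strictly decreasing
as boundary depletion weakens over five levels), not numerical equality
with that script.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere in memory and in BED/
  bedGraph; tag-pair files are 1-based on disk and converted on read.
- NB tails use `scipy.stats.nbinom.sf`; the test oracle sums an
  independently coded gammaln-based pmf (agreement < 1e-10 over
  k ≤ 500, μ ≤ 50, r ∈ {1, 5, 10, 50}).
- OLS R² is `scipy.stats.linregress` (intercept included); zero response
  variance returns NaN (flagged undefined) rather than raising.
- Window tiling: starts at multiples of the step while start+window ≤ L,
  plus one truncated tail window when those do not reach the chromosome
  end (a 10 kb chromosome yields 46 windows at the defaults).
- Merging is a sorted sweep, idempotent, with the gap test inclusive
  (gap = 1000 merges at the default).
- The pipeline derives stage seeds from the run seed by fixed offsets,
  stores manifest paths relative to the run directory, and writes no
  timestamps, so reruns are byte-identical.
- Problem sizes in the validation designs (10×10 Mb null genomes, 5×50
  planted sites on 2 Mb, 900 peaks for R², 200 rank-sum replicates, 58-bin
  contact maps) were chosen as the smallest scales at which the targeted
  effects are statistically unambiguous on a single CPU.

## Known limitations

- The caller's false-positive behavior under misspecified r is only
  characterized as conservative-when-r-too-small; no dispersion estimator
  is provided.
- Broad-domain (non-point-source) enrichment is not modeled; the NB window
  caller is the single calling path.
- The annotation and metagene utilities assume non-overlapping gene
  models; overlapping isoforms must be flattened upstream.
- Insulation boundary localization is intrinsically half-bin ambiguous at
  block-constant maps.
- The Wilcoxon exact path requires tie-free data; heavily tied count data
  always use the corrected normal approximation.
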