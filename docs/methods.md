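# Methods

This note documents the statistical procedures implemented in `l1regkit`,
the defaults and conventions chosen where a choice was genuinely open, what
the synthetic generators do and do not emulate, and the package's known
limitations.

## Resampling overlap enrichment (`setstats`)

Given a query gene set Q, a target set T and an expressed-gene universe U,
the test draws B random subsets of U of size |Q|, uniformly and without
replacement within each draw, independently across draws, and records each
draw's overlap with T.  The observed overlap k = |Q ∩ T| is standardised
against this null — z = (k − mean)/sd with the *sample* standard deviation
(ddof = 1, as R's `sd()`) — and converted to an upper-tail standard-normal
p-value.  Enrichment is the default direction; depletion is available via
`alternative="less"` but is not the default because the scientific question
is whether dysregulated genes are over-represented in a gene set of
interest.  No continuity correction is applied to z; consequently, on very
small discrete supports the normal p tracks the *mid-p* exact hypergeometric
tail (P[X > k] + P[X = k]/2) rather than the full tail — the test suite
checks exactly that correspondence.  When the resampled null is degenerate
(sd = 0, e.g. |Q| = |U|), the implementation falls back to the exact
hypergeometric upper tail and flags the result (`exact_fallback`), rather
than emitting an infinite z.

p-values are Benjamini–Hochberg adjusted across the gene sets tested in a
single `resample_enrichment_many` call — the BH family is that call, with
significance threshold 0.05 by convention.  B defaults to 1000.

Sampling is vectorised: when |Q|² ≤ |U| a rejection sampler redraws the rare
rows containing duplicates; denser draws select the |Q| smallest of |U|
random keys per row.  Both are exact uniform without-replacement samplers.

Gene identifiers are compared case-sensitively after whitespace stripping;
duplicates within one input collapse with a warning.  Jaccard of two empty
sets is defined as 0.  Fisher's exact test is one-sided (enrichment) on the
2×2 membership table via `scipy.stats.fisher_exact`.

## Interaction ranking (`ranking`)

The score of a candidate protein–RNA pair is the sum of three components,
each already in [0, 1], divided by 3:

1. normalized propensity: the interaction-propensity z-score clamped to
   [−4, 4], then (z + 4)/8 — so z ≤ −4 ↦ 0 and z ≥ 4 ↦ 1;
2. RBP propensity — accepted as given (1 for proteins in the precompiled
   RBP library or similar to one, otherwise a signature score); this module
   never computes it;
3. motif component: 0, 0.5 or 1 for zero, one, or multiple occurrences of
   the protein's RNA-binding motif on the RNA.  Occurrences, not distinct
   motif types, are counted.

Division by 3 was chosen for the final "scale to [0, 1]" because it is
deterministic, dataset-independent and strictly monotone in each component;
a min–max rescale over the candidate table is available behind
`minmax_rescale=True` and produces the identical ranking order (a constant
table maps to 0.5).  Ties share a deterministic order, lexicographic on
(protein, RNA).  Boxplot statistics use linear interpolation between order
statistics (quantile "type 7"); whiskers are quartile ± 1.5·IQR clipped to
the observed data range.

## G-quadruplex / binding-site co-occurrence (`g4`)

The built-in finder matches the canonical pattern
`G{t,}(N{1,l}G{t,}){3}` (t = 3 tracts guanines minimum, loops 1..l = 7 nt)
left-greedily and non-overlappingly; its score is the number of guanines in
the four tracts.  It is deliberately canonical-pattern only — it does not
reproduce any external scoring model (bulges, mismatches, imperfections) —
and externally predicted G4 intervals can be loaded from BED instead, with
an inclusive score filter defaulting to 45.  Minus-strand predictions scan
the reverse complement and report plus-strand coordinates.

Positional profiles bin each interval by the bin containing its **start**
(a position, not a footprint; multi-bin spanning is therefore unambiguous),
into half-open windows [i·w, (i+1)·w) of w = 50 bp, the last bin possibly
short.  The relative position of a bin is bin_start / sequence_length
∈ [0, 1), which lets sequences of unequal length pool on one axis for
cumulative-density display.

Co-occurrence of two feature sets is tested over bins: with N total bins
across all sequences, K bins holding ≥ 1 a-feature, n holding ≥ 1 b-feature
and k holding both, p = P[X ≥ k] for X ~ Hypergeometric(N, K, n).  Bins
(not base pairs) were chosen as the sampling universe of this
peak-overlap statistic; the bin width is exposed.  An empty feature set
gives a degenerate result with p = 1, flagged.  The negative control
re-predicts G4s on the minus strand and repeats the test.

## Off-target scanning (`offtarget`)

Every window of guide length in every transcript is compared to the guide
and to its reverse complement at Hamming distance ≤ k (k ∈ {0, 1, 2}); no
indels, end-to-end only.  Both orientations are reported (consumers filter
if desired); `N` in a transcript mismatches every base; duplicate transcript
identifiers are rejected at load while identical sequences under distinct
ids are both reported.  The expressed flag is CPM ≥ 2 in at least
⌈0.75 · n_samples⌉ samples, the same filter used to admit genes into
differential-expression analysis; transcripts absent from the counts matrix
are flagged unknown (`None`).

## Quantification (`quant`)

* ΔΔCt: ΔCt = mean(Ct_target) − mean(Ct_reference) per condition, ΔΔCt =
  ΔCt_treated − ΔCt_control, relative expression 2^−ΔΔCt (100 % primer
  efficiency assumed; the base is exposed), knockdown % = 100·(1 − 2^−ΔΔCt).
  Replicates aggregate by the arithmetic mean of Ct — the geometric mean on
  the expression scale — and the replicate s.e.m. is propagated to the
  relative expression by the delta method.
* Radial distribution: relative depths (0 = pia, 1 = white matter) fall into
  half-open bins [i/n, (i+1)/n), depth 1 closed into the last bin; bin 1 is
  anchored at the pia.  Whether published figure panels number bins from the
  pia or the white matter is sometimes ambiguous; this module documents its
  convention and takes no side on any figure.
* Bisulfite methylation: 100·G/(G+A) from reverse-strand chromatogram peak
  heights; undefined (error) when both peaks are zero.
* Fractions: per-compartment levels normalised to percentages of their sum.

## Synthetic data (`synthetic`)

One root seed expands into per-artifact child streams through a fixed
spawn-key schedule (one integer per artifact kind), so adding a generator
never perturbs earlier artifacts and identical configuration + seed gives
byte-identical files.  Every generator returns a `TruthRecord` naming
exactly what was planted; under zero noise each planted quantity is
recovered exactly by its analysis stage.

* **DE tables**: the common core of each direction is sampled first, then
  disjoint per-condition remainders — so requested set sizes and pairwise
  intersections are achieved exactly, not in expectation, and every pairwise
  intersection equals the core.  An optional `opposite` block is up in the
  first condition and down in the second.  Members get FDR ≤ 0.05 with
  direction-consistent log2FC (|log2FC| ∈ [0.5, 5]); non-members are clearly
  non-significant.  Gene identifiers are synthetic tokens (G000001…) to
  avoid collision with real gene symbols.
* **Sequence panels**: background residues are uniform over A/C/T with G at
  a stated frequency (default 0.10) outside planted tracts, making the
  accidental-G4 rate controllable; at `g_freq=0` no accidental canonical G4
  can occur.  Planted G4 units are `GGGG`-tract/`TTA`-loop blocks (25 bp,
  score 16) flanked by `T` so the finder recovers each planted interval
  exactly; minus-strand units plant the reverse complement.  Motif
  (binding-site) intervals are recorded verbatim in the truth BED with a
  score above the default filter.  Sequence lengths are required ≥ 300 bp.
* **Ct tables**: the replicate ΔCt of the treated condition is shifted by
  −log2(1 − kd); Gaussian noise (`noise_sd`, default 0) rides on the
  target-gene Ct so that it is exactly the replicate-level ΔCt noise, with
  reference replicates at their nominal value.  Noise on all four Ct series
  independently would inflate sd(ΔΔCt) to σ·√(4/n) and is not what the
  recovery contract describes.
* **Transcriptomes**: uniform-random transcripts with planted guide sites at
  recorded offsets, orientations and mismatch counts (mismatch positions
  drawn at random, substitutions never silent).  Expressed transcripts
  receive Poisson counts scaled so library sizes sit near 10⁶ — placing them
  far above the 2-CPM filter — while unexpressed ones get 0–1 raw counts,
  placing them below it.
* **Radial positions / chromatograms / fractions**: multinomial bin counts
  with uniform within-bin depths; peak heights proportional to planted
  methylation with optional Gaussian noise (clipped at 0); compartment
  levels equal to planted percentages under multiplicative lognormal noise
  (sd 0.02 by default).  Default fraction targets are chromatin-dominant
  (90.64 / 92.12 / 94.35 % chromatin for the three L1 subfamily assays);
  only the chromatin percentages are anchored by observation, so the
  remainder is split 60/40 nucleoplasm/cytosol, matching the qualitative
  nucleoplasm ≥ cytosol ordering of subcellular fractionation data.

What the generators do **not** emulate: sequencing reads or alignment
artifacts, real L1 consensus sequences base by base, linkage between
generated artifacts (each is independent), overdispersed count noise,
or single-cell data.  Passing recovery tests therefore demonstrates the
correctness of the statistics and the feasibility of their inputs, not the
robustness of upstream read processing on real data.

## Problem sizes used in tests and the acceptance run

Calibration of the resampling test uses 2000 null replicates (20 000-gene
universe, |Q| = 100, |T| = 500, B = 1000) and 400 power replicates at a
planted 3× enrichment; knockdown recovery uses 500 noisy replicates; oracle
equivalence uses exhaustive enumeration up to 12-gene universes and 15-bin
profiles plus 100 random transcriptomes of 0.8–2 kb per transcript.  These
sizes give Monte-Carlo error comfortably below the asserted margins while
keeping the default test run fast.

## Known limitations

* The resampling test's normal-tail p is an approximation; for tiny
  universes the exact hypergeometric tail (provided by the degenerate-null
  fallback and by `fisher_overlap`) is preferable.
* Whether the upstream publication converted z to p one- or two-sided is
  not documented; this implementation is one-sided (enrichment) and exposes
  the alternative explicitly.
* The G4 finder is canonical-pattern only; analyses depending on
  non-canonical quadruplexes should import externally predicted intervals.
* The off-target scan is purely sequence-based (no seed-region weighting,
  no thermodynamics) and transcript-level (no spliced/genomic alignment).
* Reported subfamily panel sizes in the literature are taken as parameters,
  not facts: the generator accepts any per-subfamily counts.
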