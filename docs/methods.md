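# Methods

This note documents the model behind `micard`, the parameters that matter,
the numerical conventions, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely open.

## The matching model

The primitive is a binary match relation on ions: `a` and `b` are the same
feature when |Δt_R| ≤ `dt_r` **and** |Δm/z| ≤ `dmz`. Defaults are
`dt_r = 0.20` min and `dmz = 0.01` Da, both absolute (the m/z tolerance is
*not* ppm). These two numbers are the method's entire model of cross-run
alignment: there is no chromatographic warping, drift correction, or
mass recalibration. Tightening the window starves the cards of specific
ions; loosening the m/z arm to ~0.05 Da merges genuinely distinct features
and produces false matches — the defaults sit at the empirical sweet spot
for QTOF-class data.

The relation is symmetric and reflexive but **not transitive** (two ions can
each match a middle ion without matching each other). Every operation is
therefore defined without appealing to transitivity; in particular the
multi-batch intersection is anchored on a *reference batch* (first listed by
default, selectable by batch id). Anchoring makes the operation well defined
and reproducible at the cost of making batch order part of the protocol —
only the reference matters; permuting the remaining batches provably leaves
the result unchanged, and the test suite asserts it.

## Pipeline conventions

* **Retention-time window** 1.00–33.00 min, closed at both ends ("1.00–33.00"
  reads as a closed interval). Windowing runs first: it belongs to data
  transformation and shrinks all later work. Whether blank subtraction
  precedes or follows windowing is not observable in the output (both
  operations are per-ion filters); the fixed order is a convention.
* **Blank subtraction** removes any sample ion matching any blank ion. One
  solvent blank is applied to every batch by default; per-batch blanks are
  accepted for generality.
* **Consensus coordinates.** A common ion's t_R, m/z, and intensity are the
  arithmetic means over the reference ion and one best partner per other
  batch. The mean stabilizes the subsequent top-100 intensity ranking
  against single-batch jitter. Means are computed with exactly rounded
  summation (`math.fsum`) so the consensus is bit-identical under any
  ordering of the non-reference batches.
* **Best partner** when several ions of a batch match: smallest |Δm/z|, then
  smallest |Δt_R|, then highest intensity. Mass accuracy is the more
  reliable axis on QTOF data, so it dominates the tie-break.
* **Top-N selection** ranks intensity-descending with ties broken by
  ascending m/z then ascending t_R — fully deterministic output. A card
  smaller than N is a warning, not an error (sparse specific-ion sets are a
  real regime, seen when tolerances are tightened).
* **Duplicate rows** in a peak list (identical t_R *and* m/z) collapse to the
  max-intensity row: feature detection occasionally splits a peak, and max
  preserves ranking usefulness.
* All I/O is full-precision: floats are written with `repr` and re-parsed
  with Python's exact `float()`, so write→read round trips are bit-identical
  and card artifacts are byte-deterministic given identical inputs.

## Contrast credibility and the threshold

CC counts **test-sample** ions that match ≥1 card ion, divided by card size.
Counting test ions (rather than card ions) is the only simple reading under
which CC can exceed 100%, which real data produces (split peaks yield two
detected features inside one card ion's window); card-ion counting would cap
at 100. CC is reported as a half-up-rounded integer percent; the raw value
is retained and used for all comparisons.

The detection threshold is the half-up-rounded mean of replicate
positive-control CCs (controls blended at the adulteration limit, 5% by
convention). At least two replicates are required. Classification uses
`CC ≥ threshold` on the raw value: the calibration controls are themselves
adulterated, so their mean must classify as adulterated. The threshold is
deliberately never shipped as a constant — it depends on the positive
controls prepared alongside each analysis, like an accompanying standard
curve.

## The rank test

The self-match vs cross-match comparison uses Mann–Whitney U computed from
midranks, with U = min(U_a, U_b) and the tie-corrected normal approximation

    Z = (U − n_a·n_b/2) / sqrt( (n_a·n_b/12) · [ (N+1) − Σ(t³−t) / (N(N−1)) ] )

**without** continuity correction. On the printed CC groups
{99,101,100,98,95,93,100,96,100,98} vs {0,0,0,2,0,1,3,2,1,0} this yields
U = 0 and Z = −3.819; with a continuity correction Z would be ≈ −3.78, so
the no-correction convention is the one that reproduces the published
statistic and is fixed here (documented as reverse-engineered, since
statistical packages differ silently on this point). Degenerate input (all
pooled values identical) reports Z = 0 with a warning rather than NaN.
Tests cross-check U against an exhaustive-permutation oracle (exact for
group sizes ≤ 7) and the p-value against `scipy.stats.mannwhitneyu`'s
asymptotic no-continuity path; the normal approximation is accurate to
about ±0.1 in absolute p once each group has ≥ 5 members, and worse below
that — for such tiny groups the permutation p is the meaningful number.

## The synthetic generator

`make_template_pair` plants ground truth: two species sharing `n_shared`
ions, each owning `n_specific` specific ions, positions uniform over the
retention window × m/z range (default 100–1200 Da, the usual QTOF full-scan
range), intensities log-uniform over 3 decades (default 10³–10⁶ a.u., a
realistic feature-table dynamic range). Rejection sampling enforces pairwise
separation greater than 2× the matching tolerance between *all* planted
ions, which guarantees the specificity invariant with enough margin that
default jitter cannot manufacture cross-species matches.

`sample_batch` simulates one run: per-ion Bernoulli dropout
(`dropout_rate`, default 0.02), Gaussian jitter on t_R and m/z
(`sigma_tr` = 0.03 min, `sigma_mz` = 0.002 Da — a few times smaller than the
tolerances, as a well-behaved instrument should be), and mean-preserving
log-normal intensity noise (`intensity_cv` = 0.3). Batch streams are derived
by hashing (seed, batch_id), so each batch is independently reproducible.

`mix_samples` blends two pure runs at adulterant proportion p: matched ions
merge with proportion-weighted coordinates and intensity
((1−p)·a + p·b — so p = 0 reproduces run *a* exactly and p = 1 run *b*);
unmatched ions carry (1−p)- or p-scaled intensity; anything below the
detection floor disappears. The floor (default 2×10⁴ a.u. on the default
intensity scale) is what creates the dose response: at p = 0.05 only the
adulterant's strongest ions survive. The default was chosen by a closed-form
calculation on the log-uniform intensity model so that a 5% blend recovers
roughly a fifth to a third of the adulterant's card (the canonical study
below measures ~29%) while a pure adulterant still scores ≈100%.

### Canonical study conditions

The validation studies use templates with **340 shared + 260 specific ions
per species and 10 batches per species** — shared ions in the majority, as
with the two Panax species, and enough specific ions that the top-100 card
truncates well above the intensity floor. Card construction and the
dose/calibration studies run with the default jitter sigmas and **no
dropout**: the intersection-then-difference screen assumes that shared ions
are present in every batch, and the planted-truth claims (cards drawn
entirely from specific ions, exactly 100 ions per card) are only
well-defined in that regime. Problem sizes were chosen so the full suite and
the acceptance script each run in seconds.

### A measured limitation: random dropout leaks shared ions

With uniform random dropout the screen is *not* safe: a shared ion that
misses the intersection in species A (probability 1 − 0.98¹⁰ ≈ 18% at 2%
dropout over 10 batches) while surviving it in species B passes the
cross-species difference and enters B's card as a false "specific" ion. At
the canonical template sizes this measurably inflates cross-species CC to
~15–20%. The effect is inherent to the difference-of-intersections design,
not to this implementation; on real data it is mitigated because consistently
detected, high-intensity features (the ones that reach a top-100 card)
essentially never drop out at random. Practical implication: cards should be
built from batches where the shared chemistry is reliably detected, and a
blind sample's cross-CC creeping above a few percent is a signal to rebuild
the cards, not to reinterpret the threshold. The flat-dropout regime itself
is validated against its analytic recovery law (expected intersection
recovery (1 − d)^k) in the test suite.

### What the synthetic studies do and do not show

Passing them shows the set algebra, card construction, scoring, calibration,
and dose response behave exactly as specified on data with the assumed
structure (isotropic jitter well inside tolerance, intensity-independent
noise, linear mixing, a hard detection floor). They do not show robustness
to retention drift comparable to the tolerance, ppm-like mass-error scaling,
isotope/adduct redundancy, intensity-dependent detection, or matrix effects
in real blends — the printed CC magnitudes for real ginseng samples live in
the published tables, not in these simulations.

## Degenerate inputs and errors

Empty cards refuse to score (there is no denominator); a material whose
specific-ion set is empty fails the build with the material named (two
indistinguishable materials have no cards); fewer than two calibration
replicates is an error; a peak list with zero valid rows is an error, while
individually malformed rows are dropped with a counted warning. The CLI maps
usage errors to exit 1 and data/validation errors to exit 2, and logs the
effective configuration plus input digests for every run.
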