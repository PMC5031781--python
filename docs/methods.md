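# Methods

This note documents the models and procedures implemented in `batchfix`,
the assumptions behind them, the parameters that matter, and the design
decisions taken where more than one reasonable construction exists.

## Data model

A peak table holds one analytical batch (or several) as an
`(n_samples, n_features)` matrix of non-negative intensities with missing
measurements as NaN.  Features carry m/z (Da) and retention time; rt units
are whatever the input uses (seconds or minutes) and every rt tolerance is
interpreted in those same units — the package takes no stance on the unit.
Samples carry a batch id, a 1-based batch-local injection order and a type:
biological `sample`, pooled per-batch `QC`, or long-term reference `Ref` of
independent biological origin.  Injection order 1 is the drift reference
point of its batch.

On disk a table is three plain CSV/TSV files (wide matrix, sample metadata,
feature sidecar).  `M<mz>T<rt>` column headers are accepted in place of the
sidecar, but header-encoded coordinates are lossy for high-precision m/z,
which is why the sidecar is the primary convention.  Zeros are read as
missing by default (`zero_as_missing=True`), since exports commonly write
absent peaks as 0; missing values are always written back as empty cells.

## Between-batch alignment

*Model.*  A compound split between batches appears as two features whose
batch-level presence vectors are orthogonal.  Presence is aggregated from
per-sample missingness among the basis samples (Ref by default, QC
selectable): a feature is absent from a batch when the missing proportion
strictly exceeds the threshold (default 0.80); a proportion exactly at the
threshold counts as present.  Aggregating at batch level filters out
sample-level random missingness, which carries no alignment information.

*Candidates and events.*  Only features with partial batch presence
(0 < row sum < n batches) can align.  An event is an ordered candidate pair
within the m/z–rt box (defaults 0.002 Da — instrument resolution scale —
and 15 rt units — the expected between-batch retention drift) whose
presence vectors are orthogonal.  The event distance is
`sqrt((dmz/mz_tol)^2 + (drt/rt_tol)^2)`: unitless, symmetric in the two
axes, and bounded by sqrt(2) inside the box.  This scalar is a design
choice; any monotone combination of the two axes would serve, but the
tolerance-normalised Euclidean form weights both axes equally at the scale
the user has declared meaningful.

*Deconvolution.*  Events sharing candidates form clusters (connected
components).  A cluster whose members are mutually orthogonal is a single
correspondence.  Otherwise the largest event distances are removed — exact
ties removed together, which keeps the procedure deterministic — until one
or more orthogonal sub-components separate out; these are extracted and the
remaining candidates, with their original events restored, are re-processed
recursively.  Candidates never captured in a group stay unmerged.  The
naive alternative of greedily pairing nearest candidates is implemented
only as a comparison baseline (`nearest_pairing`); it commits to the single
shortest edge and is known to mispair co-eluting near-isobaric compounds.
The recursion matches an exhaustive minimum-distance orthogonal partition
when intra-correspondence distances are smaller than cross-correspondence
ones (the physically expected geometry); when that ordering is inverted the
problem is genuinely ambiguous and no distance-based method can resolve it.

*Merging.*  Within a group, each batch's intensities come from the single
member present there (unique by orthogonality); when no member passes the
presence rule in a batch, the member with the lowest missingness there is
used.  The merged feature's id concatenates the member ids; its m/z and rt
are means weighted by the number of batches each member is present in —
any representative value inside the box would do, and this one is stable
and reproducible.  Thresholds in the 0.60–0.85 range give robust results;
0.80 is the default.

## Within-batch drift correction

*Model.*  Instrument error is treated as predominantly multiplicative:
`intensity = level(feature) x drift(injection) x (1 + eps)`.  Features are
therefore scaled by their QC-sample standard deviation **without
centring** — centring would destroy the multiplicative structure — and
clustered in observation space (features as observations, QC injections as
coordinates), where features sharing a drift pattern lie close together.

*Clustering.*  A Gaussian mixture is fitted for each candidate component
count in a grid (default 1 to 52 in steps of three) and the count with the
best (lowest) BIC wins, which removes the operator from the decision.
Full covariance is the default; the mixture is initialised
deterministically (k-means++ with a fixed seed), so runs are reproducible.
With few features (hundreds) and many QC coordinates, full-covariance
components are parameter-hungry and BIC tends to prefer few clusters; this
is conservative — an under-split clustering yields an averaged drift
function, and the fitness gate then decides whether that average helps.
Zero-variance features cannot be scaled and are excluded from clustering
and correction.

*Drift function.*  Per cluster, all (injection order, scaled intensity)
points of all member features are pooled and a cubic smoothing spline is
fitted versus injection order.  Repeated abscissae are collapsed to their
per-injection means with counts as weights, which leaves the penalised
least-squares criterion unchanged.  The smoothing penalty is chosen by
generalised cross-validation by default (`lam=None`); because each cluster
pools many features, the fit is insensitive to this choice over a wide
range.  The spline is evaluated at every injection order of the batch, so
biological and Ref injections between QC anchors are corrected by
interpolation; evaluation outside the QC injection range is clamped to the
boundary value rather than extrapolated.

*Correction and gate.*  The cluster correction factor at injection n is
`drift(1)/drift(n)`; the first injection's factor is exactly 1 by
construction.  Non-positive drift values mark a pathological fit and demote
the cluster to `no_action` instead of producing sign-flipping factors.
Correction is applied to the original unscaled intensities of all samples
only if the root-mean-squared distance of the Ref samples from their centre
point (arithmetic mean over Refs, in scaled member-feature space) strictly
decreases.  Ref samples are of different biological origin and are never
used in drift fitting, so this gate is an unbiased fitness measure: a
cluster can improve QC precision considerably and still be vetoed when the
Refs do not confirm the improvement.  With fewer than two Refs the gate
cannot be evaluated and no cluster is corrected (with a warning).

*CV filter.*  After correction, features with QC CV strictly above the
limit are removed batch-wise.  The default limit is 30 %: the common 20 %
validation limit discards far more features than exploratory untargeted
work can afford, while 30 % admits more candidate biology at the cost of
extra noise that downstream variable selection can handle.  CV is defined
as sample standard deviation over mean, x100 — the sample (n−1) form is
used because QC series are short; with a dozen QCs the difference from the
population form is a few percent relative, well below the decision margins
the limit is used for.  A CV exactly at the limit is kept, mirroring the
strictness convention of the presence rule.

## Between-batch normalisation

Normalisation is restricted to features that survived drift correction in
every batch.  Per feature, reference-based normalisation (divide each batch
by its mean Ref intensity) is chosen only if the Refs measure the feature
precisely and consistently:

1. Ref CV < 0.3 (as a fraction) in every batch, strictly; and
2. for every batch pair, the feature's Ref intensity ratio deviates from
   the all-feature average ratio by less than 5-fold on the log scale,
   taken as an absolute value so the criterion is symmetric in the pair —
   fold changes are equidistant in log space.

The all-feature average ratio is computed as the ratio of batch-wise mean
Ref intensities over all common features (ratio of means, not mean of
ratios; the alternative is equally defensible but less robust to a few
extreme features).  Features failing either part are normalised by the
median intensity over the batch's *biological* samples only — QCs and Refs
are deliberately excluded because they are not draws from the study
population.  Raising the fold limit can only move features from population
to reference normalisation, never the reverse.  All scale factors are
anchored to the first batch so output intensities stay in the input's
familiar range; this anchor is an arbitrary but harmless convention.

## Synthetic data

The generator emulates the targeted study design: per batch, 84 biological
+ 16 QC + 14 Ref injections with QC/Ref anchors spread evenly (one of each
roughly every 14th injection, anchors at the start and near the end), three
batches by default.  Intensities follow
`base x batch_offset x drift(injection) x (1 + eps)`, with per-feature base
intensities log-uniform over 1e4–1e7, measurement noise eps of 10 % CV,
biological between-sample variation of ~25 % CV (log-normal), batch
offsets log-uniform up to 2-fold (first batch anchored at 1), and four
drift patterns by default from a library of exponential-decay, linear,
sinusoidal and step shapes at 30 % relative amplitude — numbers chosen to
be typical of reversed-phase UHPLC-qTOF plasma profiling.  QCs sit at the
batch pool mean, Refs at a batch-independent pool (a fixed per-feature
log-normal shift), and Ref drift can be set to `shared`, `none` or
`opposite` to exercise the fitness gate.  Split features are planted as two
aliases with offsets inside the alignment tolerances in disjoint batch
subsets; ambiguous quadruples plant two co-eluting split compounds inside
one tolerance box with intra-pair offsets well under the cross-pair ones.
Random cell-level missingness (off by default) touches biological rows
only, so QC/Ref anchor requirements hold unless deliberately violated.

What the generator does *not* emulate: chromatographic peak shapes, m/z
domain noise beyond the planted offsets, correlated metabolite panels,
retention-time warping within a batch, and missingness that depends on
intensity.  Tests passing on this generator therefore demonstrate the
algorithms' contracts (recovery of planted structure, gate soundness,
invariances), not performance on any particular instrument's data.

## Numerical choices and degenerate inputs

- All boundary rules are strict in the documented direction: missingness
  `> threshold` flags absence, Ref RMSD must *decrease* to correct, CV
  `> limit` removes a feature, Ref CV `< 0.3` and log deviation `< log 5`
  are required for reference normalisation.  Values exactly at a boundary
  always take the lenient branch.
- Event-distance ties during deconvolution are removed together;
  candidate/group orderings are lexicographic throughout, making every
  stage deterministic without a seed.  The only seeded component is the
  mixture initialisation.
- Drift fitting requires at least 4 distinct QC injection orders (cubic
  minimum); 5+ enables GCV smoothing, below that an interpolating cubic
  spline is used.
- Degenerate inputs fail loudly: missing values in the drift stage, fewer
  than 2 QC/Ref samples where they are required, zero anchoring statistics
  in normalisation, empty common-feature intersections (with a per-batch
  survivor diagnostic).

## Problem sizes used in the shipped checks

The test-suite and the acceptance script run the method end to end on
simulated data sized to exercise every mechanism while staying desk-scale:
alignment on 3x300-feature batches with 50 planted splits and 10 ambiguous
quadruples; drift correction on a 3 000-feature, 18-QC batch with four
planted patterns; normalisation on 200 features with 3-fold offsets; and
1 000 small randomised tables for the orthogonality/idempotence and
decision-exactness properties.  These sizes are the package's own test
conditions; nothing in the algorithms depends on them.

## Known limitations

- Alignment assumes splits are batch-systematic; a compound split *within*
  a batch (two sub-populations of samples) is upstream territory.
- The drift stage needs full matrices; imputation/gap-filling is expected
  upstream and is out of scope.
- The mixture clustering scales with features x QCs; very large batches
  (tens of thousands of features) make the BIC grid the dominant cost.
- The deconvolution resolves ambiguity by distance only; coherent
  retention drift that makes a wrong pairing geometrically shorter than
  the right one is unresolvable from m/z–rt evidence alone.
- Population-median normalisation assumes similar population distributions
  across batches; designs with strongly batch-confounded biology violate
  this and need a different anchor.
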