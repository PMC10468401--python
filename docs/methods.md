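# Methods

`piezoblade` measures the blade-tip geometry of trimeric membrane channels
from 3D single-molecule localization data.  Each protomer of a trimer
carries one fluorophore near the distal end of its blade; the quantity of
interest is the per-molecule *average interblade distance* — the
arithmetic mean of the three pairwise fluorophore-centre distances — and
its distribution across a population of molecules under different
experimental conditions.  Because real instrument data cannot be shipped,
the package pairs the analysis pipeline with a calibrated synthetic-data
generator so that every stage is verifiable end to end.

## Generative model

A molecule is a C3-symmetric triskelion in the membrane plane.  Tip `k`
(k = 0, 1, 2) of a molecule with in-plane orientation `phi` sits at

    r_k     ~ Normal(mu_radius, sigma_radius)        [radial flexibility]
    theta_k = phi + 120deg * k + Normal(0, sigma_theta)
    z_k     ~ Normal(0, sigma_z)

with all three blades independent — the blades of a single channel move
essentially independently, so no inter-blade correlation is modelled.
Molecule centres are placed uniformly in a rectangular field with a
minimum pairwise separation (default 150 nm, so the 100 nm isolation rule
is exercised but not saturated).  Each subunit is labelled independently
with probability `p_label` (default 0.8; labelling efficiency is a free
simulator parameter, not an empirical claim).

Emission follows the blinking-trace structure of the data: a labelled tip
produces `max(1, Poisson(traces_per_fluor_mean))` traces of
`max(1, Poisson(locs_per_trace_mean))` localizations each, every
localization displaced by independent per-axis `Normal(0, sigma_loc)`
error.  `sigma_loc` defaults to 6 nm, the median per-axis fluorophore
localization error of 3D MINFLUX measurements.  Background traces
(fluorophore-like clouds at uniform positions, z within +-40 nm of the
membrane plane) and linear streaks (collinear localization runs from
molecules diffusing through the focal plane, default length 300 nm) are
appended at configurable areal densities (defaults 1.0 and 0.2 per um^2 —
washed, fixed-cell fields are sparse).  Defaults of 6 traces x 20
localizations per fluorophore (~120 localizations) reflect long MINFLUX
acquisitions of a cyanine dye.  Photophysics (blinking kinetics, photon
counts), detectors and drift are deliberately out of scope.

### Calibration

`calibrate_geometry` inverts the generative model: given a target mean
and standard deviation of the per-molecule mean pairwise tip distance, it
solves for `(mu_radius, sigma_radius)` by least squares on a forward
Monte-Carlo simulation with common random numbers (default 10^5
molecules), holding `sigma_theta` (8 deg) and `sigma_z` (4 nm) fixed — a
two-number target cannot identify more than two parameters.  The solution
is deterministic for a fixed seed and is verified to reproduce the
targets within 1%; an unreachable target (e.g. a spread larger than any
radial noise can produce at the requested mean) raises a calibration
error naming the residual.  In the noiseless limit the closed form
`mean_d = mu_radius * sqrt(3)` is recovered exactly.

## Trimer identification (MINFLUX branch)

1. **Trace filter.**  Traces with a per-axis sample standard deviation
   above 10 nm (background, streaks) or fewer than 3 localizations are
   removed.  The trace statistic is the *largest* per-axis s.d.
   (conservative reading of an ambiguous rule).
2. **Two-step density clustering.**  DBSCAN over all localizations at
   eps 30 nm / minpts 5, then DBSCAN at eps 6.5 nm / minpts 5 within each
   first-step cluster.  6.5 nm is the midpoint of the documented 6-7 nm
   range and is exposed in the configuration.
3. **Gaussian-mixture fit.**  Per first-step cluster, a diagonal-
   covariance mixture is fitted by expectation-maximization (per-axis
   sigmas initialized at 5 nm; tolerance 1e-6; 500 iterations max).
   Fluorophore centres are the component means, their positional
   uncertainty the component sigmas.  Components whose sigma collapses
   below 0.5 nm are clamped and flagged; components with fewer
   localizations than the clustering minpts are dropped; components
   closer than 5 nm (below any neighbour-window floor) are pooled.
4. **Trimer selection.**  DBSCAN over fluorophore centres at eps 100 nm /
   minpts 3; keep clusters of exactly three whose members are pairwise
   separated within the neighbour window (6-50 nm; 5-60 nm in the
   alternate variant used for strongly expanded conditions), are each
   more than 100 nm from every fluorophore outside the cluster, lie
   inside the z gate, and whose triangle has no vertex angle above 120
   degrees (the angle filter applies to *any* vertex; for a >120 deg
   rule, "any" and "max" coincide).  Isolation is tested against
   fluorophore centres, not raw localizations.

### Choosing the mixture size K

How many fluorophores a first-step cluster contains is not observable
from density clustering: at 6 nm localization error the clouds of two
fluorophores closer than roughly 20 nm overlap enough that eps-6.5
clustering merges them (the bridge density exceeds minpts), so the
second-step cluster count is only a lower bound.  K is instead derived
from the blinking-trace structure.  Each trace re-localizes a single
emitter, so its mean estimates that emitter's position with standard
error `sd/sqrt(n)` — typically 1-2 nm, far below the cloud sigma.  Trace
means are grouped by average-linkage clustering under an SE-normalized
metric (pairwise distance divided by the root-sum-square of the two
standard errors, cut at 4), which adapts to the data's noise scale and is
exact in the noiseless limit; the group count is K and the group
centroids initialize the EM means.  Where no trace structure is
available, K falls back to BIC selection over one to four components.
On data whose between-trace spread dominates the within-trace spread
(re-activation jitter larger than assumed here), the trace-mean rule
would undercount and the BIC route is the safer choice.

For the same reason the EM E-step runs at *trace* granularity: a trace's
log-likelihood under a component sums over its localizations, and whole
traces are (softly) assigned.  Localization-level EM pushes the means of
clouds overlapping at one to two sigma apart — on simulated pairs the
fitted distance is biased by +0.7 to +1.7 nm at 8-14 nm separation, and a
quarter of 8 nm pairs are not resolved at all — whereas a
20-localization block is decisively assigned where single localizations
are ambiguous, cutting that bias to about +0.2 nm and the estimator
spread threefold.  The fit remains a diagonal-covariance Gaussian
mixture with the documented initialization and convergence rules;
component means and sigmas are reported exactly as before.

### z gating

On instrument data the z gate is often chosen by inspection.  Here the
gate is an explicit `[z_min, z_max]` configuration interval; when unset
it defaults to the 5th-95th percentile of the filtered localization z and
is recorded in the run log.  The percentile default clips a small
fraction of genuinely membrane-bound molecules whose centres sit in the z
tails (~1% per molecule at the default noise scale, but exactly 10% of
molecules in the noiseless limit, where localization and centre z
coincide); when the membrane plane is known, pass an explicit interval.

## iPALM branch

The camera-based branch renders localizations to a summed z-projection at
3 nm per pixel (half-open bins; counts are conserved), then segments
candidate particles: difference-of-Gaussians bandpass (sigmas 1 and 3 px)
and 8-connected local maxima above an amplitude threshold, centroid-
refined in a 5 px window.  Detection deliberately runs at a fine scale —
which can split one sparse fluorophore cloud into several maxima — and
peaks closer than 9 nm are then consolidated by average linkage into
amplitude-weighted positions; 9 nm is the neighbour-window floor, below
which two retained fluorophores cannot both be real.  The coarse-scale
alternative (smoothing at the cloud diameter) merges the peaks of compact
molecules and selects against them, biasing the super-particle toward
expanded conformations; fine-scale detection plus sub-floor consolidation
is selection-neutral on simulated fields.  Candidate triples must have
exactly two mutual neighbours at 9-60 nm and be more than 60 nm (2D) from
any non-member localization; member localizations (within 30 nm of a
peak) more than 75 nm (3D) from the particle mean are pruned.
Segmentation is 2D, per the summed-projection approach; only the 75 nm
prune acts in 3D.

**Fusion.**  State-of-the-art super-particle workflows register
particles with a template-free all-to-all algorithm (scale sweep,
Lie-algebra consistency checks, bootstrap against a data-driven
template).  That algorithm is *not* re-implemented here — this is the
package's largest simplification.
Because segmentation already yields three matched blade clusters per
particle, a correspondence-based rigid alignment substitutes: each
particle is centred on its blade-centroid mean, rotated so the centroid
plane lies in x-y (both plane orientations tried), and in-plane rotated
to minimize the summed squared distance to the first particle's centroid
triangle over the three cyclic blade correspondences.  Threefold symmetry
is then promoted by rotating each aligned particle by a seeded random
integer multiple of 120 degrees before pooling, so registration cannot
lock onto labelling or density asymmetries.  Fusion is equivariant under
a global rigid motion of all input particles and is byte-reproducible for
a fixed seed.

**Blade statistics.**  A Gaussian kernel density (bandwidth 2.5 nm) over
the pooled 3D set assigns each localization a local density; the pooled
set is thresholded (Otsu on the density distribution by default; the
alternative rule — the minimum density that confines kept localizations
to a 60 nm sphere — is available), blade labels come from k-means with
k = 3 (10 seeded restarts, best inertia kept), and each localization is
averaged against all localizations of *one* neighbouring blade (the next
blade in a fixed cyclic order by centroid azimuth; averaging against both
neighbours is available behind a flag).  The distribution is summarized
by its kernel-density mode on a 0.1 nm grid.

## Condition statistics

- Per-trimer geometry: pairwise distances, vertex angles (sum 180 deg to
  1e-6), circumradius `R = abc/4K` computed in 3D, projected area
  `pi R^2`.  The projected area is computed per molecule and then
  averaged; the mean of areas necessarily exceeds the area at the mean
  distance for a spread population.
- Condition summary: mean and sample s.d. (n-1) of per-molecule mean
  distances; variance with a chi-square 95% CI (n-1 degrees of freedom).
- Two-condition comparison: two-sample two-tailed Kolmogorov-Smirnov on
  per-molecule means (exact for samples of at most 25, asymptotic
  otherwise); F-test with F = larger sample variance / smaller and
  two-tailed p; Mann-Whitney U (normal approximation with tie
  correction) on per-angle deviations `|theta - 60 deg|`, three per
  molecule.  A zero-variance sample makes F undefined (reported as NaN).
  No multiple-testing correction is applied; pairwise tests are reported
  unadjusted.
- Angle histograms are binned at 10 degrees and fitted with an
  unweighted least-squares Gaussian; R^2 is computed on bin counts; angles
  are degrees throughout.

## Condition registry and reproduction

`experiments.CONDITIONS` stores, per condition, only the reference
population values (mean, s.d., n) of the per-molecule average interblade
distance plus the neighbour-window variant (alternate window only for
osmotic swelling):

| condition        | mean (nm) | s.d. | n   | window |
|------------------|-----------|------|-----|--------|
| resting103       | 25.1      | 7.4  | 41  | 6-50   |
| detergent        | 17.1      | 4.0  | 7   | 6-50   |
| gsmtx4           | 20.7      | 6.6  | 20  | 6-50   |
| position670      | 17.8      | 4.2  | 35  | 6-50   |
| swelled103       | 34.7      | 8.8  | 14  | 5-60   |
| unstim103_swell  | 25.7      | 8.6  | 44  | 6-50   |
| unstim103_yoda   | 25.13     | 7.39 | 41  | 6-50   |
| yoda1_103        | 27.07     | 6.60 | 69  | 6-50   |
| unstim670        | 17.77     | 4.19 | 35  | 6-50   |
| yoda1_670        | 19.71     | 3.01 | 22  | 6-50   |
| ipalm103         | 25.4      | 5.9  | 726 | —      |

The two unstimulated position-103 rows differ in the source (25.7 +- 8.6,
n=44 versus 25.1 +- 7.4, n=41 for nominally the same state); both are
kept as distinct entries, with no reconciliation attempted.  A condition
run calibrates the generator to its row, plants `n` fully-labelled
molecules (the reference n counts *identified triple-labelled* molecules,
so condition replicates use `p_label = 1`; the simulator-wide default
stays 0.8), emits localizations, runs the full pipeline and summarizes
the recovered trimers.  Fields are sized at 2 molecules/um^2 (4/um^2 for
the iPALM condition).  Reported values are seed-averaged over 20
replicates (10 for the iPALM condition); per-replicate values are logged.
Conditions differ *only* by their calibrated geometry — the biophysics of
detergent, GsMTx-4, swelling or Yoda1 is not modelled.

A single master seed drives everything: `numpy.random.SeedSequence`
spawns one child stream per stage (placement, geometry, labelling;
signal, background, streaks; fusion symmetry; k-means), in that
documented order, so partial re-runs are reproducible.

## What passing tests do and do not show

The generator emulates the *statistical* structure the pipeline assumes:
isotropic Gaussian localization error that is i.i.d. within and between
traces, independent blades, a flat membrane, and background that is
either uniform clouds or long streaks.  Real data differ in known ways —
anisotropic and heteroscedastic localization error, between-trace
re-activation jitter, membrane topography, correlated blade motion,
unlabelled-protomer dark states and segmentation edge cases near cell
borders.  Recovery of the reference numbers on synthetic data therefore
validates the pipeline's correctness and calibration under its own
assumptions; it does not certify accuracy on instrument data.

Two intrinsic biases of the rule set are worth stating.  First, the
selection rules (neighbour window, angle filter, isolation) truncate the
*true* population, so a pipeline run over molecules whose ground truth is
calibrated to post-selection reference values recovers means a few
tenths of a nanometre high (up to ~0.5 nm for broad conditions) — within
the acceptance band, and documented rather than compensated.  Second,
per-localization interblade distances are convexly inflated by cluster
spread (`E||x-y|| >= ||E x - E y||`); density thresholding to the blade
cores and the mode statistic keep the net effect near zero at the
default noise scale.

## Numerical choices and degenerate inputs

- DBSCAN neighbourhoods include the point itself (scikit-learn's
  convention, matching the reference implementation's minpts semantics).
- EM: reg_covar 1e-6 nm^2 keeps zero-variance clouds fittable; the 0.5 nm
  sigma floor flags collapsed components.
- Collinear fluorophore triples have no circumradius and are rejected
  (they also fail the 120 deg angle rule).
- Identical-value samples give a degenerate variance CI (0, 0); F is NaN.
- Angle histograms with fewer than 3 occupied bins refuse to fit.
- Rendering uses half-open bins; a localization exactly on an interior
  boundary joins the higher bin.
- k-means and fusion take explicit seeds; all stochastic defaults are
  reproducible from one master seed.

## Known limitations

- The simplified fusion assumes segmentation yields exactly three blade
  clusters per particle; particles without three clusters are skipped and
  logged rather than registered against a template.
- The trace-based K rule relies on within-trace error dominating
  between-trace jitter; instruments with large re-activation offsets
  should use the BIC fallback.
- Two reference values are mutually inconsistent with the closed forms
  used here: a 19.2 nm model distance implies a 386 nm^2 equilateral
  circumcircle area (not the quoted 411 nm^2 — the model-area recipe
  behind that number is unknown and no attempt is made to match it),
  and a quoted ~29% distal expansion differs from the 30.7% implied by
  25.1/19.2 (the baseline is unclear; both quantities are computed, not
  asserted).
- Vendor raw formats, drift correction and fiducial registration are out
  of scope; input is the documented CSV schema.
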