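# Methods

## The measurement model

The pipeline consumes manual traces of single 70 nm EM sections of
presynaptic boutons: a closed perimeter polyline, zero or more open
postsynaptic-density (PSD) polylines, zero or more open glial-membrane
polylines, and vesicle centre points, with a nm-per-pixel calibration.
Coordinates are converted to nm exactly once at load (ImageJ convention:
0-based pixels, y increasing downward; all analysis is unit-consistent so
orientation never enters). Consecutive duplicate vertices are dropped at
load because zero-length segments break nearest-point computations.

### Membrane classification

The perimeter is resampled at a uniform arc-length spacing
`L / ceil(L / step)` (default step 1 nm) and each sample is labelled

- `active_zone` if its exact Euclidean distance to any PSD trace is ≤ τ_AZ,
- else `glial_facing` if within τ_glial of any glial trace,
- else `other`.

Defaults τ_AZ = τ_glial = 30 nm: the apposition gaps in this preparation
are ~6 nm (glia) and ~20 nm (synaptic cleft), while unrelated structures
sit much farther away, so 30 nm separates apposed from non-apposed
membrane robustly. Where both thresholds are met the active zone wins —
glia do not overlie the synaptic cleft. Label runs shorter than
`min_run_nm` (default 10 nm) are absorbed into the flanking label,
suppressing single-sample flicker at boundaries; maximal runs become
regions. Compartment lengths are sample counts times the spacing, so the
three compartments partition the perimeter length exactly.

An annotation may instead carry explicit compartment arc intervals (a
manual demarcation); these bypass the classifier when present.

### Distances, coverage, gaps

Per vesicle centre, the distance to the whole membrane uses exact
point-to-segment geometry (shapely); distances to the active-zone and
glial-facing compartments are minima over the resampled compartment
samples, emulating a nearest-pixel computation with discretisation error
bounded by half the resample step. Compartments are subsets of the
perimeter, so `d_compartment >= d_membrane` holds structurally. Distances
to an absent compartment are undefined (NaN) and excluded from pooled
statistics.

Glial coverage is glial-facing length over perimeter length. For each
glial-facing region the apposition gap is the exact distance from the
region's arc-length midpoint sample to the nearest glial trace.

### Pools and near-membrane fractions

Vesicle distances are pooled across all terminals of a condition (the
contingency analysis pools vesicles; it does not average per terminal).
The histogram uses half-open 10 nm bins from zero; the bin width is not
dictated by the source analysis, but 10 nm is fine relative to the 50 nm
criterion and makes peak probabilities commensurate with density × width.
The density estimate is a plain Gaussian KDE with Silverman's rule-of-thumb
bandwidth h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a 0.5 nm grid
from 0 to max + 3h. No boundary reflection is applied at zero; the
resulting near-zero bias (the kernels place a little mass below zero) is
documented rather than corrected.

Pool peaks are local maxima with prominence ≥ 5 % of the maximum density —
permissive on purpose, since shallow third pools are biologically real.
Each peak carries both its raw density (per nm) and a probability:
100 × the trapezoidal integral of the density over one bin width centred
on the peak. The integral reading is primary (an integral is a
probability; a density is not), but both are emitted so either
interpretation of "probability from the density function" is recoverable.

The near-membrane count uses a strict inequality at 50 nm — one typical
vesicle diameter (52.5 nm measured in this preparation, rounded); a
distance of exactly 50 nm counts as outside. Fractions are rounded to
3 decimals only at reporting time.

### Statistics

Fisher's exact test (two-sided) uses the sum-of-small-p convention: all
tables with the observed margins whose hypergeometric probability is at
most the observed table's, with a 1e-7 relative slack for floating-point
ties, computed from log-gamma so totals in the tens of thousands remain
exact to double precision. A zero margin returns p = 1, flagged as
degenerate. Kruskal–Wallis H is computed on midranks with the standard tie
correction (chi-square approximation, k − 1 df); Dunn's post hoc z uses
rank means with tie-corrected variance and Bonferroni adjustment over the
pairwise comparisons (configurably unadjusted). The single-sample t-test
on normalized current amplitudes that accompanies the physiology is out of
scope: it requires recordings, not traces.

## The synthetic generator

The generator emits annotation bundles with known ground truth so that
classification, distance measurement, pool identification and the
statistics can all be validated end to end.

- **Perimeter**: a Fourier-perturbed circle, r(θ) = R·(1 + Σ_{k=2..5} a_k
  cos(kθ + φ_k)) with |a_k| ≤ noise/k (default R = 180 nm, noise 8 %,
  200 vertices) — smooth, convex-ish profiles at the scale of a bouton
  section (~1.1 µm perimeter).
- **Arc layout**: one active-zone arc (12 % of the perimeter) behind a
  PSD trace offset 20 nm (cleft scale); 2 or 3 glial arcs (16 % each)
  behind glial traces offset by per-region gamma-distributed gaps
  (mean 6 nm, sd 1.5 — positive and mildly right-skewed, the observed
  5.8–6.3 nm scale). The first two glial regions flank the active zone
  across a short jittered margin, as ensheathing glia do; a third sits in
  the remaining arc.
- **Apposition consistency**: ground truth defines a glial-facing interval
  as membrane within τ = 30 nm of its glial trace. Parallel traces are
  therefore inset at each end by √(τ² − gap²); without the inset, membrane
  just beyond the intended interval would also fall within τ of the trace
  endpoint, and any threshold classifier would systematically overshoot
  each region end by ~29 nm (≈ +0.09 coverage per terminal). With the
  inset, measured coverage matches ground truth to < 0.01.
- **Vesicles**: counts are Poisson (mean 58, the per-terminal average
  implied by pooled counts of ~9 500–17 400 vesicles over 167–295
  terminals). Each vesicle draws a pool: defaults 30 % in a narrow pool at
  32 nm (sd 12), 55 % in a broad pool at 97 nm (sd 30), 15 % uniform
  background. Pool locations follow the unstimulated peak table; the
  weights and spreads are not published, so they were fixed once at values
  that give a within-50 nm fraction near 0.2 and clearly separated KDE
  modes. Pool vesicles are placed along the inward normal of a random
  active-zone sample at the drawn distance (for near-circular arcs the
  nearest-AZ distance then equals the target; candidates violating the
  target by > 1.5 nm or leaving the polygon are re-drawn); background
  vesicles are uniform in the polygon. Placement conditions on the AZ
  distance only — the distance-to-glia distribution is left emergent, and
  with the flanking layout it reproduces the single broad ~100 nm peak
  observed for glial-facing membrane.
- **Conditions**: presets mirror the study's structure — 167 / 295 / 287
  terminals for unstimulated / 0.033 Hz / 1 Hz, per-condition pool
  locations (32/97, 36/87, 31/81 + a shallow 117 nm pool), a 0.02 drop in
  near-pool weight per step, and gap means 5.82 / 6.01 / 6.26 nm.
- **Reproducibility**: one seeded generator per condition spawns a
  recorded per-terminal seed; a fixed seed reproduces byte-identical JSON.

### What the generator does not emulate

Real tracing noise (hand jitter, curvature-dependent vertex density),
non-convex or partially sectioned boutons, vesicle exclusion zones around
organelles, correlated vesicle clustering, and section-projection effects
are all absent. Passing recovery tests therefore demonstrates that the
measurement chain is correct and unbiased under the generative model, not
that the thresholds would reproduce a particular manual demarcation of
noisy real material.

## Numerical choices and degenerate inputs

- Resampling of traces keeps original vertices and subdivides each segment
  into `ceil(len/step)` equal parts, so chord sums equal exact arc length;
  the classifier's internal perimeter resampling is uniform so that sample
  counts convert to lengths exactly.
- Degenerate traces (zero arc length), empty distance pools, zero-spread
  KDE samples and zero-margin contingency tables raise or are flagged
  rather than silently producing numbers.
- Vesicles more than one vesicle radius (26.25 nm) outside the perimeter
  polygon trigger a warning and are retained; a strict mode drops them.
  Silent exclusion would bias counts; tracing noise at the membrane is
  expected.
- Ties at region-merge boundaries resolve toward the preceding (or longer)
  flanking run; ties in peak ordering are impossible on a strict grid.

## Problem sizes in the test and acceptance runs

The validation suites run on scaled-down synthetic datasets chosen to make
the statistics decisive: pool-peak recovery uses 10 terminals × ~500
vesicles per seed over 20 seeds (5 000 pooled distances resolve the 32 and
97 nm modes to a few nm); coverage/gap recovery uses 50 terminals
(~125 glial regions); the contingency power check uses ~9 000 vesicles per
condition. The acceptance script reproduces the published contingency
fractions and p-values from the printed pooled counts directly, since the
underlying per-vesicle distances were never deposited.
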