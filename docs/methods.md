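# Methods

`locotrack` quantifies the crawling behaviour of *C. elegans*-style animals
from dark-field video or centroid tables: it detects bright animal blobs,
links them into per-animal tracks, derives smoothed speed and acceleration
series, segments acceleration events, and compares populations with
speed-binned curves and hypothesis tests.  Because no public recordings
accompany the analysis it reimplements, the package ships a generative
model of the assay so that every stage is testable end to end.

## The assay model

A virtual assay is a 2-minute recording at 1 frame/s (dt = 1 s) of
`n_animals` worms crawling on a rectangular arena (default 12 × 12 mm for
20 animals).  Three stochastic ingredients:

**Speed process.**  Each animal's speed follows a mean-reverting
(Ornstein–Uhlenbeck) diffusion reflected at zero,

    dv = θ (μ − v) dt + σ dW,   v ← |v| after each Euler–Maruyama step,

whose unreflected stationary law is N(μ, σ²/2θ).  This is the simplest
process with independently tunable mean speed (μ) and fluctuation
magnitude (σ at fixed θ), matching the two phenotype axes the analysis
measures: average speed and within-track speed SD.  Reflection by absolute
value is the simplest scheme preserving nonnegativity; it biases the mean
upward only when μ ≲ the stationary SD.  Integration can run on a finer
internal step (`substeps`) than the camera rate; observations are
subsampled, decoupling process accuracy from the 1 Hz frame clock.

**Heading.**  An independent random walk (SD `turn_sd` rad/step, default
0.5) gives smooth persistent paths; arena walls reflect the position and
flip the heading component, as plate edges do.

**Individuality.**  Each animal draws a personal mean speed from
|N(μ, μ_sd²)|.  Without between-animal variability every track would land
in one or two average-speed bins and the binned-curve analyses would be
vacuous; real populations spread over the full 0–0.3 mm/s range.

Detection dropout is i.i.d. per animal per frame.  The default
`dropout_prob = 0.135` was calibrated once, against the default tracker
settings, so that the mean linked-track length is ≈ 53 s in a 120 s assay —
the fragmentation scale of the real tracker this emulates.

### Strain presets

| preset | μ (mm/s) | stationary SD (mm/s) | μ_sd (mm/s) |
|---|---|---|---|
| `wild_type` | 0.15 | 0.037 | 0.031 |
| `cat2_like` | 0.15 | 0.054 | 0.047 |
| `slowed_mutant` | 0.08 | 0.054 | 0.047 |
| `da_pretreated` | 0.15 | 0.037 | 0.031 |

θ = 0.5 /s throughout; σ = SD·√(2θ).  The presets are phenomenological:
they encode the dopamine-deficient fluctuation excess (larger within-track
and between-animal SDs at matched mean), a serotonin-pathway-like variant
that is slower but keeps the mutant fluctuation parameters, and a
dopamine-pretreatment condition that restores the wild-type parameter set.
Only orderings between strains are claimed, not the absolute values any
particular wet-lab assay would produce.

What the generator does **not** emulate: body posture and undulation
(animals are points), merging/occlusion geometry beyond blob overlap,
bacterial-lawn structure, centroid jitter from segmentation noise, and any
dose–response of pharmacological treatment.  Passing tests therefore
validate the measurement pipeline and its statistical behaviour, not any
biological claim about real recordings.

## Detection

Frames are thresholded at a fixed global level (synthetic frames have
controlled contrast, so adaptive thresholding would only obscure the
stage), labelled with 8-connectivity, filtered by minimum component area,
and reduced to intensity-weighted centers of mass, giving sub-pixel
centroids (< 0.2 px error on isolated blobs).  Touching animals merge into
one detection by design; the tracker, not the detector, handles the
consequences.  Calibration is a single scalar, 0.01 mm/px by default.

## Tracking

Per frame, open track heads are matched to detections by a gated optimal
assignment: pairs farther than `max_disp` apart are inadmissible; among
matchings of maximal admissible cardinality the one with minimal total
distance is chosen (`scipy.optimize.linear_sum_assignment` with a
forbidden-pair cost exceeding any feasible total, which enforces exactly
that lexicographic objective).  Unlike greedy nearest-neighbour this is
deterministic and order-independent, and coincides with greedy whenever
animals are far apart.  Unmatched detections seed new tracks; a track
unmatched for more than `max_gap` frames closes.  Defaults `max_disp` =
0.5 mm/frame (comfortably above the ~0.3 mm/s speed ceiling) and
`max_gap` = 2.  When animals merge into one blob, one track claims it and
the other terminates — fragmentation is preferred to identity guessing.
Tracks shorter than 2 frames are discarded as singletons (counted in
diagnostics, so detections are conserved).

Bridged 1–2-frame gaps are filled by linear interpolation before
kinematics so differencing sees a uniform dt; a track's interpolated
frames are a strict subset of its gap frames by construction.

## Kinematics

- raw speed: |p(i+1) − p(i)| / dt (path distance per interval);
- speed recording: mean over a 5-sample (5 s) sliding window, full windows
  only, so every smoothed sample has equal variance; trailing indexing;
- acceleration: first difference of the smoothed speed over dt;
- events: maximal runs of strictly same-sign acceleration; duration = run
  length × dt, peak = signed extreme; samples within 1e−12 mm/s² of zero
  are treated as exact zeros (differencing round-off) and belong to no
  event.

Per-track statistics use the smoothed speed: mean, SD (sample, n−1
denominator), CV = SD/mean (undefined, not infinite, at zero mean), RMS
acceleration, mean event duration and mean peak acceleration/deceleration
(absent, not zero, when a track has no events of the given sign).  Only
tracks spanning ≥ 30 s are analysed.  Whether the upstream assay computed
acceleration from raw or smoothed speed is not documented; smoothed is
used here, consistently with the definition of the speed recording.

## Population statistics

Pooled smoothed-speed histograms use half-open bins [k·w, (k+1)·w) of
width 0.006 mm/s (fractions of time, summing to 1).  The population
average speed is the mean of all pooled samples — long tracks weigh more,
by definition.  For curve comparisons each track is one independent
measurement: tracks are binned by average speed (floor(avg/width), width
0.03 mm/s by default), per-bin mean ± SEM is reported, and genotype
differences across the curve are tested with a two-way ANOVA
(value ~ genotype + speed-bin, main effects, Type-II sums of squares on
the unbalanced design, via statsmodels OLS).  Bins with fewer than 2
tracks are excluded (no within-bin variance); an interaction term is
available but off by default since the comparison of interest is the
curve-level genotype effect.  Pairwise comparisons use Student's
pooled-variance t-test (Welch behind a flag).  No multiple-testing
correction is applied.  Degenerate designs raise; degenerate-variance
t-tests return p = 1 (equal constant groups) or p = 0 (separated constant
groups) by convention.

## Reproducibility and problem sizes

All randomness flows from one root seed (`numpy.random.default_rng`);
identical configs give byte-identical outputs, recorded with SHA-256
checksums in a run manifest.  The validation suite uses desk-scale
problem sizes chosen once: 1000-series / 500-instance oracle comparisons,
100 seeded 20-animal assays for exact identity recovery, a 20 000-step
trace for closed-form SD recovery (±5%), 1000 null replicates of 20
tracks/genotype for test calibration (99% binomial band 3.5–6.5% at
α = 0.05), and 100 runs of 200 tracks/genotype for the fluctuation
contrast (σ doubled at matched μ: binned SD curve higher in every shared
occupied bin, genotype p < 0.01) and the dissociation control (μ lowered
at fixed σ: genotype p > 0.05).  "Shared occupied" means ≥ 2 tracks per
genotype in the bin, the same rule the SEM and ANOVA use.

## Known limitations

Identity swaps between animals closer than the gate are possible and
unflagged (real trackers share this); the ANOVA assumes within-cell
normality, adequate for per-track SDs from ~100-sample tracks but not
guaranteed for short tracks; the reflected OU mean is biased above μ for
slow strains (μ ≲ stationary SD), so preset μ values are nominal;
rendering uses isotropic Gaussian blobs, so detector performance on real
worm silhouettes is out of scope.
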