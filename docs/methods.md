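# Methods

## Scope and model

`migshuttle` quantifies the nucleocytoplasmic localization of Mig1-GFP in
single yeast cells across a media shift, and provides a synthetic-data
generator that emulates the experiment closely enough that every pipeline
stage can be validated against known ground truth.  The generator is a
first-class component: its defaults define the study conditions under which
all validation numbers in this repository are computed.

### Acquisition model

Frames are taken every 30 min from −240 to 0 min (relative to the shift)
and every 5 min from 0 to 720 min; the shift frame t = 0 belongs to both
grids and is counted once, giving 153 frames.  The expression-level marker
channel (mAmetrine-like) is acquired only on every 4th post-shift frame
(37 frames) to model photodamage avoidance; all other channels are imaged
at every frame.

### Ground-truth localization dynamics

Each cell's noise-free localization index is

```
index(t) = b                                                        t < 0
index(t) = b + A·k(t) + (L − b)·(1 − e^(−t/τ)) + Σ pulses(t)        t ≥ 0
```

with basal level `b`, initial-response amplitude `A`, plateau `L`, and the
gamma-shaped kernel `k(t) = (t/t_peak)^(t_peak/τ) · e^((t_peak − t)/τ)`,
which has unit maximum exactly at `t_peak` (default 30 min) and an
exponential tail with time constant `τ` (default 60 min).  This is the
simplest smooth two-parameter shape with the observed rise-by-30-min /
decay-over-hours behaviour.

Shuttling pulses are Gaussian bumps (FWHM 10 min, default mean height 0.4)
whose arrival times form a renewal process: inter-arrival = refractory gap
+ exponential, with the refractory gap set to 1.5× the pulse FWHM (15 min)
and the exponential mean chosen so the mean gap is exactly `60/λ` minutes.
Two consequences were design goals: consecutive pulses always remain
resolvable as distinct local maxima at the 5-min sampling interval (bumps
closer than ~13 min would merge into one maximum), and — because the first
arrival is drawn from the equilibrium residual-life distribution — the
expected pulse count in any window is exactly `λ · Δt`.  Pulses run from
`pulse_start` (default 240 min) to the end of the movie: pulsatile
shuttling is a property of adapted cells, and the adapted-phase metrics
window (240–480 min) is where pulse statistics are defined; placing pulses
on the decaying initial response would also make their basal-referenced
heights systematically unmeasurable.

Cell-to-cell variability is multiplicative log-normal jitter with unit
mean (CV 0.3 by default) on `A`, `λ` and pulse height — a standard minimal
model of expression-capacity variability.  Trace-only observation adds
i.i.d. Gaussian noise (σ = 0.05 index units) per sample.

### Reporter kinetics

The promoter-reporter (destabilized Citrine-like) is modelled as: zero
production before the shift; leaky production at `repressed_rate` from
t = 0; a step to `derepressed_rate` at `derepression_onset`; conversion of
immature to fluorescent protein after a fixed `maturation_delay` (default
30 min, a Citrine-class maturation time); first-order decay of the
fluorescent pool at `degradation_rate` (default 0.023 min⁻¹, ~30-min
half-life as appropriate for a destabilized reporter).  The solution is
evaluated in closed form as a superposition of first-order step responses,
so reporter traces are exact, and steady state equals rate/degradation.

### Strain × hexose presets

The preset table (`src/migshuttle/data/presets.yaml`) encodes the
qualitative response matrix: the initial peak appears whenever the strain
can phosphorylate the sugar at all; adapted-phase shuttling requires Hxk2
on glucose/mannose and Hxk1 or Hxk2 on fructose; overexpressed Hxk1/Hxk2
restore shuttling dose-responsively while Glk1 never does; the reporter
derepresses on glucose/fructose where shuttling-based repression fails
(weakly, 1.5-fold, for *hxk2Δ* on fructose) and partially in all strains
on mannose; and hexokinase overexpression on mannose is toxic above an
expression-marker threshold (1000 AU for +Hxk2, 1500 AU for +Hxk1), with
dying cells freezing in place and intensity.  Absolute magnitudes
(`A`, `λ`, `L`) are free parameters — only their orderings across
conditions are meaningful, and nothing downstream depends on their exact
values except through the qualitative classification.

### Rendering

Cells are circles (radius 12 ± 1.5 px by default) with concentric nuclei
occupying 12% of the cell area, placed without overlap (random sequential
placement with a jittered-grid fallback at high density) and drifting as a
bounded per-cell random walk (1 px/frame step).  Brightfield above/below
focus renders each cell as a bright/dark Gaussian ring of opposite
polarity on a shared background × illumination field, the minimal pattern
whose ratio cancels illumination and enhances the outline.  The GFP
channel fixes each cell's total fluorescence and chooses the
nucleus:cytoplasm intensity split analytically so that, background
included, `median(nuc)/median(cell) − 1` equals the ground-truth index
*exactly* — rendering is invertible at zero noise, which is what makes
round-trip validation meaningful.  The illumination field multiplies every
channel (brightfield and excitation share the optical path).  Camera noise
is Poisson-like (variance ∝ intensity) plus Gaussian read noise; both
default on and can be zeroed.

## Measurement pipeline

**Brightfield division** is pixelwise `above/(below + ε)` with
ε = 10⁻⁶ × median(below) guarding against blow-ups.

**Segmentation** thresholds the smoothed |log| of the divided image
(Otsu, floored at 0.1), closes and fills the ring interiors, splits
touching cells by watershed on the distance transform, erodes the ring
half-width, and filters by area (80–2500 px) and solidity (≥ 0.8).  This
is a documented equivalent of ring-pattern segmenters, not a re-creation
of any specific tool; the package's contribution is the quantification.

**Nucleus identification** takes the largest connected component of the
Otsu-thresholded nuclear-marker channel inside the cell; if the marker is
absent or flat, or would select the whole cell, it falls back to the
brightest contiguous 12% of the cell's GFP pixels (greedy region growth,
deterministic tie-breaks, exact target size).  Which definition the
original analyses used is not documentable, so the strategy is an option.

**Measurement** uses medians for the localization index (exactly the
defining formula) and means for the reporter/expression channels (linear
in expression).  Non-positive whole-cell medians flag the measurement
invalid; invalid points become missing values downstream.

**Tracking** links frames by optimal bipartite assignment on centroid
distance with a hard gate (default 15 px), bridges detection gaps of up to
1 frame with a proportionally relaxed gate, and can require tracks to span
from before the shift to past 240 min so each cell contributes both
short- and long-term metrics.  Divisions are not lineage-tracked: daughters
start new tracks.

## Trace metrics

- `basal`: mean index over t < 0.
- `max_short`, `t_max_short`, `mean_short`: over 0–60 min (≥ 3 points
  required; ties resolve to the earliest time).
- `mean_long`: over 240–480 min, requiring ≥ 50% frame coverage.
- Pulses: local maxima in 60–480 min with topographic prominence ≥
  max(0.1, 3σ̂) and pairwise separation ≥ 15 min; single-frame gaps are
  linearly interpolated, longer gaps split the trace.  Height is measured
  from the basal reference (the figures' basal line); `height_baseline=
  "local"` instead uses the prominence.  Width is at half prominence.
- σ̂ is the median-absolute-successive-difference noise estimate computed
  on the *pre-shift* frames (they carry no signal by design; successive
  differences inside the pulse window ride on pulse flanks and
  overestimate noise ~2×).  In the pipeline path σ̂ is pooled (median)
  across the cells of a condition, since measurement noise is a property
  of the acquisition, not of the cell: per-trace thresholds from 8
  pre-shift differences scatter enough (90th percentile ≈ 0.28 vs nominal
  0.15) to distort pulse statistics.
- Expression: `expr_mean_long` (mean reporter over 240–480 min) and
  `expr_onset`, the first post-shift time the reporter exceeds the
  pre-shift mean + 3 SD for 3 consecutive frames.

Characterized detector operating point under the default study conditions
(λ = 2/h, heights 0.4 with CV ≈ 0.44, σ = 0.05, 5-min sampling): detected
rate ≈ 0.87–0.90 of the true rate (small pulses in the log-normal tail
fall below the 3σ prominence cut, and close unequal pairs occasionally
merge), mean height bias ≈ +0.03 (initial-response tail plus noise-maximum
selection, partly cancelled by sampling attenuation), and a noise-only
background of ≈ 0.4 false pulses/h.  These numbers set the qualitative
classifier below.

## Statistics and reporting

Cells are independent units.  Groups are summarized by mean, sample SD and
t-based 95% CI.  Comparisons against the reference condition use Welch's
unequal-variance t test — strains contain different cells, so no pairing
exists; a permutation test on the mean difference is available.  No
multiple-testing correction is applied by default (Benjamini–Hochberg is
provided).  Fold changes are ratios of group means of `expr_mean_long`;
with a non-positive reference the absolute difference is reported instead.
The dose–response analysis bins cells by quantiles of the
expression-marker level and reports binned means plus the Spearman rank
correlation.  The viability filter drops generator-flagged dead cells and
estimates the toxicity threshold as the midpoint between the highest
viable and lowest dead expression levels.

The qualitative matrix classifies each condition from its *measured*
metrics: initial response present if group mean (max_short − basal) > 0.2
(no-response conditions score ≈ 0.08 from noise maxima alone, the weakest
responder ≥ 0.5); shuttling present if the mean detected pulse rate in
240–480 min exceeds 0.8/h (midway between the detector's 0.4/h noise
background and the ~1.2/h of the weakest shuttling condition); reporter
derepressed if the group's expression exceeds 1.25× the repressed
reference (the weakest modelled derepression is 1.5-fold).  The reporter
flag is only compared on glucose and fructose; on mannose derepression is
graded across all strains and excluded from the binary table.

## Validation problem sizes

The test suite and the reproduction script use: 1000 random masks for
index exactness; a 10-cell noise-free movie for illumination invariance
(noise is zeroed so the comparison isolates the illumination effect); 500
random traces (length ≤ 200) for the pulse-detector oracle; 200 cells per
condition for parameter recovery; a 20-cell, 153-frame, 256×256 px movie
for segmentation/tracking; 1000 replicates of 50-cell groups for
statistical calibration (the true group mean is computed analytically from
the model: deterministic trace average plus stationary pulse mass with the
onset ramp); and 50 cells per condition for the 21-condition matrix.

## Known limitations

- The generator does not model growth/budding lineages, photobleaching,
  focus drift, or microfluidic flow artifacts; cells are circles with
  concentric nuclei.  Passing round-trip tests therefore demonstrates the
  measurement chain's correctness on idealized geometry, not robustness to
  real-cell morphology.
- Preset magnitudes are not calibrated to any published absolute values
  (none exist for this index); only qualitative orderings are meaningful.
- Pulse detection at 5-min sampling of ~10-min events is inherently lossy
  (~10% of pulses); rate comparisons between conditions are unaffected
  because the detector is identical across conditions, but absolute rates
  underestimate the true event frequency.
- The brute-force pulse oracle and the detector share a declared contract
  (plateau-midpoint maxima, border-bounded prominence, greedy separation);
  equality tests validate the implementation against the definition, not
  the biological appropriateness of the definition.
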