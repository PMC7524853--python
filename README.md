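# migshuttle

Single-cell quantification of Mig1 nucleocytoplasmic shuttling in budding
yeast time-lapse microscopy.

## The problem

Mig1 is the transcriptional repressor that executes carbon catabolite
repression in *Saccharomyces cerevisiae*: when a preferred hexose (glucose,
fructose, mannose) is available, Mig1 enters the nucleus and shuts down
genes for alternative carbon sources such as *SUC2*; when the Snf1 kinase is
active under sugar limitation, Mig1 is phosphorylated and exported.  In
microfluidic media-shift experiments, single cells shifted from ethanol to a
hexose show a *biphasic* response: a rapid initial nuclear-accumulation peak
(maximal within ~30 min) that decays over hours, followed by an adapted
phase in which Mig1 pulses between nucleus and cytoplasm on a minutes
timescale.  Which phases appear depends on the sugar kinases present
(Hxk1, Hxk2, Glk1) and on the hexose.

This package is for researchers analysing such movies (or modelling them).
It implements the full measurement chain and a synthetic-movie generator
that gives every stage a known-answer test bed:

- **synthetic data** — per-cell ground-truth localization dynamics
  (gamma-shaped initial response, adapted-phase plateau, stochastic
  shuttling pulses, cell-to-cell variability), a promoter-reporter model
  with fluorophore maturation lag, and a renderer producing two-plane
  brightfield + 4 fluorescence channels with ground-truth masks;
- **image pipeline** — brightfield division (above-focus / below-focus,
  cancelling uneven illumination), ring-based cell segmentation, nucleus
  identification, and per-cell intensity measurement;
- **tracking** — optimal bipartite (Hungarian) frame-to-frame linking with
  gap bridging;
- **trace metrics** — basal level, short-term maximum (0–60 min),
  adapted-phase mean (240–480 min), prominence-based pulse detection, and
  reporter-expression metrics;
- **statistics & reporting** — group means with SD and t-based 95% CIs,
  Welch tests against wild type, fold changes, dose–response analysis,
  viability filtering, and a qualitative strain × hexose response-matrix
  check.

## The statistic at the core

For each cell in each frame, with GFP fluorescence *f*, the localization
index is

```
index = median(f over nuclear mask) / median(f over whole-cell mask) − 1
```

so 0 means uniformly distributed Mig1-GFP, positive values nuclear
enrichment, and the ratio form makes the index invariant to global
intensity scaling and (to first order) to slowly varying illumination.
Per-cell traces of this index are summarized by the biphasic metrics above;
shuttling pulses are local maxima with topographic prominence at least
3× the pooled measurement-noise SD (floor 0.1), separated by ≥ 15 min,
with heights measured from the pre-shift basal level.

## Worked example

`examples/04_group_statistics.py` compares wild type and the *hxk2Δ* mutant
on glucose (60 simulated cells each):

```
wt      mean_long = 0.532
hxk2Δ   mean_long = 0.091  sd = 0.014  95% CI = [0.088, 0.095]
Welch test vs wt: p = 1.97e-48  significant at 0.05: True
reporter derepression (ratio): 7.8-fold over wild type
```

Wild-type cells keep Mig1 partly nuclear in the adapted phase
(mean 240–480 min index ≈ 0.53 at these preset magnitudes), while deleting
*HXK2* collapses it to near the basal level (≈ 0.09 ≈ basal + detection
background) and derepresses the destabilized *SUC2*-promoter reporter
about eightfold — the loss-of-repression phenotype.  The other examples
walk through simulation (`01`), rendering + segmentation round trips
(`02`, median RMSE vs ground truth ≈ 0.05 index units), pulse detection on
a constructed trace (`03`, heights 0.500/0.300 recovered exactly at the
5-min sampling), and a small end-to-end grid with the matrix check (`05`).

A thin CLI wraps the same library calls:

```
migshuttle simulate --config run.yaml --out out/
migshuttle analyze  --movie out/wt_glucose/movie --out tables/
migshuttle report   --metrics out/ --reference wt:glucose --out report/
```

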