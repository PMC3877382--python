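# mitodyn

Quantification of mitochondrial dynamics in cultured neurons: axonal
transport from time-lapse movies, organelle morphometry, membrane-potential
dye intensity, and extracellular-flux bioenergetics — together with a
synthetic-data generator that produces all of these inputs with known
ground truth.

The package is aimed at labs quantifying organelle trafficking phenotypes
(for example the axonal transport deficit of A53T α-synuclein neurons, a
Parkinson's disease model) who want the entire measurement chain —
simulation, detection, tracking, segmentation, decomposition, statistics —
as reusable, tested Python instead of a mixture of ImageJ macros and
spreadsheets.

## What it computes

**Axonal transport** (`mitodyn.transport`). Movies are 2D+t stacks of
fluorescent puncta moving along an axon. Puncta are detected per frame
(difference-of-Gaussians band-pass, sub-pixel centroids) and linked into
tracks with a velocity-predictive nearest-neighbour linker that survives
organelles passing each other. For each track with positions x(t) along
the axon:

- overall velocity `v̄ = |x(T) − x(0)| / T` (net displacement over elapsed
  time, pauses included);
- mobile iff `v̄ ≥ 0.005 μm/s` (boundary inclusive); the cohort mobile
  fraction is the percentage of mobile tracks;
- instantaneous velocity: mean of `|Δx|/Δt` over frame pairs above the
  mobility threshold (pauses excluded), reported for mobile tracks only;
- direction (anterograde/retrograde) from the sign of the net displacement
  relative to the soma end.

Kymographs — the maximum pixel value over a five-pixel-wide line along the
axon, one row per frame — are built as a visual cross-check: stationary
organelles appear as vertical lines, moving ones as diagonals.

**Morphometry** (`mitodyn.morphology`). Global threshold (Otsu),
8-connected components, exclusion of touching and border objects, then per
object: length (major axis of the second-moment ellipse), width (minor
axis), `circularity = 4πA/P²`, `aspect ratio = major/minor`, and
`roundness = 4A/(π·major²)`. The perimeter P uses a rasterization-corrected
sub-pixel contour estimator (naive pixel counting depresses a disc's
circularity by ~20%).

**Membrane potential** (`mitodyn.potential`). Mean intensity of a
ψ_m-sensitive dye (MitoTracker Red / TMRM) inside soma ROIs, reported as
percent of the control-group mean.

**Bioenergetics** (`mitodyn.bioenergetics`). From OCR phase means B
(baseline, mean of 4 readings), O (post-oligomycin), F (post-FCCP), R
(post-rotenone/antimycin):

    non-mitochondrial = R        mitochondrial = B − R
    ATP-linked        = B − O    proton leak   = O − R
    maximal capacity  = F − R    OCR/ECAR ratio = B / basal ECAR

so `mitochondrial = ATP-linked + proton leak` holds as an exact algebraic
identity on every trace.

**Synthetic data** (`mitodyn.simulate`, `mitodyn.presets`). Named presets
(`wt_7div`, `a53t_7div`, `wt_14div`, `a53t_autophagosome`,
`a53t_rapamycin`, `wt_len`, `a53t_flux`, …) are calibrated so the expected
cohort statistic equals the corresponding condition mean (e.g. 0.021 μm/s
for wt at 7 days in vitro, 1.96 μm mean length, 169.1 pmol/min basal OCR).
Mobile particles follow two-state run/pause kinetics with truncated-normal
run speeds; everything is reproducible bit-for-bit from a seed.

**Statistics and pipeline** (`mitodyn.stats`, `mitodyn.pipeline`). Mean ±
SEM summaries, Student/Welch two-sample t-tests, and `run_pipeline(config)`
which executes simulate → analyze → summarize for all stages and writes a
deterministic CSV/PNG report bundle. A thin CLI wraps it:
`mitodyn all --config examples/demo_config.yaml --out demo_out`.

## Worked example

```bash
python examples/bioenergetics_demo.py
```

prints, for the noise-free A53T flux preset:

```
a53t_flux (noise-free, pmol/min per 40,000 cells):
  basal OCR             169.1
  OCR/ECAR ratio         5.28
  mitochondrial         127.1
  ATP-linked            101.0
  proton leak            26.1
  non-mitochondrial      42.0
  maximal capacity      188.0
```

Basal OCR is the mean of the four baseline readings; the remaining rows
are the phase-difference decomposition above. Compared with `wt_flux`
(basal 160.3, ratio 6.41, maximal capacity 272.0), the A53T profile shows
the characteristic pattern: similar basal respiration but lower ATP-linked
and maximal respiration, higher non-mitochondrial oxygen consumption, and
a lower OCR/ECAR ratio (a more glycolytic state).

`python examples/transport_demo.py` does the same for transport — a wt
movie recovers a cohort of 94 tracks at ≈0.02 μm/s with >40% mobile, an
A53T movie ≈0.002 μm/s with <10% mobile — and the other examples cover
kymographs, morphometry and the membrane-potential normalization.

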