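# spt-modes

Single-particle-tracking (SPT) analysis of membrane-receptor mobility:
from localization tables to diffusion coefficients, diffusion-mode
populations, and time-resolved ligand-response profiles.

Receptor tyrosine kinases such as HER2 change their lateral mobility in the
plasma membrane when they are recruited into signaling complexes: freely
diffusing receptors become confined or immobile upon ligand-induced
heterodimerization. SPT makes this visible at the single-molecule level, and
because each imaged cell can carry its own time stamp, a sequence of cells
measured in one dish turns receptor mobility into a time course of receptor
activation. This package implements that analysis chain for anyone working
with ThunderSTORM-style localization tables — and ships a synthetic-data
generator with known ground truth so every stage is recovery-testable.

## What it computes

For each trajectory segment with at least 20 localizations the time-averaged
mean squared displacement

MSD(n·Δt) = ⟨|r(t + n·Δt) − r(t)|²⟩

is fit over its first 4 points with an ordinary least-squares line,
MSD(t) = 4·D·t + 4·σ_dyn²; the slope gives the diffusion coefficient D
(µm²/s) and the intercept the dynamic localization precision σ_dyn. Segments
are classified into three diffusion modes:

- **immobile** — D < D_min, with D_min = σ_Q3²/(4·Δt) from the third
  quartile of the dynamic localization precision (published per-target
  values, e.g. 0.0084 µm²/s for HER2, are available as overrides);
- **confined** — the anomalous exponent α of MSD(t) = 4·Γ·t^α + c falls
  below a length-calibrated critical value (sub-linear MSD);
- **free** — otherwise (linear MSD).

Per cell this yields the global D, the mode fractions and per-mode D. Cells
are pooled into 1- or 5-minute intervals relative to ligand addition;
baselines are aligned across conditions, and each property is reported as a
relative change from its pre-ligand baseline with the standard error of the
difference (SED). Group comparisons use Shapiro–Wilk screening plus
two-sided Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired) tests
with the star scheme (* p<0.05, ** p<0.01, *** p<0.001).

The tracking stage estimates its own parameters from the data (per-cell
precision, expected frame-to-frame displacement from mutual-nearest-neighbour
links, bleaching probability as the geometric MLE of segment durations) and
links localizations with a greedy nearest-neighbour assignment with gap
closing.

## Worked example

The numbered scripts under `analysis/` run the full study design on
synthetic data: 25 cells imaged sequentially over 30 min (1000 frames at
20 ms each), the EGF-like ligand response starting after cell 5.

```
python analysis/01_simulate_experiment.py
python analysis/02_link_trajectories.py
python analysis/03_diffusion_modes.py
python analysis/04_timecourse.py
python analysis/05_stats_report.py
```

Output of steps 3–5 (seed 1):

```
D_min used: 0.0084 µm²/s (mode: override)
analyzed 25 cells, 1742 segments
resting    : D_global = 0.098 µm²/s, fractions imm/conf/free = 0.110/0.271/0.619
stimulated : D_global = 0.074 µm²/s, fractions imm/conf/free = 0.228/0.267/0.505

relative change of f_imm: [-5,0): +0±23%, [0,5): +115±49%, [5,10): +156±36%,
  [10,15): +108±31%, [15,20): +91±17%, [20,25): +68±29%
immobile fraction peaks in [5,10) at +156%

resting vs stimulated (Mann-Whitney U, two-sided):
  D_global  p = 1.09e-03  **
  f_imm     p = 3.12e-03  **
  f_free    p = 2.64e-04  ***
```

Reading this: in resting cells ~11% of receptors are immobile and the global
diffusion coefficient is ~0.10 µm²/s; after ligand addition the immobile
fraction roughly doubles (peaking in the 5–10 min interval, +156% relative
to baseline), freely diffusing receptors are lost in exchange, and the shift
is statistically significant across cells. The free-D dip trails the
immobilization by about 5 minutes — both mirror the injected ground truth.

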