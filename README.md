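# renalperf

Multiparametric quantification of renal perfusion and oxygenation for
canine kidney imaging studies.

Functional MRI (arterial spin labeling, BOLD relaxometry, dynamic
contrast-enhanced imaging) and contrast-enhanced ultrasound each probe a
different facet of kidney physiology: ASL measures renal blood flow (RBF,
mL/100 g/min) with magnetically labeled blood water, BOLD measures the
apparent transverse relaxation rate R2\* = 1/T2\* (1/s), which rises with
deoxyhemoglobin and hence falls with better oxygenation, DCE-MRI tracks a
gadolinium bolus through the kidney to estimate plasma flow and a
filtration surrogate, and CEUS parameterizes a microbubble time-intensity
curve.  `renalperf` implements the full quantitative chain needed to
compare these modalities regionally and to detect a pharmacological
challenge (low-dose dopamine vs. saline) in a crossover design of 8
subjects x 2 treatments x 2 kidneys — together with a synthetic phantom
cohort so every stage is testable without any scanner data.

## What it computes

* **Regional partitioning** — the twelve-layer concentric objects scheme
  (TLCO: each parenchymal pixel classified by its normalized centroid
  distance r/R(θ) into 12 equal-thickness layers; layer 1 outer, 12
  inner; cortex = layers 1–3, medulla = layers 8–10, whole kidney = all)
  and the ten-equiangular-objects scheme (TEO: pole-to-pole segments,
  1 = caudal, 10 = cranial).
* **BOLD** — voxelwise mono-exponential fit S(TE) = S0·e^(−R2\*·TE) over
  12 echoes (weighted log-linear or nonlinear least squares).
* **ASL** — pulsed-ASL quantification
  RBF = 6000·λ·ΔM / (2·α·M0·τ·e^(−TI/T1b)), ΔM = control − label,
  averaged over two consecutive runs.
* **DCE** — signal→concentration conversion (relative enhancement or SPGR
  inversion), gamma-variate arterial input functions with four aortic ROI
  placements (Cr25, Cr12, Ca, AD) adding configurable delay/dispersion,
  and four plasma-flow analyses: maximum slope (MS), model-free Tikhonov
  deconvolution (MF), two-compartment uptake (C2UM) and filtration (C2FM)
  models; RBF = F_p/((1−Hct)·ρ).
* **CEUS** — the seven bolus parameters PI, WiR, WoR, TTP, RT, FT, AUC
  (plus the TI/TO regression intercepts) from raw time–intensity samples.
* **Statistics** — Spearman correlations with Schober interpretation bands
  and Bonferroni correction, linear mixed models (treatment fixed effect;
  dog / side-within-dog / segment nesting) with likelihood-ratio tests,
  and treatment-delta reporting tables.

## Worked example

```python
from renalperf import (StudyConfig, run_pipeline, summary_from_means,
                       treatment_delta)
from renalperf.synthetic import REGIONAL_REFERENCE

# 1. treatment-delta reporting on the published canine regional means
ref = lambda t: summary_from_means(
    "TLCO-12", "RBF",
    {r: REGIONAL_REFERENCE[t][r]["RBF"] for r in ("cortex", "medulla", "whole")})
print(treatment_delta(ref("dopamine"), ref("control")))

# 2. synthetic ASL+BOLD cohort, end to end
cfg = StudyConfig(master_seed=1, modalities=("asl", "bold"))
bundle = run_pipeline(cfg)
```

This prints the reference deltas

```
 region  treated_mean  control_mean  delta
 cortex        409.87        338.72  71.15
medulla        177.46        156.63  20.83
  whole        279.79        232.21  47.58
```

(+71.15 mL/100 g/min cortical RBF under dopamine, etc.), and the fitted
cohort reproduces the physiology built into the phantom:

```
ASL whole-kidney dopamine effect: +52.9 mL/100 g/min, p = 5.05e-11
BOLD medullary dopamine effect:   -2.51 1/s, p = 1.20e-07
baseline Spearman RBF vs R2*: cortex r = -0.67 (moderate), medulla r = -0.71 (strong)
```

i.e. dopamine raises perfusion and lowers medullary R2\* (better
oxygenation), and at baseline perfusion and R2\* are inversely related.

A command-line interface mirrors the library stage by stage
(`renalperf simulate | regions | fit-bold | fit-asl | fit-dce | fit-ceus |
stats | run-all`), reading and writing NIfTI images and CSV tables so real
data can replace the simulator at any stage.

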