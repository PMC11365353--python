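# kexmeta

Meta-analytic prediction equations for **urinary and fecal potassium
excretion in dairy cattle**, built from study-level treatment means.

Potassium fed in excess of requirement leaves the cow mainly through urine
and, to a lesser extent, feces; predicting those flows from quantities a
nutritionist already knows (dry-matter intake, K intake, dietary K
concentration, water intake, urine volume, milk yield) supports manure
management and environmental assessment without total-collection balance
trials. `kexmeta` implements the full modelling workflow used for this kind
of literature meta-analysis:

- a **treatment-mean database** layer (CSV in/out, per-row validation,
  derivation of K intake as DMI × dietary K × 10, Table-style summaries);
- **IQR outlier screening** (Tukey fences, factor 1.5, full audit trail);
- a **weighted random-intercept linear mixed model** fitted by REML,

  ```
  Y_ij = β₀ + β₁ X_ij + S_i + e_ij,   S_i ~ N(0, τ²),   e_ij ~ N(0, σ²/w_ij)
  ```

  where `S_i` is the shared intercept deviation of study *i* and the weight
  `w_ij` is the number of animals behind treatment mean *j* — a mean of many
  animals is a more precise observation. The REML criterion is profiled over
  the single variance ratio θ = τ²/σ², so each fit is a bounded
  one-dimensional search with closed-form GLS at every step;
- **leave-one-study-out cross-validation** (each fold holds out one whole
  publication; held-out predictions use fixed effects only), scored by the
  **MSPE decomposition** into mean bias `MB = (P̄ − Ō)²`, slope bias
  `SB = (S_p − r·S_o)²` and random error `ED = (1 − r²)·S_o²` (population
  SDs, so MB + SB + ED = MSPE exactly), plus RMSPE as % of the observed
  mean, RSR (RMSPE / sample SD of observations), Pearson *r* and **Lin's
  concordance correlation coefficient**;
- a **synthetic multi-study generator** with exactly the generative
  structure the model assumes, including calibration presets for the
  urinary (slope 0.65 g/g) and fecal (slope 0.126 g/g) K-intake equations,
  so every stage is testable end to end;
- a **pipeline** (`kexmeta.pipeline.run`, or the thin `kexmeta` CLI) that
  chains load → derive → screen → fit all candidates → LOSO-CV → metrics →
  rank and writes a reproducible, seed-stamped report bundle.

## Worked example

```python
import dataclasses
from kexmeta import (URINARY_K_INTAKE, ModelSpec, generate, fit,
                     loso_cv, decompose_mspe)

db = generate(dataclasses.replace(URINARY_K_INTAKE, seed=42))
model = fit(db, ModelSpec("k_ur", "k_intake"))
print(model.equation())
cv = loso_cv(db, ModelSpec("k_ur", "k_intake"))
m = decompose_mspe(cv)
print(f"RSR={m.rsr:.2f} CCC={m.ccc:.2f} RMSPE%={m.rmspe_pct:.1f}")
```

prints

```
k_ur = -2.464 (±9.13) + 0.6444 (±0.00978) × k_intake
RSR=0.28 CCC=0.96 RMSPE%=11.1
```

The fitted slope 0.644 (±0.010) recovers the generating truth 0.65: each
extra gram of ingested K adds about 0.65 g of urinary K per day. RSR well
below 0.5 and CCC near 1 say the equation transfers to studies it never
saw; the MSPE decomposition (`m.mb_pct`, `m.sb_pct`, `m.ed_pct`) attributes
essentially all remaining error to random scatter rather than systematic
bias. The scripts in `examples/` walk through simulation, fitting,
cross-validation and the full ranked pipeline one step at a time.

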