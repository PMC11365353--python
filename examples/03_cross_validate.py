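"""Judge a model on unseen studies: LOSO-CV plus the MSPE decomposition.

Each fold holds out one whole study, refits on the rest and predicts the
held-out means from the fixed effects alone.  MB/SB/ED split the prediction
error into a location shift, a scale mismatch, and irreducible scatter (they
sum to 100% of MSPE); RSR compares RMSPE to the spread of the observations
(lower is better, < 0.5 is usually called good) and CCC measures agreement
with the identity line.
"""

import dataclasses

from kexmeta import ModelSpec, URINARY_K_INTAKE, decompose_mspe, generate, loso_cv

db = generate(dataclasses.replace(URINARY_K_INTAKE, seed=42))
cv = loso_cv(db, ModelSpec("k_ur", "k_intake"))
m = decompose_mspe(cv)

print(f"{cv.n_folds} folds, {m.n} observed/predicted pairs")
print(f"RMSPE  : {m.rmspe:6.1f} g/d  ({m.rmspe_pct:.1f}% of the observed mean)")
print(f"MB/SB/ED: {m.mb_pct:.1f}% / {m.sb_pct:.1f}% / {m.ed_pct:.1f}% of MSPE")
print(f"RSR    : {m.rsr:6.2f}")
print(f"CCC    : {m.ccc:6.2f}   (Pearson r = {m.pearson_r:.2f})")
print(f"bias significance: mean p = {m.p_mean_bias:.2f}, slope p = {m.p_slope_bias:.2f}")
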