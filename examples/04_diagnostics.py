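"""Model diagnostics: residual ACF, visual predictive check, EBLUP shrinkage.

Fits the base model to a small simulated cohort and runs the diagnostic
suite: whitened-residual autocorrelation (should be flat if AR(1) captured
the serial correlation), a simulation-based predictive band (should hold
~90% of the observations), and subject-level EBLUP trajectories.
"""

import numpy as np

import circspline as cs
from circspline import lmm
from circspline.models import ModelSpec, fit_circadian, predict_subject

profiles, _ = cs.simulate_cohort(cs.default_config(n_subjects=40), seed=41)
cfit = fit_circadian(profiles, ModelSpec(constrained=False), seed=0)

acf = lmm.residual_acf(cfit.fitted, cfit.data, max_lag=6)
band = 3 / np.sqrt(cfit.data.n_obs)
print("whitened-residual ACF (values beyond +-%.3f would flag misfit):" % band)
print(acf.round(3).to_string(index=False))

vpc = lmm.vpc(cfit.fitted, cfit.data, nsim=200, seed=5)
lo = dict(zip(vpc["slot"], vpc["sim_lo"]))
hi = dict(zip(vpc["slot"], vpc["sim_hi"]))
inside = sum(
    lo[s] <= v <= hi[s]
    for b in cfit.data.blocks
    for s, v in zip(np.round(b.slots).astype(int), b.y)
)
total = cfit.data.n_obs
print(f"\nVPC: {inside}/{total} = {inside / total:.1%} of observations inside "
      f"the simulated 5-95% band (target ~90%)")

sid = cfit.data.blocks[0].subject_id
traj = predict_subject(cfit, sid)
obs = cfit.data.blocks[0].y
print(f"\nsubject {sid}: observed SD {obs.std():.1f} mmHg, "
      f"residual SD about own EBLUP trajectory "
      f"{(obs - traj['value'].to_numpy()).std():.1f} mmHg")
# The EBLUP trajectory absorbs the subject's own intercept and slopes, so
# its residual SD approaches the within-subject sigma rather than total SD.
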