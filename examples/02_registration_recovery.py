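"""Registration parameter recovery.

Applies known rigid transforms (rotations up to 35 deg, translations up to
15 mm) to remeshed copies of a synthetic vertebra, registers each copy back
onto the original by ICP, and prints the residual rotation (deg) and
translation (mm) errors.  Errors far below 0.5 deg / 0.3 mm mean the
registration chain can resolve intervertebral motion at the scale joints
actually move.
"""

from cervkin.evaluation import parameter_recovery_trials

for sigma in (0.0, 0.2):
    trials = parameter_recovery_trials(n_trials=5, noise_sigma=sigma, seed=42)
    print(f"surface noise sigma = {sigma} mm")
    for _, row in trials.iterrows():
        print(f"  trial {int(row.trial)}: rotation error "
              f"{row.rot_error_deg:.4f} deg, translation error "
              f"{row.trans_error_mm:.4f} mm ({int(row.iterations)} iters)")
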