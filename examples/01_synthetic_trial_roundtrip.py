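"""Simulate a two-arm trial, digitize its KM curve, and reconstruct the IPD.

Demonstrates that the reconstruction recovers the published-figure
information: the re-estimated survival curve deviates from the digitized one
by well under one percentage point, and refitting the exponential model
recovers the simulated monthly death hazard.
"""

import warnings

from clipcea import (
    OSTruth,
    TrialSpec,
    digitize_km,
    fit_parametric,
    km_estimate,
    preprocess_curve,
    reconstruct_ipd,
    simulate_ipd,
    validate_reconstruction,
)

TRUE_HAZARD = 0.019  # per month

spec = TrialSpec(
    arm_sizes={"intervention": 300, "control": 300},
    os_truth={"intervention": OSTruth(rate=TRUE_HAZARD),
              "control": OSTruth(rate=TRUE_HAZARD)},
    censor_rate=0.012,
    follow_up_months=24,
    seed=9,
)
ipd = simulate_ipd(spec, "intervention")
km = km_estimate(ipd)
curve, risk_table = digitize_km(km, ipd, n_points=200, jitter_sd=0.0, seed=9)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    reconstructed = reconstruct_ipd(preprocess_curve(curve), risk_table)
report = validate_reconstruction(curve, reconstructed)
refit = fit_parametric(reconstructed, "exponential")

print(f"simulated arm size          : {len(ipd)}")
print(f"reconstructed records       : {len(reconstructed)}")
print(f"events (true / reconstructed): {ipd.event.sum()} / {reconstructed.event.sum()}")
print(f"max |S_rec - S_digitized|   : {report.max_abs_deviation:.4f}")
print(f"true monthly hazard         : {TRUE_HAZARD:.4f}")
print(f"refitted monthly hazard     : {refit.params[0]:.4f}")
# A max deviation near zero means the reconstructed patients reproduce the
# digitized survival curve; the refitted hazard sits within sampling error
# of the generating one.
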