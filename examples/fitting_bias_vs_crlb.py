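"""Fitting precision and bias of the three estimators against the CRLB.

Replicated grid-emitter movies on the striped sensor, fit by the
RQE-blind Poisson MLE, the RQE-corrected MLE and flat-field WLS.
"""

from scmosfit import accuracy_experiment

res = accuracy_experiment(seed=0, frame_shape=(160, 160), n_frames=300, n_replicates=3)

print(f"250 photons/frame, {res['n_replicates']} replicates")
print(f"CRLB position bound: {res['crlb_nm']['mean']:.1f} nm")
for est in ("mle", "mle-rqe", "wls"):
    r = res[est]
    print(
        f"{est:8s} precision {r['precision_nm']['mean']:5.1f} nm "
        f"({r['precision_over_crlb']:.2f} x CRLB)   "
        f"bias {r['bias_nm']['mean']:5.2f} +- {r['bias_nm']['std']:.2f} nm "
        f"(x: {r['bias_x_nm']['mean']:.2f}, y: {r['bias_y_nm']['mean']:.2f})"
    )
# All estimators reach near-CRLB precision, but the RQE-blind MLE carries a
# systematic position bias concentrated in x — the direction across the
# vertical RQE stripes; the RQE-corrected MLE is unbiased within error bars.
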