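"""Fit a biexponential to noisy synthetic samples and rerun the NCA.

Samples the KL25A iv disposition curve on a 14-point 0.25-24 h grid
with 5% proportional noise, recovers the curve by stripping plus
least-squares refinement, and compares the clearance estimate with the
generating truth.
"""

from kirchpk import (
    PolyexponentialCurve,
    StudyRecord,
    fit_series,
    generate_series,
    kl25a_study,
    nca_iv,
)

truth = kl25a_study().curve_iv
series = generate_series(truth, noise_model="proportional", cv=0.05, seed=42)
fit = fit_series(series, n_terms=2)

print("generating curve:", [(round(c, 2), round(l, 3)) for c, l in truth.terms])
print("fitted curve:    ",
      [(round(c, 2), round(l, 3)) for c, l in fit.curve.terms],
      f"(converged={fit.converged}, log-scale rms {fit.residual_rms:.3f})")

rec = StudyRecord(
    dose_iv=2500.0,
    curve_iv=PolyexponentialCurve(fit.curve.terms, role="iv_disposition"),
)
print(f"CL from fit:  {nca_iv(rec).CL:.1f} L/h (truth 24.2 L/h)")

# The terminal exponent — carried by ten late samples — comes back
# within a few percent; the fast exponent rests on four early samples
# and scatters more.  AUC-level quantities such as CL are robust.
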