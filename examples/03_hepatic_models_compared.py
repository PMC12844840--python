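"""Hepatic clearance: series calculus vs the Extended Clearance Concept.

Both frameworks combine blood flow, basolateral transport and intrinsic
elimination, but the series calculus carries transport as a single net
(influx - efflux) rate-defining stage, while the ECC keeps the two
directions as separate parameters.  On some parameter sets they nearly
agree; on others only one framework yields a value at all.
"""

from kirchpk import (
    HepaticParameters,
    classify_rate_limiting_step,
    compare_ecc_vs_kirchhoff,
    hepatic_clearance,
    well_stirred_form,
)

# transport-free reduction: the familiar Q*fu*CLint/(Q + fu*CLint) form
p0 = HepaticParameters(Q_H=90.0, f_uB=0.1, CL_int=500.0)
print(f"no transport:   CL_H = {hepatic_clearance(p0):.2f} L/h "
      f"(= flow/intrinsic form {well_stirred_form(90, 0.1, 500):.2f})")

# transport in scope: three stages in series
p1 = HepaticParameters(
    Q_H=90.0, f_uB=0.1, CL_int=500.0,
    CL_int_influx=60.0, CL_int_efflux=10.0, transport_in_scope=True,
)
cls = classify_rate_limiting_step(p1)
print(f"with transport: CL_H = {hepatic_clearance(p1):.2f} L/h, "
      f"rate limit: {cls.label} (share {cls.dominance_ratio:.2f})")

# influx == efflux: a passive process; the net stage vanishes and only
# the ECC still returns a number
p2 = HepaticParameters(
    Q_H=90.0, f_uB=0.1, CL_int=500.0, CL_int_influx=20.0, CL_int_efflux=20.0
)
r = compare_ecc_vs_kirchhoff(p2)
print(f"influx=efflux:  ECC {r['CL_ecc']:.2f} L/h; "
      f"series calculus: {r['kirchhoff_note']}")
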