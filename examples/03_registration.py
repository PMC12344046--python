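"""Deformable registration: recover a known smooth misalignment.

A phantom is warped by a 3-px sinusoidal field (standing in for anatomy that
moved between planning CT and treatment-day CBCT); B-spline registration
brings it back and is scored against the known inverse field.
"""

from ossr.experiments import registration_recovery

st = registration_recovery(seed=0, size=128, amplitude=3.0, period=64.0)

print(f"mean endpoint error:        {st.mean_epe:.3f} px (whole image)")
print(f"mean endpoint error (body): {st.mean_epe_body:.3f} px")
print(f"NMI  fixed vs moving/warped: {st.nmi_before:.3f} -> {st.nmi_after:.3f}")
print(f"RMSE fixed vs moving/warped: {st.rmse_before:.2f} -> {st.rmse_after:.2f}")
print("\nSub-pixel mean recovery of the deformation; NMI rises because the "
      "warped planning CT lines back up with the fixed image.")
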