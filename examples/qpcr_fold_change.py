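"""Relative qPCR quantification with the ddCt method.

Converts raw cycle thresholds (Ct) of a differentiation marker, measured
against the 18S rRNA housekeeping reference, into fold induction:
dCt = Ct_target - Ct_reference per condition, and
fold = 2^-(dCt_treated - dCt_control).
"""

from myoquant import QpcrSample, delta_delta_ct

# myogenin-like induction: the marker's Ct drops ~2 cycles upon treatment
control = QpcrSample(ct_target=24.1, ct_reference=10.2, condition="control")
treated = QpcrSample(ct_target=22.0, ct_reference=10.3, condition="knockdown")

fold = delta_delta_ct(treated, control)
print(f"control : dCt = {control.ct_target - control.ct_reference:.2f}")
print(f"treated : dCt = {treated.ct_target - treated.ct_reference:.2f}")
print(f"fold induction = {fold:.2f}")
print("\nEach PCR cycle doubles the product, so a one-cycle drop in dCt")
print("corresponds to a two-fold higher starting transcript abundance.")
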