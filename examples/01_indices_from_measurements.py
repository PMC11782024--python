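"""Compute the AVS index panel and reference label for one patient.

Builds a bilaterally successful sampling from duplicate aldosterone
(pmol/L) and cortisol (nmol/L) readings, then prints the derived indices:
A/C per site, selectivity (SI), lateralization (LI), contralateral
suppression (CSI) and the LAV/IVC index, plus the reference subtype the
LI >= 4 / CSI < 1 rule assigns.
"""

from avskit import (
    PatientAVSRecord,
    SiteMeasurement,
    compute_indices,
    is_adequate,
    reference_subtype_label,
)

patient = PatientAVSRecord(
    patient_id="example-001",
    # left adrenal vein: strongly elevated A/C -> left-dominant secretion
    lav=SiteMeasurement(aldosterone=(52000.0, 49000.0), cortisol=(4800.0, 4600.0)),
    # right adrenal vein: A/C below the periphery -> contralateral suppression
    rav=SiteMeasurement(aldosterone=(5200.0, 5400.0), cortisol=(6100.0, 5900.0)),
    # inferior vena cava (peripheral reference)
    ivc=SiteMeasurement(aldosterone=(2200.0, 2100.0), cortisol=(1000.0, 980.0)),
)

panel = compute_indices(patient)
print(f"adequacy      : {is_adequate(patient).value}")
print(f"A/C  LAV/RAV/IVC: {panel.ac_lav:.2f} / {panel.ac_rav:.2f} / {panel.ac_ivc:.2f}")
print(f"SI   LAV/RAV  : {panel.si_lav:.1f} / {panel.si_rav:.1f}   (>= 3 means adequate)")
print(f"LI            : {panel.li:.1f}  (dominant side: {panel.dominant_side})")
print(f"CSI           : {panel.csi:.2f}  (< 1 means contralateral suppression)")
print(f"LAV/IVC index : {panel.lav_ivc:.2f}")
print(f"reference subtype: {reference_subtype_label(panel).value}")
# An LI of ~12 with CSI < 1 marks unilateral left-sided disease: the left
# gland oversecretes while the right is suppressed below the periphery.
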