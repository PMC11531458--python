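"""Expected lung weight and thermodilution-derived edema for one patient.

Expected (healthy) lung weight comes from the Cressoni height model; the
thermodilution side converts an EVLWI reading into an edema volume by
subtracting the physiological 7 ml/kg of ideal body weight.
"""

from edemaquant import PatientRecord, expected_lung_weight, ideal_body_weight
from edemaquant.anthropometry import edema_from_tptd

height_m = 1.73
print(f"expected lung weight at {height_m} m: {expected_lung_weight(height_m):.1f} g")
print(f"Devine IBW (male, 1.80 m): {ideal_body_weight(1.80, 'male'):.1f} kg")

rec = PatientRecord("P001", height=1.73, weight=90.0, sex="male", evlwi=14.0)
t = edema_from_tptd(rec)
print(f"IBW {t.ibw:.1f} kg, physiological lung water {t.physiological_lung_water:.0f} ml")
print(f"PE_TPTD at EVLWI {rec.evlwi} ml/kg: {t.pe_tptd:.0f} ml")
# Everything above 7 ml/kg of IBW counts as edema: (14 - 7) x IBW here.
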