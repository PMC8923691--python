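"""eGFR from serum creatinine, and the annual eGFR slope from a visit series.

Builds a short longitudinal record for one synthetic patient, fits the
trajectory line, and prints the renal-function targets used as regression
labels throughout the package.
"""

from datetime import date, timedelta

from renaltlco import SubjectRecord, compute_egfr, fit_trajectory
from renaltlco.clinical import invert_egfr

print("eGFR for Cr = 1.0 mg/dL, age 60:")
print(f"  male:   {compute_egfr(1.0, 60, 'male'):6.2f} mL/min/1.73 m^2")
print(f"  female: {compute_egfr(1.0, 60, 'female'):6.2f} mL/min/1.73 m^2  (x 0.739)")

# a patient declining by 4 mL/min/1.73 m^2 per year, visits every ~4 months
t0 = date(2020, 1, 15)
obs = []
for months in (0, 4, 8, 12, 16, 20):
    t_years = months / 12
    egfr_t = 58.0 - 4.0 * t_years
    d = t0 + timedelta(days=round(t_years * 365.25))
    obs.append((d, invert_egfr(egfr_t, 64.0, "male")))

record = SubjectRecord("patient-1", "male", 64.0, t0 + timedelta(days=365), obs)
target = fit_trajectory(record)
print(f"\nfitted from {len(obs)} creatinine observations:")
print(f"  eGFR at imaging date: {target.egfr_at_imaging:6.2f} mL/min/1.73 m^2")
print(f"  annual eGFR slope:    {target.egfr_slope:6.2f} mL/min/1.73 m^2 / year")
print(f"  trajectory-line R^2:  {target.fit_r2:.4f}")
print("\nA negative slope is decline; this patient loses ~4 units of eGFR per year.")
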