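"""Score one patient and read off their life expectancy.

A 77-year-old man with heart failure and difficulty walking several blocks
scores 4 (age 75-79) + 2 (male) + 2 (heart failure) + 2 (walking) = 10 Lee
points.  The reconstructed Gompertz model then converts the 10-point group
into survival quantiles: a median life expectancy near 7.3 years, with a
quarter of such patients dying before ~3.8 years and a quarter surviving
past ~11.2 years.
"""

import gompertzle as gle

patient = gle.RiskFactorProfile(
    age_years=77,
    male=True,
    heart_failure=True,
    difficulty_walking_blocks=True,
)
score = gle.score_profile(patient)
print(f"Lee points: {score.points}  (risk group {score.group_label})")

model = gle.reference_model()
est = gle.predict_le(model, score.group)
print(f"time to 25% mortality: {est.t25:5.1f} years")
print(f"median life expectancy: {est.t50:5.1f} years")
print(f"time to 75% mortality: {est.t75:5.1f} years")
if est.extrapolated:
    print("note: extends beyond the 10-year validated follow-up (extrapolated)")
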