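"""Fit a CCK-8 viability plate and classify the batch's toxicity tier.

Simulates a plate (4 replicate wells per dose, 5% viability noise) from a
known Hill curve, converts absorbances to viability via
(dosing - blank)/(control - blank), fits the 4PL curve and reports the IC50
with its three-tier toxicity class (>450 ug/mL low, 390-450 medium, <390 high).
"""

from pmtox import HillParams, classify_toxicity_tier, fit_hill, generate_viability_plate

truth = HillParams(floor=0.0, ceiling=1.0, ic50=417.0, slope=2.0)
doses = [1, 10, 50, 100, 200, 300, 400, 500, 700, 1000]  # ug/mL

plate = generate_viability_plate(truth, doses, noise_sd=0.05, seed=3)
print(f"plate: {plate.dose.size} wells over {len(doses)} doses")

fit = fit_hill(plate)
tier = classify_toxicity_tier(fit.params.ic50)
print(f"fitted IC50 = {fit.params.ic50:.1f} ug/mL (true 417.0), slope = {fit.params.slope:.2f}")
print(f"residual SSE = {fit.residual_sse:.4f}, converged = {fit.converged}")
print(f"toxicity tier: {tier} "
      "(IC50 between 390 and 450 ug/mL marks intermediate hepatotoxicity)")
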