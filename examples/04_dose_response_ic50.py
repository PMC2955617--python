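"""4PL dose-response fits with censored absolute IC50.

Simulates two WST-1-style plates on the packaged monotherapy dose grids:
drug A plateaus at ~60% viability (a mild responder), drug B crosses 50%.
The absolute IC50 — where the fitted curve crosses viability 0.5 — is
reported for drug B but censored as NOT_REACHED for drug A: a curve that
never drops below 60% viability has no IC50, no matter the dose.
"""

import kinoscope as ks

truth_a = ks.ViabilityTruth(lower=0.60, upper=1.0, ec50=300.0, hill=1.2,
                            noise_sd=0.02, seed=4)
truth_b = ks.ViabilityTruth(lower=0.15, upper=1.0, ec50=80.0, hill=1.5,
                            noise_sd=0.02, seed=5)

for name, truth, grid, unit in (
    ("drug_a", truth_a, ks.DASATINIB_DOSES_NM, "nM"),
    ("drug_b", truth_b, ks.TBB_DOSES_UM, "uM"),
):
    plate = ks.simulate_viability(grid, truth, n_replicates=4, drug=name, unit=unit)
    dr = ks.normalize_plate(plate)
    fit = ks.fit_4pl(dr)
    ic50 = "NOT_REACHED" if fit.ic50 is ks.NOT_REACHED else f"{fit.ic50:.1f} {unit}"
    print(f"{name}: floor={fit.lower:.2f}  ec50={fit.ec50:.1f} {unit}  "
          f"hill={fit.hill:.2f}  absolute IC50={ic50}  (true ec50 {truth.ec50})")

print("\nA censored IC50 is data, not failure: it reproduces the situation of a "
      "drug whose maximum effect is a 40% viability decrease.")
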