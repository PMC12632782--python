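"""Area-summation curves and DoG receptive-field fits.

Generates a noiseless and a noisy spot-size response curve from known
difference-of-Gaussians parameters, refits them, and reports parameter
recovery — the procedure used to size a cell's RF centre before
constructing linear-equivalent discs.
"""
import numpy as np
import pandas as pd

from rgcsubunits import DoGAreaParams, area_summation_response, fit_area_summation
from rgcsubunits.io import write_params, write_table

truth = DoGAreaParams(kc=60.0, ks=25.0, sigma_c=55.0, sigma_s=180.0, r0=4.0)
radii = np.array([10, 20, 35, 50, 75, 100, 150, 200, 300, 400, 500, 600], float)
clean = area_summation_response(radii, truth)

rng = np.random.default_rng(0)
noisy = clean + rng.normal(0.0, 0.05 * np.ptp(clean), radii.size)

fit_clean = fit_area_summation(radii, clean)
fit_noisy = fit_area_summation(radii, noisy)

write_table(pd.DataFrame({"radius_um": radii, "response": clean, "response_noisy": noisy}),
            "results/01_area_summation_curve.tsv")
write_params({
    "truth": truth, "fit_noiseless": fit_clean, "fit_5pct_noise": fit_noisy,
    "sigma_c_recovery_error": abs(fit_noisy.sigma_c - truth.sigma_c) / truth.sigma_c,
}, "results/01_dog_fits.json")

print(f"noiseless fit recovers sigma_c={fit_clean.sigma_c:.2f} um (truth {truth.sigma_c})")
print(f"5% noise fit: sigma_c={fit_noisy.sigma_c:.2f} um "
      f"({100*abs(fit_noisy.sigma_c-truth.sigma_c)/truth.sigma_c:.1f}% error)")
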