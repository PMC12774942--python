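"""Compute both multivariate detection-limit frameworks, with and without OSC.

The variance-leverage mLOD reflects global calibration geometry; the
NAS-LOD reflects how much analyte-specific signal is isolated on LV1.
Orthogonal signal correction strips matrix variance that co-varies with
the analyte, which concentrates the analyte in LV1 and lowers NAS-LOD.
"""

import pandas as pd

from nirlod import (
    PreprocessOptions, SyntheticConfig, average_replicates, get_profile,
    lod_report, loocv, pls_fit, preprocess_chain, simulate_dataset,
)

spectra, table = simulate_dataset(SyntheticConfig(seed=11), get_profile("n500"))
averaged = average_replicates(spectra)
y = table.y("vitexin")

rows = []
for use_osc in (False, True):
    opts = PreprocessOptions(osc=use_osc)
    cv = loocv(averaged.absorbance, y, A_max=8, options=opts)
    X, _ = preprocess_chain(averaged.absorbance, y, opts)
    model = pls_fit(X, y, cv.chosen_A)
    report = lod_report(model, X, y, cv, osc_used=use_osc)
    rows.append({"OSC": "yes" if use_osc else "no", **report.to_row()})

print(pd.DataFrame(rows).round(2).to_string(index=False))
print("\nmLOQ/mLOD = 10/3.3 and NAS-LOQ/NAS-LOD = 10/3 on every row;")
print("mLODavg is the midpoint of the min (blank-surrogate leverage) and")
print("max (worst-case leverage) variants. All values in mg/g.")
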