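"""Observed-vs-predicted residual foci across all five dose-rate regimens.

Data are generated FROM the model here, so the observed/predicted ratios
should scatter around 1 — this is the null calibration of the comparison
machinery.  With real assay data the same table is where an inverse
dose-rate effect shows up as late-timepoint ratios well above 1 at the
lowest rates.
"""

import pandas as pd

from imkdose import compare_foci, gen_foci, load_reference_params, reference_scenarios

hlec = load_reference_params()["HLEC"]
scenarios = reference_scenarios(total_dose=1.0)

observed = pd.concat(
    [
        gen_foci(hlec, sched, 1.0, tps, n_cells=100, lambda0=0.5, seed=500 + i)
        for i, (sched, tps) in enumerate(scenarios)
    ],
    ignore_index=True,
)

table = compare_foci(observed, hlec, scenarios, lambda0=0.5)
late = table[(table.timepoint_h == 48.0)]
print("48 h after start of irradiation (residual foci):")
print(
    late[
        ["avg_dose_rate_Gy_per_min", "observed_mean", "predicted_foci", "ratio", "ratio_se"]
    ].to_string(index=False, float_format=lambda x: f"{x:.4f}")
)

within = (abs(table["ratio"] - 1.0) <= 3 * table["ratio_se"]).sum()
print(
    f"\n{within}/{len(table)} regimen x timepoint cells have observed/predicted "
    "within 3 SE of 1.0:\nthe pipeline itself introduces no spurious dose-rate "
    "effect; ratios far above 1 in\nreal data are therefore a biological signal, "
    "not an analysis artifact."
)
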