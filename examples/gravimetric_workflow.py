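"""Gravimetric reference workflow on simulated weighing campaigns.

Simulates three specimens per material wearing at material-specific rates,
weighed in triplicate every 0.4 million cycles alongside an unloaded soak
control, then runs the standard reduction: soak-corrected cumulative
losses, steady-state wear-rate regression, and the exact Kruskal-Wallis
comparison of total losses between materials.
"""

import cupwear as cw

RATES = {"STD_PE": 11.0, "XLPE": 5.0, "XLPE_VE": 13.0}  # mg per million cycles

totals = {m: [] for m in RATES}
for i, (material, rate) in enumerate(RATES.items()):
    for k in range(3):
        series = cw.simulate_weight_series(
            rate,
            soak_params=cw.SoakParams(amplitude_mg=1.0, tau_Mc=0.3),
            balance_sd=0.01,
            seed=100 * i + k,
            specimen_id=f"{material}_{k+1}",
            material_label=material,
        )
        result = cw.analyze_series(series)
        totals[material].append(result.total_loss)
        print(f"{result.specimen_id:10s} rate {result.wear_rate:5.2f} mg/Mc "
              f"(R^2 {result.rate_fit_r2:.4f}), total loss {result.total_loss:6.2f} mg")

kw = cw.kruskal_wallis(list(totals.values()))
print(f"\nKruskal-Wallis across materials: H = {kw.H:.2f}, "
      f"p = {kw.p_value:.4f} ({kw.method})")
print()
print("The recovered rates match the simulated ones because the control's")
print("fluid-uptake gain cancels the specimens' soak term stop by stop; the")
print("exact permutation p-value is reliable even at n = 3 per group.")
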