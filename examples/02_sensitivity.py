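"""Sensitivity analysis: tornado diagram, probabilistic draws and the
cost-effectiveness acceptability curve."""

from tascea import ceac, ce_plane_export, dsa_tornado, paper_scenario, psa_run, tornado_frame

scenario = paper_scenario()

# One-way deterministic sensitivity: each parameter to its min and max with
# the rest at base, ranked by the induced ICER range.
entries = dsa_tornado(scenario)
print("five widest tornado bars:")
print(tornado_frame(entries).head(5).to_string(index=False))

# Probabilistic sensitivity: resample every parameter 1000 times from its
# fitted beta/gamma distribution and rerun the model per draw.  The scenario
# carries a default seed, so this is reproducible.
psa = psa_run(scenario, n_draws=1000)
_, quadrants = ce_plane_export(psa)
print(f"\ncost-effectiveness plane quadrants (of {psa.n_draws} draws): {quadrants}")

# Acceptability curve: probability the combination maximizes net monetary
# benefit as a function of willingness-to-pay.
curve = ceac(psa)
for wtp in (10_000, 20_000, 50_000, scenario.wtp_threshold):
    print(f"P(combination cost-effective at ${wtp:>9,.0f}/QALY) = {curve.at(wtp):.3f}")
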