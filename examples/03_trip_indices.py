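"""Foraging effort, success and efficiency indices per trip.

Processes a 10-day simulated deployment end to end and prints the
per-trip table: benthic dive rate b (vertical metres per hour of benthic
diving — effort), FTSI (summed prey-capture probabilities per hour of
benthic diving — success), FTEI (success per unit effort), the proportion
of benthic dives (PBD) and of time at sea spent diving.
"""

import pandas as pd

from tdrforage import PipelineConfig, SimConfig, process_deployment, simulate_deployment

series, _ = simulate_deployment(SimConfig(seed=9, deployment_days=10.0))
result = process_deployment(series, PipelineConfig())

trips = result["trips"]
ft = trips[trips["status"] == "foraging_trip"]
cols = ["trip_id", "duration_h", "N", "PBD", "prop_time_diving", "b", "FTSI", "FTEI"]
with pd.option_context("display.float_format", "{:.3f}".format, "display.width", 120):
    print(ft[cols].to_string(index=False))
print(f"\nmean benthic dive rate: {ft['b'].mean():.0f} m/h")
print(f"mean FTSI: {ft['FTSI'].mean():.2f} captures per benthic-dive-hour")
print(f"mean FTEI: {ft['FTEI'].mean():.4f} captures per (m/h) of effort")
# A trip over deep seafloor has longer dives and a higher b; FTEI falls
# when the same expected captures require more vertical travel.
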