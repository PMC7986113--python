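"""Thermal-regime metrics from synthetic logger series.

Bare soil heats and cools faster than moss-insulated soil: twice the daily
amplitude and many more freeze-thaw cycles in the shoulder seasons.
"""

from soilncycle.climate import (aggregate_period_mean, count_freeze_thaw,
                                daily_amplitude)
from soilncycle.synth import generate_temperature_series

regimes = {
    "moss": {"summer_mean": 8.7, "winter_mean": 0.3, "amplitude": 1.5,
             "ar_coeff": 0.8, "noise_sd": 0.2, "freeze_events": 5},
    "bare": {"summer_mean": 9.1, "winter_mean": 0.3, "amplitude": 3.0,
             "ar_coeff": 0.8, "noise_sd": 0.2, "freeze_events": 22},
}

for cover, regime in regimes.items():
    s = generate_temperature_series(regime, cover, "2016-09-01", 365, seed=4)
    summer = aggregate_period_mean(s, "2017-06-01", "2017-08-31 23:59")
    amp = daily_amplitude(s).loc["2017-06-01":"2017-08-31"].mean()
    raw = count_freeze_thaw(s, 0.0).cycles
    thr = count_freeze_thaw(s, 0.1).cycles
    print(f"{cover:6s} summer mean {summer:.2f} C | summer daily amplitude "
          f"{amp:.2f} C | freeze-thaw cycles raw={raw} banded(0.1C)={thr}")

print("\nthe insulating moss layer halves the amplitude and suppresses")
print("most freeze-thaw cycling relative to bare soil")
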