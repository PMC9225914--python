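"""Sample the moxa-stick burning-end temperature schedule.

Writes the source temperature over one cleaning cycle and over the full
15-minute treatment: the slow ash-accumulation envelope with per-minute
cleaning dips to 50 degC.
"""

from pathlib import Path

import pandas as pd

from moxitherm.source import BurnSchedule, temperature_series

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

schedule = BurnSchedule(max_temperature=600.0)

for label, duration in (("one_minute", 70.0), ("treatment", 900.0)):
    times, temps = temperature_series(schedule, duration, 1.0)
    pd.DataFrame({"t_s": times, "temp_C": temps}).to_csv(
        OUT / f"burning_curve_{label}.csv", index=False)

times, temps = temperature_series(schedule, 900.0, 1.0)
clean = temps == schedule.clean_temperature
print(f"peak {temps.max():.0f} degC, end-of-treatment {temps[-1]:.1f} degC "
      f"(envelope decay {temps[0] - temps[~clean].min():.1f} degC over 15 min)")
print(f"{int(clean.sum())} cleaning samples across "
      f"{len(times)} one-second samples; windows open after each whole minute")
print(f"wrote results/burning_curve_one_minute.csv and _treatment.csv")
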