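"""Univariate sweeps of the four moxibustion parameters.

One factor varies per sweep — peak burning temperature (600/650/700 degC),
stick diameter (12/15/18 mm), stick-to-skin distance (25/30/35 mm),
ambient temperature (17/25/32 degC) — with everything else at the
standard condition.  Writes per-level point series and final profiles and
prints the effect direction on the 5 mm-depth reference temperature.
"""

from pathlib import Path

import pandas as pd

from moxitherm.study import SWEEP_FACTORS, run_sweep

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

summary = []
for factor in SWEEP_FACTORS:
    sweep = run_sweep(factor)
    for level, res in zip(sweep.levels, sweep.results):
        summary.append({"factor": factor, "level": level,
                        "reference_C": res.reference_point_temperature,
                        "surface_point_C": float(res.point_series[-1])})
        pd.DataFrame({"t_s": res.times, "point_C": res.point_series}).to_csv(
            OUT / f"sweep_{factor}_{level:g}.csv", index=False)
    temps = sweep.reference_temperatures
    direction = ("increases" if temps[-1] > temps[0] else "decreases")
    print(f"{factor:16}: reference temperature {direction} with the factor "
          f"({' -> '.join(f'{t:.2f}' for t in temps)} degC)")

pd.DataFrame(summary).to_csv(OUT / "sweep_summary.csv", index=False)
print("wrote results/sweep_summary.csv and per-level series")
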