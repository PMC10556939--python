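"""Interposed-graft length and diameter sweeps.

Reproduces the two design questions for graft interposition: how long and
how wide may the interposed side graft be?  Shorter grafts (and the
15-mm hemisphere stump) stagnate less; narrower grafts stagnate less during
early systole.  Each sweep solves one systole per variant.
"""

import warnings
from pathlib import Path

import graftflow as gf

warnings.filterwarnings("ignore", message="segmental artery")
out = Path(__file__).resolve().parent.parent / "scratch"
out.mkdir(exist_ok=True)

print("== length sweep (10/20/30 mm + hemisphere) ==")
lt = gf.run_length_sweep()
print(lt.df[["design", "lvv_mean_mL", "segmental_outflow_mL"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("ranking:", " < ".join(lt.ranking))

print("\n== diameter sweep (6/8/10/12 mm), early-systole window ==")
wf = gf.PulseWaveform()
dt = gf.run_diameter_sweep(window=(0.0, wf.systole_duration / 2))
print(dt.df[["design", "lvv_mean_mL", "segmental_outflow_mL"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("early-systole ranking:", " < ".join(dt.ranking))

lt.df.to_csv(out / "length_sweep.csv", index=False)
dt.df.to_csv(out / "diameter_sweep.csv", index=False)
print(f"\nwrote CSVs to {out}")
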