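#!/usr/bin/env python
"""Concentration-dependent NIR emission red shift from reabsorption.

Runs the three-layer (skin / BBS-lymph / ideal reflector) Monte Carlo for
a ladder of BBS concentrations and tracks the escaping-fluorescence peak:
zero concentration reproduces the intrinsic 697 nm emission, while
concentrations in the range measured in vivo push the detected peak past
710 nm. Uses 2e4 photons per wavelength on a 5-nm grid for speed (the
acceptance script runs 1e5). Writes results/mc_redshift.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bbsoptics import synth
from bbsoptics import tissue_mc as mc

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

bbs = synth.make_bbs("TpBBS")
emission = bbs.emission.as_spectrum(np.arange(600.0, 901.0))
config = mc.FluorSimConfig(
    wavelengths=np.arange(650.0, 821.0, 5.0),
    photons_per_wavelength=20_000,
    seed=17,
)

rows = []
print("== Escaping-fluorescence peak vs BBS concentration ==")
for c_uM in (0.0, 50.0, 100.0, 200.0, 500.0):
    esc = mc.simulate_bbs_emission(bbs.absorption, emission, c_uM * 1e-6, config)
    shift = mc.red_shift(esc)
    print(
        f"  {c_uM:5.0f} uM: peak {shift.peak_out:6.1f} nm"
        f"  (shift {shift.shift:+5.1f} nm from the {shift.peak_in:.0f} nm source)"
    )
    rows.append(
        {
            "concentration_uM": c_uM,
            "peak_nm": shift.peak_out,
            "shift_nm": shift.shift,
        }
    )

pd.DataFrame(rows).to_csv(OUT / "mc_redshift.csv", index=False)
print(
    "\nHigher BBS concentrations re-absorb the blue flank of the emission\n"
    "during waveguided propagation (mirror below, TIR above), moving the\n"
    "detected peak from 697 nm to beyond 710 nm."
)
print(f"wrote {OUT / 'mc_redshift.csv'}")
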