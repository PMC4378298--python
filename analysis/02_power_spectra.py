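#!/usr/bin/env python
"""Group-mean parametric power spectra and their dominant-band peaks.

Fits the full five-region VAR per preprocessed subject, averages the
spectral-matrix diagonals per group, and tabulates the peak frequency of
every region in the 0.04-0.1 Hz analysis band. The expectation from the
generator design is a peak inside 0.06-0.08 Hz for every region and group.
Writes results/power_peaks.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import lfo_gcnet as g

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
N_SUBJECTS = {"AB": 13, "SS": 13, "MP": 6, "MPPT": 7}


def main() -> None:
    base = g.default_network()
    freqs = g.default_freq_grid(base.tr_s)
    rows = []
    for label, n in N_SUBJECTS.items():
        # equal session lengths across groups, as in the study pipeline
        subs = g.make_group_scenario(
            g.GroupScenario(label, n, n_samples=237, seed=SEED), base
        )
        powers = []
        for ts in subs:
            filt = g.detrend_bandpass(ts)
            order = g.select_order(filt, p_max=6).order_p
            powers.append(g.spectral_matrix(g.fit_var(filt, order), freqs, base.tr_s).power)
        mean_power = np.mean(powers, axis=0)
        for i, region in enumerate(base.region_names):
            peak = g.peak_frequency(freqs, mean_power[:, i], band=(0.04, 0.1))
            rows.append({"group": label, "region": region, "peak_hz": round(peak, 4)})
    table = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "power_peaks.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    table["in_band"] = table["peak_hz"].between(0.06, 0.08)
    print("\nregions peaking inside 0.06-0.08 Hz, by group:")
    print(table.groupby("group")["in_band"].sum().to_string())
    print("(peak location is exact in the innovation spectrum; the parametric"
          "\n estimate wobbles for weakly coupled cohorts at these lengths)")


if __name__ == "__main__":
    main()
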