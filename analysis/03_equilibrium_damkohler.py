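"""Equilibrium points and Damkohler numbers per bead.

For every simulated bead the medium and in-bead viable series are
intersected (linear interpolation between bracketing samples) and the
Damkohler number Da = growth rate / release rate is computed from the
in-bead growth curve (slope of ln density) and the first-order release
constant (negated slope of ln(1 - Mt/Minf)).  Beads whose series never
intersect retain their cells through the intestinal phase; Da > 1 marks
growth-governed (cell-trapping) systems.

Reads results/data/, writes results/equilibrium_damkohler.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from probead import kinetics as kin

HERE = Path(__file__).resolve().parent.parent
DATA = HERE / "results" / "data"
OUT = HERE / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.parse_args()
    with open(DATA / "ground_truth.json") as fh:
        truth = json.load(fh)
    rows = []
    for path in sorted(DATA.glob("release_*.csv")):
        bead = path.stem.replace("release_", "")
        curve = kin.ReleaseCurve.read_csv(path)
        growth = kin.GrowthCurve.read_csv(DATA / f"inbead_growth_{bead}.csv")
        eq = kin.find_equilibrium_time(curve.cfu_medium, curve.cfu_inbead, curve.time_min)
        f = curve.fraction_released
        t_hi = float(curve.time_min[f < 0.999][-1])
        try:
            g_rate, r_rate = kin.estimate_rates(growth, curve, (0.0, t_hi))
            da = kin.damkohler(g_rate, r_rate)
            da_val, regime = da.da, da.regime
        except ValueError as err:
            g_rate = r_rate = da_val = float("nan")
            regime = f"undefined ({err})"
        rows.append({
            "bead": bead,
            "equilibrium_min": eq,
            "true_crossing_min": truth[bead]["noiseless_crossing_min"],
            "growth_rate_per_min": g_rate,
            "release_rate_per_min": r_rate,
            "da": da_val,
            "regime": regime,
        })
        eq_s = "none" if eq is None else f"{eq:.1f} min"
        print(f"{bead}: equilibrium {eq_s} "
              f"(truth {truth[bead]['noiseless_crossing_min']}), Da = {da_val:.3g} ({regime})")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "equilibrium_damkohler.csv", index=False)
    print(f"wrote {OUT / 'equilibrium_damkohler.csv'}")


if __name__ == "__main__":
    main()
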