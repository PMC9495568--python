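"""Response-surface analysis and desirability optimization of the design.

Fits coded quadratic surfaces to the factorial morphometry table (area,
perimeter, circularity, solidity over agavin % x whey %), runs one-way
ANOVA with Tukey grouping per response, and maximizes the composite
desirability (area/circularity/solidity maximized, perimeter minimized,
equal importance) over the experimental square.

Reads results/data/factorial_morphometry.csv; writes
results/surface_coefficients.json, results/anova_tukey.csv and
results/optimization.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from probead import doe

HERE = Path(__file__).resolve().parent.parent
DATA = HERE / "results" / "data"
OUT = HERE / "results"

DIRECTIONS = {
    "area": "maximize",
    "circularity": "maximize",
    "solidity": "maximize",
    "perimeter": "minimize",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.parse_args()
    df = pd.read_csv(DATA / "factorial_morphometry.csv")
    models = {r: doe.fit_quadratic_surface(df, r) for r in DIRECTIONS}
    for r, m in models.items():
        print(f"{r}: R^2 {m.r2:.3f}, coefficients "
              + ", ".join(f"{k}={v:.4g}" for k, v in m.coefficients.items()))

    anova_rows = []
    for r in DIRECTIONS:
        sub = df[df["response"] == r]
        groups = {t: g["value"].to_numpy() for t, g in sub.groupby("treatment")}
        res = doe.anova_tukey(groups, alpha=0.05)
        print(f"{r}: ANOVA F = {res.f_statistic:.2f}, p = {res.p_value:.2e}")
        for t in sorted(res.means, key=lambda k: -res.means[k]):
            anova_rows.append({"response": r, "treatment": t,
                               "mean": res.means[t], "letters": res.letters[t],
                               "f_statistic": res.f_statistic, "p_value": res.p_value})

    goals = doe.default_goals(models, DIRECTIONS)
    result = doe.optimize_composite(models, goals)
    print(f"optimum: {result.agavin_pct:.2f}% agavins, {result.whey_pct:.2f}% whey protein, "
          f"composite desirability {result.composite:.3f}")

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "surface_coefficients.json", "w") as fh:
        json.dump({r: {"coefficients": m.coefficients, "r2": m.r2,
                       "residual_variance": m.residual_variance}
                   for r, m in models.items()}, fh, indent=2)
    pd.DataFrame(anova_rows).to_csv(OUT / "anova_tukey.csv", index=False)
    with open(OUT / "optimization.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    print(f"wrote surface_coefficients.json, anova_tukey.csv, optimization.json under {OUT}")


if __name__ == "__main__":
    main()
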