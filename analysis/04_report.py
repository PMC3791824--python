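#!/usr/bin/env python
"""Distribution classes and stratified component means: does one scheme
dichotomize the population?

For every component and the subscore, tabulates the proportion of children at
the minimum (0), strictly between, and at the maximum (5, or 25 for the
subscore), by index and stratum, plus mean component scores per stratum.

Reads:  results/scores.csv
Writes: results/distribution_classes.csv, results/component_means.csv
"""

from pathlib import Path

import pandas as pd

from childdqi import comparison

OUT = Path("results")


def main() -> None:
    scores = pd.read_csv(OUT / "scores.csv")
    rep = comparison.stratified_report(scores)
    dist = rep["distribution_classes"]
    dist.to_csv(OUT / "distribution_classes.csv", index=False)

    rows = []
    for label, group in comparison._iter_strata(scores, comparison.STRATA_COLUMNS):
        for index, prefix in (("HEI2005", "hei_"), ("RCDQI", "rcdqi_")):
            for comp in comparison.COMPARABLE + ("subscore",):
                rows.append({"stratum": label, "index": index, "component": comp,
                             "mean_score": float(group[f"{prefix}{comp}"].mean()),
                             "n": len(group)})
    pd.DataFrame(rows).to_csv(OUT / "component_means.csv", index=False)

    total = dist[dist.stratum == "total"]
    print("proportion of children at min / between / max (total sample):")
    for comp in comparison.COMPARABLE + ("subscore",):
        line = f"  {comp:<13}"
        for index in ("HEI2005", "RCDQI"):
            r = total[(total["index"] == index) & (total.component == comp)].iloc[0]
            line += f"  {index}: {r.prop_min:.1%}/{r.prop_between:.1%}/{r.prop_max:.1%}"
        print(line)
    piv = total.pivot(index="component", columns="index", values="prop_between")
    wins = (piv.loc[list(comparison.COMPARABLE), "RCDQI"]
            > piv.loc[list(comparison.COMPARABLE), "HEI2005"]).sum()
    print(f"\nRC-DQI places more children between the extremes for "
          f"{wins}/5 comparable components")


if __name__ == "__main__":
    main()
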