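#!/usr/bin/env python
"""Validate the localized and assimilated models against the measurements.

Reads results/summary.json (produced by 03_assimilate.py), prints the
four statistics (R2, CRM, RMSE, NRMSE) side by side for LAI and yield,
and writes the comparison table to results/validation.csv.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    with open(RESULTS / "summary.json") as fh:
        summary = json.load(fh)

    rows = []
    for variable in ("lai", "yield"):
        block = summary[variable]
        for variant in ("localized", "assimilated"):
            rep = block[variant]
            rows.append(
                {
                    "variable": variable,
                    "variant": variant,
                    "n": rep["n"],
                    "r2": round(rep["r2"], 4),
                    "crm": round(rep["crm"], 4),
                    "rmse": round(rep["rmse"], 4),
                    "nrmse_pct": round(rep["nrmse_pct"], 2),
                    "accuracy_class": rep["accuracy_class"],
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "validation.csv", index=False)
    print(table.to_string(index=False))
    for variable in ("lai", "yield"):
        cmp_ = summary[variable]["comparison"]
        print(
            f"{variable}: NRMSE change {cmp_['delta_nrmse']:+.2f} percentage points "
            f"({'improved' if cmp_['improved'] else 'not improved'})"
        )


if __name__ == "__main__":
    main()
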