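#!/usr/bin/env python
"""Assemble the final report tables from stored suite outputs.

Reads results/suite/summary.csv (produced by 03_deployment_suite.py) and
the per-case manifests, renders the pressure-drop / RF table alongside
the tabulated reference values for the same cases, and writes
results/resistance_table.csv.  The comparison column is qualitative: the
reduced-resolution RF values share the reference ordering but not its
absolute scale, which requires the multi-million-node mesh of a fully
resolved study.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
REFERENCE_RF = {"normal": 63.9, "reverse": 58.0, "small_open": 61.1,
                "moderate_open": 50.5, "large_open": 32.2}


def main():
    summary = ROOT / "suite" / "summary.csv"
    if not summary.exists():
        raise SystemExit("run analysis/03_deployment_suite.py first")
    t = pd.read_csv(summary)
    t["reference_rf_percent"] = t["case"].map(REFERENCE_RF)
    cols = ["case", "delta_p_mmHg", "rf_percent", "reference_rf_percent",
            "stagnation_length_over_D", "max_upstream_arm_wss_over_wss0",
            "peak_speed_over_Vm"]
    out = t[cols]
    out.to_csv(ROOT / "resistance_table.csv", index=False)
    print(out.round(3).to_string(index=False))

    ranks_sim = out.dropna().sort_values("rf_percent")["case"].tolist()
    ranks_ref = sorted(REFERENCE_RF, key=REFERENCE_RF.get)
    print(f"\nsimulated RF ranking : {ranks_sim}")
    print(f"reference RF ranking : {ranks_ref}")

    for mf in sorted((ROOT / "suite").glob("*/manifest.json")):
        m = json.loads(mf.read_text())
        print(f"{mf.parent.name:>14s}: config {m['config_hash']} "
              f"converged={m['converged']}")


if __name__ == "__main__":
    main()
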