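#!/usr/bin/env python
"""The study's statistical battery on the quantified tables.

RM-ANOVA (group x time) with Sidak/Bonferroni post hoc contrasts per
(protocol, phase, response), baseline-equality one-way ANOVA, Welch
t-tests + one-way ANOVA on infarct volumes, and slit-size regressions for
the lidocaine groups.  Reads results/wfr_metrics.csv and results/infarct.csv
(run 02 first); writes results/stats.json and prints the pattern of
significant baseline-to-24 h changes per group.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from isoipipe.orchestration import _jsonable, run_study_stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--correction", default="sidak", choices=["sidak", "bonferroni"])
    args = ap.parse_args()

    out = ROOT / "results"
    wfr = pd.read_csv(out / "wfr_metrics.csv")
    infarct = pd.read_csv(out / "infarct.csv")
    stats = run_study_stats(wfr, infarct, correction=args.correction)

    print("baseline -> 24 h contrasts (corrected p < 0.05):")
    for key, res in stats["wfr"].items():
        con = res["contrasts"].set_index("group")
        sig = [int(g) for g in con.index if con.loc[g, "significant"]]
        p_int = res["anova"].effects.set_index("effect").loc["group_x_time", "p"]
        print(f"  {key:45s} interaction p={p_int:8.2e}  significant groups: {sig}")
    for key, check in stats["baseline_check"].items():
        print(f"baseline equality {key}: p={check['p']:.3f}")
    for g, reg in stats["infarct"]["regressions"].items():
        print(
            f"group {g} slit regression: slope={reg.slope:.2f} mm^3/mm^2 "
            f"(SE {reg.slope_se:.2f}), R^2={reg.r_squared:.2f}, p={reg.p_slope:.2e}"
        )

    payload = {
        "wfr": {
            k: {"anova": v["anova"].effects, "contrasts": v["contrasts"]}
            for k, v in stats["wfr"].items()
        },
        "baseline_check": stats["baseline_check"],
        "infarct": stats["infarct"],
    }
    (out / "stats.json").write_text(json.dumps(_jsonable(payload), indent=1))
    print(f"\nfull report -> {out / 'stats.json'}")


if __name__ == "__main__":
    main()
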