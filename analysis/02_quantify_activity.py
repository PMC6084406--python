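"""Quantify enhancer activity: scaffold, plasmid RPP, and the threshold.

Runs the pipeline (cached between analysis scripts) on the simulated
dataset from 01_simulate.py and reports the region scaffold, the ranked-RPP
changepoint threshold theta, and the resulting activity calls. Summary to
results/02_activity_summary.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from chipstarr.pipeline import run_all

ROOT = Path(__file__).resolve().parents[1]
RUNDIR = ROOT / "scratch" / "pipeline"


def ensure_run() -> Path:
    run_all({"outdir": str(RUNDIR), "simulate": {"seed": 1}})
    return RUNDIR


def main() -> None:
    rundir = ensure_run()
    scaffold = pd.read_csv(rundir / "scaffold.tsv", sep="\t")
    activity = pd.read_csv(rundir / "activity.tsv", sep="\t")
    threshold = json.loads((rundir / "threshold.json").read_text())
    quant_log = json.loads((rundir / "quant_log.json").read_text())

    classes = activity["activity_class"].value_counts().to_dict()
    summary = pd.DataFrame(
        [
            {
                "n_scaffold_regions": len(scaffold),
                "max_region_bp": int((scaffold["end"] - scaffold["start"]).max()),
                "n_measured": int((activity["n_plasmids"] > 0).sum()),
                "theta": round(threshold["theta"], 2),
                "n_active": classes.get("active", 0),
                "n_inactive": classes.get("inactive", 0),
                "n_unmeasured": classes.get("unmeasured", 0),
                "orphan_rna_rate": round(quant_log["orphan_rate"], 4),
            }
        ]
    )
    summary.to_csv(ROOT / "results" / "02_activity_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
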