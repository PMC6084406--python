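"""Score the whole pipeline against the simulation's ground truth.

Compares latent locus activities, active/inactive truth, planted repeat
enrichments, the planted super-enhancer active fractions, and the orphan-RNA
rate with what the pipeline recovered. Report to results/07_recovery.json.
"""

import json
from pathlib import Path

import pandas as pd

from chipstarr.pipeline import run_all
from chipstarr.simulate import read_truth, recovery_report

ROOT = Path(__file__).resolve().parents[1]
RUNDIR = ROOT / "scratch" / "pipeline"


def main() -> None:
    run_all({"outdir": str(RUNDIR), "simulate": {"seed": 1}})
    truth = read_truth(RUNDIR / "simdata")
    report = recovery_report(
        truth,
        {
            "activity": pd.read_csv(RUNDIR / "activity.tsv", sep="\t"),
            "theta": json.loads((RUNDIR / "threshold.json").read_text())["theta"],
            "te": pd.read_csv(RUNDIR / "te_enrichment.tsv", sep="\t"),
            "dissection": pd.read_csv(RUNDIR / "se_dissection.tsv", sep="\t"),
            "orphan_rate": json.loads((RUNDIR / "quant_log.json").read_text())["orphan_rate"],
        },
    )
    out = ROOT / "results" / "07_recovery.json"
    out.write_text(json.dumps(report, indent=2, default=float) + "\n")
    print(json.dumps(report, indent=2, default=float))


if __name__ == "__main__":
    main()
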