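import json
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> dict:
    """One full pipeline run on the default simulated dataset (seed 1).

    Shared across tests that probe recovery of the planted ground truth.
    """
    from chipstarr.pipeline import run_all
    from chipstarr.simulate import read_truth

    outdir = tmp_path_factory.mktemp("default_run")
    manifest = run_all({"outdir": str(outdir), "simulate": {"seed": 1}})
    truth = read_truth(outdir / "simdata")
    return {
        "outdir": outdir,
        "manifest": manifest,
        "truth": truth,
        "activity": pd.read_csv(outdir / "activity.tsv", sep="\t"),
        "plasmids": pd.read_csv(outdir / "plasmid_rpp.tsv", sep="\t"),
        "scaffold": pd.read_csv(outdir / "scaffold.tsv", sep="\t"),
        "theta": json.loads((outdir / "threshold.json").read_text())["theta"],
        "te": pd.read_csv(outdir / "te_enrichment.tsv", sep="\t"),
        "dissection": pd.read_csv(outdir / "se_dissection.tsv", sep="\t"),
        "quant_log": json.loads((outdir / "quant_log.json").read_text()),
    }
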