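"""End-to-end orchestration with a checksummed run manifest.

Seven stages run in dependency order: scaffold -> quant -> threshold ->
modules -> repeats -> se -> features. Each stage records the SHA-256 of its
inputs and outputs in ``manifest.json``; on re-run a stage is skipped when
its parameters and input/output checksums are unchanged, and any corrupted
or missing intermediate forces that stage (and everything downstream) to
recompute.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .activity import compute_rpp, region_activity
from .changepoint import find_threshold
from .enhancer_modules import PredictedEnhancerSet, assign_genes, partition_modules
from .features import extract_features, read_meme
from .repeats import count_overlaps, enrichment_by_activity_level, o_over_e
from .scaffold import build_scaffold, frame_to_scaffold, scaffold_to_frame
from .simulate import SimulationConfig, simulate_experiment
from .superenhancers import (
    call_super,
    dissect_active_subspace,
    se_vs_ne_summary,
    stitch_peaks,
)

log = logging.getLogger(__name__)

STAGES = ["scaffold", "quant", "threshold", "modules", "repeats", "se", "features"]

DEFAULT_PARAMS = {
    "method": "amoc",
    "penalty": "mbic",
    "max_points": 50_000,
    "stitch_distance": 12_500,
    "tss_exclusion": 2_500,
    "signal_mode": "difference",
    "te_bins": [0.0, 2.0, 8.0, 32.0, 138.0],
    "te_unit": "pairs",
    "alpha": 0.05,
    "fix_widths": True,
}

SIM_INPUT_FILES = {
    "tf_peaks": "peaks_tf.narrowPeak",
    "histone_peaks": "peaks_h3k27ac.narrowPeak",
    "blacklist": "blacklist.bed",
    "fragments": "fragments.tsv",
    "samples": "samples.tsv",
    "repeats": "repeats.tsv",
    "tss": "tss.bed",
    "predicted": "predicted.bed",
    "genome": "genome.fa",
    "conservation": "conservation.bedGraph",
    "chip": "chip_se.bedGraph",
    "input": "input_se.bedGraph",
    "motifs": "motifs.meme",
}


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_genome(path: Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "outdir" not in config:
        raise ValueError("config must be a mapping with an 'outdir' key")
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    config = dict(config)
    config["params"] = params
    return config


class PipelineRun:
    """One orchestrated run rooted at ``outdir``."""

    def __init__(self, config: str | Path | dict):
        self.config = load_config(config)
        self.outdir = Path(self.config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.params = self.config["params"]
        self.manifest_path = self.outdir / "manifest.json"
        self.previous = self._load_previous()
        self.manifest: dict = {
            "tool": "chipstarr",
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": [],
        }

    def _load_previous(self) -> dict:
        if self.manifest_path.exists():
            try:
                with open(self.manifest_path) as fh:
                    return json.load(fh)
            except (json.JSONDecodeError, OSError):
                log.warning("unreadable previous manifest; rerunning all stages")
        return {}

    # -- caching -----------------------------------------------------------
    def _stage_fresh(self, name: str, params: dict, inputs: list[Path]) -> dict | None:
        for rec in self.previous.get("stages", []):
            if rec["name"] != name or rec.get("params") != _jsonable(params):
                continue
            in_ok = all(
                Path(p).exists() and sha256(Path(p)) == h
                for p, h in rec["inputs"].items()
            ) and set(rec["inputs"]) == {str(p) for p in inputs}
            out_ok = all(
                Path(p).exists() and sha256(Path(p)) == h
                for p, h in rec["outputs"].items()
            )
            if in_ok and out_ok:
                return rec
        return None

    def _run_stage(self, name: str, params: dict, inputs: list[Path], fn) -> None:
        cached = self._stage_fresh(name, params, inputs)
        if cached is not None:
            log.info("stage %s: up to date, skipped", name)
            rec = dict(cached)
            rec["skipped"] = True
            self.manifest["stages"].append(rec)
            return
        log.info("stage %s: running", name)
        t0 = time.time()
        try:
            outputs = fn()
        except Exception:
            self.manifest["stages"].append(
                {"name": name, "params": _jsonable(params), "failed": True}
            )
            self._write_manifest()
            raise
        self.manifest["stages"].append(
            {
                "name": name,
                "params": _jsonable(params),
                "inputs": {str(p): sha256(Path(p)) for p in inputs},
                "outputs": {str(p): sha256(Path(p)) for p in outputs},
                "seconds": round(time.time() - t0, 3),
                "skipped": False,
            }
        )

    def _write_manifest(self) -> None:
        self.manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    # -- inputs ------------------------------------------------------------
    def resolve_inputs(self) -> dict[str, Path]:
        if "simulate" in self.config:
            simdir = self.outdir / "simdata"
            cfg = SimulationConfig(**(self.config["simulate"] or {}))
            marker = simdir / "sim_config.json"
            want = json.loads(json.dumps(_jsonable(cfg.__dict__), sort_keys=True))
            have = None
            if marker.exists():
                with open(marker) as fh:
                    have = json.load(fh)
            if have != want:
                log.info("generating simulated dataset in %s", simdir)
                simulate_experiment(cfg, simdir)
            return {k: simdir / v for k, v in SIM_INPUT_FILES.items()}
        inputs = self.config.get("inputs", {})
        return {k: Path(v) for k, v in inputs.items()}

    # -- the pipeline ------------------------------------------------------
    def run(self) -> dict:
        paths = self.resolve_inputs()
        out = self.outdir
        p = self.params

        scaffold_tsv = out / "scaffold.tsv"

        def stage_scaffold():
            peaks = sio.read_narrowpeak(paths["tf_peaks"], "TF") + sio.read_narrowpeak(
                paths["histone_peaks"], "histone"
            )
            blacklist = sio.read_bed(paths["blacklist"]) if "blacklist" in paths else []
            regions = build_scaffold(peaks, blacklist, fix_widths=p["fix_widths"])
            scaffold_to_frame(regions).to_csv(scaffold_tsv, sep="\t", index=False)
            return [scaffold_tsv]

        self._run_stage(
            "scaffold",
            {"fix_widths": p["fix_widths"]},
            [paths["tf_peaks"], paths["histone_peaks"], paths.get("blacklist", paths["tf_peaks"])],
            stage_scaffold,
        )

        plasmids_tsv = out / "plasmid_rpp.tsv"
        activity_raw_tsv = out / "activity_unthresholded.tsv"

        def stage_quant():
            fragments = sio.read_fragments(paths["fragments"])
            sheet = sio.read_sample_sheet(paths["samples"])
            plasmids = compute_rpp(fragments, sheet)
            plasmids.to_csv(plasmids_tsv, sep="\t", index=False)
            scaffold = pd.read_csv(scaffold_tsv, sep="\t")
            act = region_activity(scaffold, plasmids, theta=None)
            act.to_csv(activity_raw_tsv, sep="\t", index=False)
            (out / "quant_log.json").write_text(
                json.dumps(
                    {
                        "orphan_rna_counts": plasmids.attrs.get("orphan_rna_counts", 0),
                        "total_rna_counts": plasmids.attrs.get("total_rna_counts", 0),
                        "orphan_rate": plasmids.attrs.get("orphan_rate", 0.0),
                    },
                    indent=2,
                )
            )
            return [plasmids_tsv, activity_raw_tsv, out / "quant_log.json"]

        self._run_stage(
            "quant", {}, [paths["fragments"], paths["samples"], scaffold_tsv], stage_quant
        )

        threshold_json = out / "threshold.json"

        def stage_threshold():
            act = pd.read_csv(activity_raw_tsv, sep="\t")
            rpp = act.loc[act["n_plasmids"] > 0, "rpp_max"].to_numpy(float)
            try:
                res = find_threshold(
                    rpp, method=p["method"], penalty=p["penalty"], max_points=p["max_points"]
                )
                payload = {
                    "theta": res.theta,
                    "theta_log2": res.theta_log2,
                    "changepoints": res.changepoint_indices,
                    "method": res.method,
                    "penalty": res.penalty,
                    "n_points": res.n_points,
                    "subsampled": res.subsampled,
                }
            except ValueError as exc:
                log.warning("threshold stage: %s", exc)
                payload = {"theta": None, "error": str(exc)}
            threshold_json.write_text(json.dumps(payload, indent=2))
            return [threshold_json]

        self._run_stage(
            "threshold",
            {k: p[k] for k in ("method", "penalty", "max_points")},
            [activity_raw_tsv],
            stage_threshold,
        )

        activity_tsv = out / "activity.tsv"
        modules_tsv = out / "modules.tsv"
        genes_tsv = out / "gene_assignments.tsv"

        def stage_modules():
            theta = json.loads(threshold_json.read_text()).get("theta")
            scaffold = pd.read_csv(scaffold_tsv, sep="\t")
            plasmids = pd.read_csv(plasmids_tsv, sep="\t")
            act = region_activity(scaffold, plasmids, theta=theta)
            act.to_csv(activity_tsv, sep="\t", index=False)
            predicted = PredictedEnhancerSet.from_intervals(
                sio.read_bed(paths["predicted"])
            )
            partition_modules(act, predicted).to_csv(modules_tsv, sep="\t", index=False)
            tss = sio.read_tss_bed(paths["tss"])
            assign_genes(act, tss).to_csv(genes_tsv, sep="\t", index=False)
            return [activity_tsv, modules_tsv, genes_tsv]

        self._run_stage(
            "modules",
            {},
            [threshold_json, scaffold_tsv, plasmids_tsv, paths["predicted"], paths["tss"]],
            stage_modules,
        )

        te_tsv = out / "te_enrichment.tsv"
        te_bins_tsv = out / "te_by_activity.tsv"

        def stage_repeats():
            act = pd.read_csv(activity_tsv, sep="\t")
            reps = sio.read_repeatmasker(paths["repeats"])
            universe = act[act["n_plasmids"] > 0].reset_index(drop=True)
            test = universe[universe["activity_class"] == "active"].reset_index(drop=True)
            all_counts = count_overlaps(universe, reps, unit=p["te_unit"])
            if len(test):
                test_counts = count_overlaps(test, reps, unit=p["te_unit"])
                table = o_over_e(all_counts, test_counts, len(universe), len(test))
            else:
                table = o_over_e(all_counts, {}, len(universe), 1).iloc[0:0]
            table.to_csv(te_tsv, sep="\t", index=False)
            enrichment_by_activity_level(
                act, reps, p["te_bins"], unit=p["te_unit"]
            ).to_csv(te_bins_tsv, sep="\t")
            return [te_tsv, te_bins_tsv]

        self._run_stage(
            "repeats",
            {"bins": p["te_bins"], "unit": p["te_unit"]},
            [activity_tsv, paths["repeats"]],
            stage_repeats,
        )

        se_tsv = out / "se_dissection.tsv"
        se_summary_tsv = out / "se_summary.tsv"

        def stage_se():
            theta = json.loads(threshold_json.read_text()).get("theta")
            peaks = sio.read_narrowpeak(paths["histone_peaks"], "histone")
            tss = sio.read_tss_bed(paths["tss"])
            stitched = stitch_peaks(
                peaks, tss, d=p["stitch_distance"], tss_excl=p["tss_exclusion"]
            )
            chip = sio.read_bedgraph(paths["chip"])
            input_ = sio.read_bedgraph(paths["input"])
            stitched = call_super(stitched, chip, input_, mode=p["signal_mode"])
            plasmids = pd.read_csv(plasmids_tsv, sep="\t")
            dis = dissect_active_subspace(
                stitched, plasmids, theta if theta is not None else np.inf
            )
            dis.to_csv(se_tsv, sep="\t", index=False)
            se_vs_ne_summary(dis).to_csv(se_summary_tsv, sep="\t", index=False)
            return [se_tsv, se_summary_tsv]

        self._run_stage(
            "se",
            {k: p[k] for k in ("stitch_distance", "tss_exclusion", "signal_mode")},
            [paths["histone_peaks"], paths["tss"], paths["chip"], paths["input"], plasmids_tsv, threshold_json],
            stage_se,
        )

        features_tsv = out / "features.tsv"

        def stage_features():
            scaffold = pd.read_csv(scaffold_tsv, sep="\t")
            genome = _read_genome(paths["genome"])
            conservation = (
                sio.read_bedgraph(paths["conservation"])
                if "conservation" in paths
                else None
            )
            pwms = read_meme(paths["motifs"]) if "motifs" in paths else []
            feats = extract_features(
                scaffold, genome, conservation, pwms, alpha=p["alpha"]
            )
            feats.to_csv(features_tsv, sep="\t", index=False)
            return [features_tsv]

        self._run_stage(
            "features",
            {"alpha": p["alpha"]},
            [scaffold_tsv, paths["genome"], paths["conservation"], paths["motifs"]],
            stage_features,
        )

        self._write_manifest()
        return self.manifest


def run_all(config: str | Path | dict) -> dict:
    """Run every stage; returns the manifest (also written to outdir)."""
    return PipelineRun(config).run()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(obj.__dict__)
    return obj
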