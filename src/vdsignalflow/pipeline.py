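"""Configuration-driven orchestration: simulate -> prep -> paths -> locus.

A run is described by a YAML/JSON-style mapping with per-stage blocks; the
pipeline executes the enabled stages in dependency order, writes every
output under one directory, and records a manifest with the parameter
echo, per-file SHA-256 checksums and accumulated warnings. Deterministic
stages reproduce identical checksums for the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import io as vio
from . import locus as vlocus
from . import network as vnet
from . import paths as vpaths
from . import prep as vprep
from . import simulate as vsim

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_STAGES = ("simulate", "prep", "paths", "locus")


class RunConfig:
    """Validated pipeline configuration.

    Keys: ``outdir`` (required), ``seed``, ``stages`` (list of stage
    names), per-stage blocks ``simulate``, ``prep``, ``paths``, ``locus``
    and an ``inputs`` block with file paths for stages run without the
    simulator.
    """

    def __init__(self, mapping: dict):
        if "outdir" not in mapping:
            raise ValueError("config must name an output directory 'outdir'")
        self.outdir = Path(mapping["outdir"])
        self.seed = int(mapping.get("seed", 0))
        self.stages = list(mapping.get("stages", _STAGES))
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.simulate = dict(mapping.get("simulate", {}))
        self.prep = dict(mapping.get("prep", {}))
        self.paths = dict(mapping.get("paths", {}))
        self.locus = dict(mapping.get("locus", {}))
        self.inputs = dict(mapping.get("inputs", {}))

    def preflight(self) -> None:
        """Every referenced input file must exist before any stage runs."""
        missing = [str(p) for p in self.inputs.values()
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def to_dict(self) -> dict:
        return {"outdir": str(self.outdir), "seed": self.seed,
                "stages": self.stages, "simulate": self.simulate,
                "prep": self.prep, "paths": self.paths,
                "locus": self.locus, "inputs": self.inputs}


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        return RunConfig(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest.

    A stage failure halts the run with the failing stage named; outputs
    of completed stages are retained on disk.
    """
    cfg.preflight()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "warnings": []}
    files: dict[str, Path] = dict()
    state: dict = {}

    for stage in _STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                files.update(_stage_simulate(cfg, state))
            elif stage == "prep":
                files.update(_stage_prep(cfg, state))
            elif stage == "paths":
                files.update(_stage_paths(cfg, state))
            elif stage == "locus":
                files.update(_stage_locus(cfg, state))
        except Exception as exc:
            _finish_manifest(cfg, manifest, files)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 4)}
        logger.info("stage %s finished in %.2fs", stage,
                    manifest["stages"][stage]["wall_time_s"])
    _finish_manifest(cfg, manifest, files)
    return manifest


def _finish_manifest(cfg: RunConfig, manifest: dict,
                     files: dict[str, Path]) -> None:
    manifest["checksums"] = {name: _sha256(Path(p))
                             for name, p in sorted(files.items())
                             if Path(p).exists()}
    out = cfg.outdir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_simulate(cfg: RunConfig, state: dict) -> dict[str, Path]:
    sim_cfg = vsim.SimConfig(seed=cfg.seed, **cfg.simulate)
    bundle = vsim.simulate_all(sim_cfg)
    state["bundle"] = bundle
    simdir = cfg.outdir / "sim"
    files = vsim.write_simulation(bundle, simdir)
    fx = vsim.generate_locus_fixture(seed=cfg.seed)
    state["locus_fixture"] = fx
    files.update({f"locus_{k}": p for k, p in
                  vsim.write_locus_fixture(fx, simdir).items()})
    return files


def _stage_prep(cfg: RunConfig, state: dict) -> dict[str, Path]:
    if "bundle" in state:
        simdir = cfg.outdir / "sim"
        counts = vio.read_counts(simdir / "counts.tsv", simdir / "samples.tsv")
        idmap = vio.read_idmap(simdir / "idmap.tsv")
    else:
        counts = vio.read_counts(cfg.inputs["counts"], cfg.inputs["samples"])
        idmap = (vio.read_idmap(cfg.inputs["idmap"])
                 if "idmap" in cfg.inputs else None)
    weights = vprep.prepare_condition_weights(
        counts,
        min_count=int(cfg.prep.get("min_count", 5)),
        pseudocount=float(cfg.prep.get("pseudocount", 1.0)),
        idmap=idmap)
    state["weights"] = weights
    files = {}
    for cond, w in weights.items():
        path = cfg.outdir / f"weights_{cond}.tsv"
        vio.write_weights(w, path)
        files[f"weights_{cond}"] = path
    return files


def _stage_paths(cfg: RunConfig, state: dict) -> dict[str, Path]:
    if "bundle" in state:
        g = state["bundle"]["graph"]
        receptors = state["bundle"]["receptors"]
        tfs = state["bundle"]["tfs"]
    else:
        g = vnet.load_edge_list(cfg.inputs["edges"])
        receptors = vio.read_node_list(cfg.inputs["receptors"])
        tfs = vio.read_node_list(cfg.inputs["tfs"])
    g = vnet.largest_connected_component(
        g, strong=bool(cfg.paths.get("strong", False)))
    weights = state.get("weights")
    if weights is None:
        conds = cfg.paths.get("conditions", ["control", "treatment"])
        weights = {c: vio.read_weights(cfg.inputs[f"weights_{c}"], c)
                   for c in conds}
    conds = sorted(weights)
    if len(conds) != 2:
        raise ValueError(f"path comparison needs exactly 2 conditions, "
                         f"got {conds}")
    policy = cfg.paths.get("missing_policy", "floor")
    g_a, w_a = vnet.annotate_weights(g, weights[conds[0]],
                                     missing_policy=policy)
    _, w_b = vnet.annotate_weights(g, weights[conds[1]],
                                   missing_policy=policy)
    top_k = int(cfg.paths.get("top_k", 50))
    report = vpaths.compare_conditions(
        g, receptors, tfs, w_a, w_b, top_k=top_k,
        max_paths_per_pair=int(cfg.paths.get("max_paths_per_pair", 10_000)))
    files = {}
    for rs, tag in ((report.ranked_a, conds[0]), (report.ranked_b, conds[1])):
        path = cfg.outdir / f"ranked_{tag}.tsv"
        path.write_text(rs.to_tsv())
        files[f"ranked_{tag}"] = path
    path = cfg.outdir / "comparison.json"
    report.to_json(path)
    files["comparison"] = path
    gml = cfg.outdir / "network.graphml"
    g_ann, _ = vnet.annotate_weights(g_a, weights[conds[1]],
                                     missing_policy=policy)
    vnet.export_graphml(g_ann, gml,
                        condition_specific_edges=report.specific_to_b)
    files["graphml"] = gml
    state["report"] = report
    return files


def _stage_locus(cfg: RunConfig, state: dict) -> dict[str, Path]:
    if "locus_fixture" in state:
        fx = state["locus_fixture"]
        snps, intervals = fx.snps, fx.intervals
        r2, pheno = fx.r2, fx.phenotypes
    else:
        snps = vio.read_snp_table(cfg.inputs["snps"])
        intervals = vio.read_bed(cfg.inputs["sites"])
        r2 = vio.read_r2_matrix(cfg.inputs["r2"])
        pheno = vio.read_phenotypes(cfg.inputs["phenotypes"])
    alpha = float(cfg.locus.get("alpha", 1e-5))
    ld_threshold = float(cfg.locus.get("ld_threshold", 0.8))
    vitd_threshold = float(cfg.locus.get("vitd_threshold", 30.0))
    significant = vlocus.filter_significant(snps, alpha=alpha)
    per_region, total = vlocus.overlap_counts(snps, intervals)
    blocks = vlocus.ld_blocks(r2, threshold=ld_threshold)
    y, X = vlocus.build_interaction_design(
        pheno, vitd_threshold=vitd_threshold,
        covariates=cfg.locus.get("covariates", ["maternal_asthma", "race"]))
    fit = vlocus.interaction_logistic(y, X)
    result = {
        "n_significant": int(len(significant)),
        "overlap_per_region": {str(intervals.loc[i].get("name", i)):
                               int(c) for i, c in per_region.items()},
        "overlap_total": int(total),
        "ld_blocks": [sorted(b) for b in blocks],
        "glm": {name: {"coef": float(c), "se": float(s), "p": float(p)}
                for name, c, s, p in zip(fit.names, fit.params,
                                         fit.bse, fit.pvalues)},
        "glm_converged": bool(fit.converged),
    }
    path = cfg.outdir / "locus_report.json"
    path.write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    state["locus_result"] = result
    return {"locus_report": path}
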