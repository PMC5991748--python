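"""End-to-end pipeline: simulate/load -> networks -> module comparison ->
preservation -> network-SVM -> diagnostics -> annotation.

Each stage reads its inputs from, and writes its outputs to, stable file
names under the configured output directory, so any stage can be re-run
standalone from the previous stage's artifacts.  ``run_pipeline`` chains
all stages and records a manifest with a content hash per output file;
re-running with the same config reproduces identical hashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from .containers import ExpressionMatrix, ModulePartition
from . import simulate as sim
from .coexpr import CoexpressionNetwork
from .modcompare import compare_partitions
from .preservation import ModulePreservation, classify_modules
from .netsvm import (build_laplacian, NetworkSVM, rank_nodes,
                     extract_subnetwork, evaluate_classifier)
from .diagnostics import evaluate_marker, evaluate_combinations
from .annotate import (TargetMap, load_target_file, consensus_targets,
                       load_gmt, enrich)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "STAGES"]

STAGES = ("simulate", "coexpr", "compare", "preserve", "netsvm",
          "diagnose", "annotate")

_DEFAULTS = {
    "coexpr": {"powers": list(range(1, 21)), "fit_cut": 0.8,
               "min_module_size": 3, "deep_split": 2, "tom_cutoff": 0.1},
    "preservation": {"n_perm": 200},
    "netsvm": {"lambda_margin": 0.01, "lambda_net": 0.01,
               "top_k_up": 20, "top_k_down": 20, "folds": 5},
    "diagnostics": {"weight_mode": "netsvm", "min_subset_size": 1,
                    "max_members": 12},
    "annotate": {"synthesize": True, "n_genes": 200, "alpha": 0.05},
}


@dataclass
class PipelineConfig:
    output_dir: Path
    data: dict            # {"synthetic": {...design...}} or {"paths": {...}}
    coexpr: dict = field(default_factory=dict)
    preservation: dict = field(default_factory=dict)
    netsvm: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)

    def path(self, *parts) -> Path:
        return Path(self.output_dir).joinpath(*parts)


def validate_config(doc: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a raw config document, returning the parsed config and an
    exhaustive error list (empty when valid)."""
    errors: list[str] = []
    if not isinstance(doc, dict) or not doc:
        return None, [f"config must be a non-empty mapping with sections "
                      f"output_dir and data (got {type(doc).__name__})"]
    if "output_dir" not in doc:
        errors.append("missing required key: output_dir")
    data = doc.get("data")
    if not isinstance(data, dict) or not (
            "synthetic" in data or "paths" in data):
        errors.append("data section must contain 'synthetic' (a design) "
                      "or 'paths' (ref/rep/norm CSVs)")
    else:
        if "synthetic" in data:
            syn = data["synthetic"]
            if "seed" not in syn:
                errors.append("data.synthetic.seed is required")
            try:
                sim.SyntheticDesign.from_dict(syn)
            except (TypeError, ValueError) as exc:
                errors.append(f"data.synthetic invalid: {exc}")
        else:
            for key in ("ref", "rep", "norm"):
                p = data["paths"].get(key)
                if p is None:
                    errors.append(f"data.paths.{key} is required")
                elif not Path(p).exists():
                    errors.append(f"data.paths.{key} does not exist: {p}")

    merged = {}
    for section, defaults in _DEFAULTS.items():
        got = doc.get(section, {})
        if not isinstance(got, dict):
            errors.append(f"{section} section must be a mapping")
            got = {}
        merged[section] = {**defaults, **got}

    cx = merged["coexpr"]
    if cx["fit_cut"] <= 0 or cx["fit_cut"] > 1:
        errors.append("coexpr.fit_cut must lie in (0, 1]")
    if cx["min_module_size"] < 1:
        errors.append("coexpr.min_module_size must be >= 1")
    if not (0 <= cx["tom_cutoff"] <= 1):
        errors.append("coexpr.tom_cutoff must lie in [0, 1]")
    pv = merged["preservation"]
    if pv.get("n_perm", 0) < 20:
        errors.append("preservation.n_perm must be >= 20")
    if "seed" not in pv:
        errors.append("preservation.seed is required")
    nv = merged["netsvm"]
    if "seed" not in nv:
        errors.append("netsvm.seed is required")
    if nv["folds"] < 2:
        errors.append("netsvm.folds must be >= 2")
    if nv["lambda_margin"] <= 0:
        errors.append("netsvm.lambda_margin must be positive")
    if nv["lambda_net"] < 0:
        errors.append("netsvm.lambda_net must be nonnegative")
    dg = merged["diagnostics"]
    if dg["weight_mode"] not in ("netsvm", "equal"):
        errors.append("diagnostics.weight_mode must be 'netsvm' or 'equal'")
    an = merged["annotate"]
    if not an.get("synthesize", False):
        for key in ("target_files", "annotation_file"):
            if key not in an:
                errors.append(f"annotate.{key} required when synthesize "
                              "is false")
        for p in an.get("target_files", []):
            if not Path(p).exists():
                errors.append(f"annotate target file missing: {p}")
        af = an.get("annotation_file")
        if af and not Path(af).exists():
            errors.append(f"annotate.annotation_file missing: {af}")
    if errors:
        return None, errors
    return PipelineConfig(
        output_dir=Path(doc["output_dir"]), data=data, **merged), []


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg, errors = validate_config(doc)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


# ----------------------------------------------------------------------
# stage implementations

def _log(cfg: PipelineConfig, record: dict) -> None:
    cfg.path().mkdir(parents=True, exist_ok=True)
    with open(cfg.path("pipeline.log.jsonl"), "a") as fh:
        fh.write(json.dumps(record) + "\n")


def _synthesize_annotation(cfg: PipelineConfig, features, seed: int):
    """Write synthetic three-source target exports and a term-annotation
    GMT for the synthetic feature universe (synthetic stand-ins for the
    database exports the real pipeline would consume)."""
    rng = np.random.default_rng(seed + 7919)
    n_genes = int(cfg.annotate["n_genes"])
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    d = cfg.path("data")
    d.mkdir(parents=True, exist_ok=True)
    sources = {name: {} for name in ("sourceA", "sourceB", "sourceC")}
    for mir in features:
        core = rng.choice(genes, size=rng.integers(2, 8), replace=False)
        for name in sources:
            extra = rng.choice(genes, size=rng.integers(5, 20),
                               replace=False)
            sources[name][mir] = sorted(set(core) | set(extra))
    paths = []
    for name, mapping in sources.items():
        p = d / f"targets_{name}.tsv"
        with open(p, "w") as fh:
            fh.write("mirna\tgene\n")
            for mir in features:
                for g in mapping[mir]:
                    fh.write(f"{mir}\t{g}\n")
        paths.append(str(p))
    gmt = d / "annotation.gmt"
    with open(gmt, "w") as fh:
        for t in range(20):
            cat = "GO" if t < 12 else "KEGG"
            members = rng.choice(genes, size=rng.integers(8, 40),
                                 replace=False)
            fh.write(f"TERM{t + 1:02d}\t{cat}\t" + "\t".join(members) + "\n")
    return paths, str(gmt)


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("data")
    d.mkdir(parents=True, exist_ok=True)
    if "synthetic" in cfg.data:
        design = sim.SyntheticDesign.from_dict(cfg.data["synthetic"])
        ref, rep, norm, truth = sim.generate_cohorts(design)
        ref.to_csv(d / "ref.csv")
        rep.to_csv(d / "rep.csv")
        norm.to_csv(d / "norm.csv")
        sim.truth_table(design).to_csv(d / "truth.csv", index=False)
        with open(d / "design.json", "w") as fh:
            fh.write(design.to_json())
        outputs = [d / f for f in ("ref.csv", "rep.csv", "norm.csv",
                                   "truth.csv", "design.json")]
        if cfg.annotate.get("synthesize", False):
            tpaths, gmt = _synthesize_annotation(cfg, ref.feature_ids,
                                                 design.seed)
            cfg.annotate["target_files"] = tpaths
            cfg.annotate["annotation_file"] = gmt
            outputs += [Path(p) for p in tpaths] + [Path(gmt)]
        return outputs
    paths = cfg.data["paths"]
    for key in ("ref", "rep", "norm"):
        ExpressionMatrix.from_csv(paths[key]).to_csv(d / f"{key}.csv")
    return [d / f"{k}.csv" for k in ("ref", "rep", "norm")]


def _load_group(cfg: PipelineConfig, group: str) -> ExpressionMatrix:
    return ExpressionMatrix.from_csv(cfg.path("data", f"{group}.csv"))


def stage_coexpr(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("coexpr")
    d.mkdir(parents=True, exist_ok=True)
    cx = cfg.coexpr
    summary = {}
    outputs = []
    for group in ("ref", "rep", "norm"):
        X = _load_group(cfg, group)
        net = CoexpressionNetwork.from_expression(
            X, candidate_powers=cx["powers"], fit_cut=cx["fit_cut"])
        part = net.detect_modules(min_module_size=cx["min_module_size"],
                                  deep_split=cx["deep_split"])
        part.to_csv(d / f"{group}_partition.csv")
        net.network.power_scan.to_csv(d / f"{group}_power_scan.csv",
                                      index=False)
        net.network.write_sif(d / f"{group}_network.sif", cx["tom_cutoff"])
        net.network.write_graphml(d / f"{group}_network.graphml",
                                  cx["tom_cutoff"])
        summary[group] = {
            "beta": net.network.beta,
            "reached_fit_cut": bool(net.network.reached_fit_cut),
            "n_modules": len(part.module_labels),
            "module_sizes": part.module_sizes(),
        }
        _log(cfg, {"stage": "coexpr", "group": group,
                   "beta": net.network.beta,
                   "n_modules": len(part.module_labels)})
        outputs += [d / f"{group}_partition.csv",
                    d / f"{group}_power_scan.csv",
                    d / f"{group}_network.sif",
                    d / f"{group}_network.graphml"]
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return outputs + [d / "summary.json"]


def stage_compare(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("compare")
    d.mkdir(parents=True, exist_ok=True)
    parts = {g: ModulePartition.from_csv(
        cfg.path("coexpr", f"{g}_partition.csv"))
        for g in ("ref", "rep", "norm")}
    outputs = []
    summary = {}
    for other in ("rep", "norm"):
        res = compare_partitions(parts["ref"], parts[other])
        res.counts.to_csv(d / f"ref_vs_{other}_counts.csv")
        res.pvalues.to_csv(d / f"ref_vs_{other}_pvalues.csv")
        summary[f"ref_vs_{other}"] = json.loads(res.to_json())
        outputs += [d / f"ref_vs_{other}_counts.csv",
                    d / f"ref_vs_{other}_pvalues.csv"]
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return outputs + [d / "summary.json"]


def stage_preserve(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("preserve")
    d.mkdir(parents=True, exist_ok=True)
    with open(cfg.path("coexpr", "summary.json")) as fh:
        beta = json.load(fh)["ref"]["beta"]
    ref = _load_group(cfg, "ref")
    part = ModulePartition.from_csv(cfg.path("coexpr", "ref_partition.csv"))
    n_perm, seed = cfg.preservation["n_perm"], cfg.preservation["seed"]
    results = {}
    for other in ("rep", "norm"):
        res = ModulePreservation(ref, _load_group(cfg, other), part,
                                 beta=beta).fit(n_perm=n_perm, seed=seed)
        res.to_csv(d / f"preservation_vs_{other}.csv")
        results[other] = res
        _log(cfg, {"stage": "preserve", "vs": other, "n_perm": n_perm,
                   "seed": seed,
                   "z_summary": res.z_summary.round(3).to_dict()})
    table, biomarkers = classify_modules(results["rep"].z_summary,
                                         results["norm"].z_summary)
    table.to_csv(d / "classification.csv")
    with open(d / "biomarkers.json", "w") as fh:
        json.dump({"activated_biomarkers": biomarkers,
                   "n_perm": n_perm, "seed": seed, "beta": beta}, fh,
                  indent=2)
    return [d / "preservation_vs_rep.csv", d / "preservation_vs_norm.csv",
            d / "classification.csv", d / "biomarkers.json"]


def _graph_from_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split("\t")
            if len(parts) >= 3:
                w = float(parts[3]) if len(parts) > 3 else 1.0
                g.add_edge(parts[0], parts[2].strip(), weight=w)
    return g


def stage_netsvm(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("netsvm")
    d.mkdir(parents=True, exist_ok=True)
    ref, norm = _load_group(cfg, "ref"), _load_group(cfg, "norm")
    part = ModulePartition.from_csv(cfg.path("coexpr", "ref_partition.csv"))
    combined = ExpressionMatrix(pd.concat([ref.data, norm.data], axis=1))
    y = np.r_[np.ones(ref.n_samples), -np.ones(norm.n_samples)]
    graph = _graph_from_sif(cfg.path("coexpr", "ref_network.sif"))
    graph.add_nodes_from(combined.feature_ids)
    lap = build_laplacian(graph, nodes=combined.feature_ids)
    nv = cfg.netsvm
    res = NetworkSVM(combined, y, laplacian=lap,
                     lambda_margin=nv["lambda_margin"],
                     lambda_net=nv["lambda_net"]).fit(seed=nv["seed"])
    tbl = res.rank_table(part)
    tbl.to_csv(d / "weights.csv")
    up, down, merged = rank_nodes(res.weights, nv["top_k_up"],
                                  nv["top_k_down"])
    log2fc = pd.Series(
        ref.values.mean(axis=1) - norm.values.mean(axis=1),
        index=ref.feature_ids)
    sub = extract_subnetwork(graph, merged, res.weights, log2fc)
    sub.write_sif(d / "subnetwork.sif")
    sub.write_graphml(d / "subnetwork.graphml")
    perf = evaluate_classifier(
        combined, y,
        lambda_grid=[(nv["lambda_margin"], nv["lambda_net"])],
        laplacian=lap, folds=nv["folds"], seed=nv["seed"])
    metrics = {"top_up": up, "top_down": down, "top_merged": merged,
               "cv": perf["cv_table"].to_dict(orient="records"),
               "apparent": perf["apparent"],
               "converged": res.converged,
               "duality_gap": res.duality_gap}
    with open(d / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    _log(cfg, {"stage": "netsvm", "cv": metrics["cv"],
               "apparent": metrics["apparent"]})
    return [d / "weights.csv", d / "subnetwork.sif",
            d / "subnetwork.graphml", d / "metrics.json"]


def _biomarker_members(cfg: PipelineConfig) -> tuple[list[int], list[str]]:
    with open(cfg.path("preserve", "biomarkers.json")) as fh:
        bio = json.load(fh)["activated_biomarkers"]
    part = ModulePartition.from_csv(cfg.path("coexpr", "ref_partition.csv"))
    if not bio:
        # no activated module: fall back to the most-disrupted one
        cls = pd.read_csv(cfg.path("preserve", "classification.csv"),
                          index_col=0)
        bio = [int(cls["z_vs_norm"].idxmin())]
    members = []
    for m in bio:
        members.extend(part.members(m))
    return [int(m) for m in bio], members


def stage_diagnose(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("diagnose")
    d.mkdir(parents=True, exist_ok=True)
    modules, members = _biomarker_members(cfg)
    ref, norm = _load_group(cfg, "ref"), _load_group(cfg, "norm")
    combined = ExpressionMatrix(pd.concat([ref.data, norm.data], axis=1))
    labels = np.r_[np.ones(ref.n_samples), np.zeros(norm.n_samples)] == 1
    weights = None
    if cfg.diagnostics["weight_mode"] == "netsvm":
        wtab = pd.read_csv(cfg.path("netsvm", "weights.csv"), index_col=0)
        weights = [float(wtab.loc[f, "weight"]) for f in members]
    marker = evaluate_marker(combined, members, labels, weights,
                             name=f"modules_{'_'.join(map(str, modules))}")
    marker.roc.points.to_csv(d / "module_roc.csv", index=False)
    results = {"module_marker": marker.to_dict(),
               "weight_mode": cfg.diagnostics["weight_mode"],
               "modules": modules}
    max_members = cfg.diagnostics["max_members"]
    combo_members = members
    if len(members) > max_members:
        order = np.argsort([-abs(w) for w in (weights or [0] * len(members))])
        combo_members = [members[i] for i in order[:max_members]]
    combos = evaluate_combinations(
        combined, combo_members, labels,
        weights=None if weights is None else
        [weights[members.index(f)] for f in combo_members],
        min_size=max(1, cfg.diagnostics["min_subset_size"]))
    results["combinations"] = [c.to_dict() for c in combos]
    results["best_combination"] = combos[0].to_dict()
    with open(d / "diagnostics.json", "w") as fh:
        json.dump(results, fh, indent=2)
    _log(cfg, {"stage": "diagnose", "module_auc": marker.auc,
               "best_combo_auc": combos[0].auc})
    return [d / "module_roc.csv", d / "diagnostics.json"]


def stage_annotate(cfg: PipelineConfig) -> list[Path]:
    d = cfg.path("annotate")
    d.mkdir(parents=True, exist_ok=True)
    _, members = _biomarker_members(cfg)
    tfiles = cfg.annotate.get("target_files")
    if tfiles is None and cfg.annotate.get("synthesize"):
        tfiles = [str(cfg.path("data", f"targets_source{s}.tsv"))
                  for s in "ABC"]
        cfg.annotate["annotation_file"] = str(
            cfg.path("data", "annotation.gmt"))
    tmap = TargetMap({Path(p).stem: load_target_file(p) for p in tfiles})
    cons = consensus_targets(tmap, members)
    cons.to_frame().to_csv(d / "consensus_targets.csv", index=False)
    nx.write_graphml(cons.to_graph(), d / "target_network.graphml")
    ann = load_gmt(cfg.annotate["annotation_file"])
    if cons.union:
        universe = sorted(set().union(*ann["genes"]) | cons.union)
        table = enrich(sorted(cons.union), ann, universe=universe,
                       alpha=cfg.annotate["alpha"])
    else:
        table = pd.DataFrame()
    table.to_csv(d / "enrichment.csv", index=False)
    _log(cfg, {"stage": "annotate", "n_targets": len(cons.union),
               "n_terms_tested": len(table)})
    return [d / "consensus_targets.csv", d / "target_network.graphml",
            d / "enrichment.csv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "coexpr": stage_coexpr,
    "compare": stage_compare, "preserve": stage_preserve,
    "netsvm": stage_netsvm, "diagnose": stage_diagnose,
    "annotate": stage_annotate,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages in order and return the manifest."""
    manifest = {"stages": {}, "config_seeds": {
        "synthetic": cfg.data.get("synthetic", {}).get("seed"),
        "preservation": cfg.preservation.get("seed"),
        "netsvm": cfg.netsvm.get("seed"),
    }}
    for stage in STAGES:
        t0 = time.monotonic()
        try:
            outputs = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            record = {"stage": stage, "error": type(exc).__name__,
                      "message": str(exc)}
            _log(cfg, record)
            raise RuntimeError(f"pipeline stage '{stage}' failed: "
                               f"{exc}") from exc
        manifest["stages"][stage] = {
            "elapsed_s": round(time.monotonic() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
    with open(cfg.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
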