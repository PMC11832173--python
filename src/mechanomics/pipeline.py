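"""Configuration-driven orchestration of the full marker-discovery analysis.

``run_config`` executes, from one YAML/JSON config: dataset loading
(collapse duplicates, normalize, intersect genes) -> per-dataset PCA
and processed loadings -> PC-corr scoring, cross-dataset combination
and thresholding -> network export -> combinatorial-marker construction
-> per-hypothesis multiview AUC evaluation -> JVT for every single-gene
marker and the combinatorial marker. Every output is stamped with the
config hash and seed; re-running a config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from contextlib import contextmanager
from pathlib import Path
from typing import Any, Sequence

import networkx as nx
import numpy as np
import yaml

from . import evaluation, marker as marker_mod, pccorr
from .datasets import (
    ComparisonSpec,
    ExpressionDataset,
    collapse_duplicates,
    intersect_genes,
    normalize,
    read_expression_matrix,
)

logger = logging.getLogger(__name__)

STAGES = ("load", "network", "marker", "evaluate", "jvt")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def load_config(config_path: str | Path) -> dict[str, Any]:
    """Read a YAML (or JSON) pipeline config; paths resolve relative to it."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    cfg["_base_dir"] = str(config_path.parent.resolve())
    return cfg


def _resolve_path(cfg: dict, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else Path(cfg.get("_base_dir", ".")) / path


def _config_hash(cfg: dict[str, Any], seed: int) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    payload = json.dumps({"config": clean, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _comparison_from(entry: dict, default_dataset: str | None = None) -> ComparisonSpec:
    return ComparisonSpec(
        dataset_name=entry.get("dataset", default_dataset),
        group_a=entry["group_a"],
        group_b=entry["group_b"],
    )


def _dataset_comparison(ds: ExpressionDataset, entry: dict) -> ComparisonSpec:
    """The two-class comparison used for component selection on one view."""
    if "group_a" in entry and "group_b" in entry:
        return _comparison_from({**entry, "dataset": ds.name})
    labels = sorted(set(ds.sample_groups.values()))
    if len(labels) != 2:
        raise PipelineError(
            f"dataset {ds.name!r} has {len(labels)} groups; specify group_a/group_b"
        )
    # convention: 'stiff' is the positive side when present
    if set(labels) == {"stiff", "soft"}:
        a, b = "stiff", "soft"
    else:
        a, b = labels
        logger.info("dataset %s: defaulting group_a=%r, group_b=%r", ds.name, a, b)
    return ComparisonSpec(dataset_name=ds.name, group_a=[a], group_b=[b])


def _child_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence((base, *key)).generate_state(1)[0] % (2**31))


def select_module(network: pccorr.CombinedNetwork) -> list[str]:
    """Marker module from a thresholded network: its largest clique.

    The module sought is a *strongly interconnected* gene set — every
    pair co-expressed and discriminative in all views — which in graph
    terms is a clique, not merely a connected component (spurious edges
    chain unrelated genes into large sparse components). Ties between
    equal-size cliques break by total |edge weight|, then
    lexicographically.
    """
    graph = network.to_graph()
    if graph.number_of_nodes() == 0:
        return []
    weight = {frozenset((a, b)): abs(w) for a, b, w in network.edges}

    def clique_key(clique: list[str]):
        total = sum(
            weight.get(frozenset((a, b)), 0.0)
            for i, a in enumerate(clique)
            for b in clique[i + 1:]
        )
        return (len(clique), total, sorted(clique, reverse=True))

    best = max(nx.find_cliques(graph), key=clique_key)
    return sorted(best)


def run_config(
    config: str | Path | dict[str, Any],
    seed: int | None = None,
    out: str | Path | None = None,
    stages: Sequence[str] = STAGES,
) -> dict[str, Any]:
    """Execute the configured analysis and write the output bundle.

    Returns the results dictionary also written to ``results.json``.
    A failure in any stage removes partial outputs and raises
    :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    outdir = Path(out if out is not None else _resolve_path(cfg, cfg.get("output", "results")))
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {
        "config_hash": _config_hash(cfg, seed),
        "seed": seed,
        "stages": list(stages),
    }
    try:
        return _run(cfg, seed, outdir, set(stages), bundle)
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for name in ("results.json", "marker.json"):
                (outdir / name).unlink(missing_ok=True)
        raise


def _run(cfg, seed, outdir, stages, bundle):
    # ---- load ------------------------------------------------------------
    with _stage("load"):
        entries = cfg["datasets"]
        datasets: list[ExpressionDataset] = []
        for entry in entries:
            ds = read_expression_matrix(
                _resolve_path(cfg, entry["matrix"]),
                _resolve_path(cfg, entry["annotations"]),
                entry["name"],
                transpose=bool(entry.get("transpose", False)),
            )
            ds = collapse_duplicates(ds)
            mode = entry.get("normalization", "log1p")
            if mode != "raw":
                ds = normalize(ds, mode, pseudocount=float(entry.get("pseudocount", 1.0)))
            datasets.append(ds)
        if len(datasets) > 1:
            datasets = intersect_genes(datasets)
        by_name = {ds.name: ds for ds in datasets}
        prediction = cfg.get("prediction", [ds.name for ds in datasets])
        unknown = [n for n in prediction if n not in by_name]
        if unknown:
            raise ValueError(f"prediction set references unknown datasets: {unknown}")
        bundle["datasets"] = {
            ds.name: {"genes": ds.n_genes, "samples": ds.n_samples, "norm": ds.norm_state}
            for ds in datasets
        }

    if "network" not in stages:
        _write_results(bundle, outdir)
        return bundle

    # ---- network ---------------------------------------------------------
    with _stage("network"):
        strategy = cfg.get("component", "joint" if len(prediction) > 1 else "auto")
        if isinstance(strategy, str) and strategy not in ("auto", "joint"):
            strategy = int(strategy)
        method = cfg.get("combination", "mean")
        entry_by_name = {e["name"]: e for e in entries}
        views, masks = [], []
        for name in prediction:
            ds = by_name[name]
            comp_spec = _dataset_comparison(ds, entry_by_name[name])
            masks.append(comp_spec.resolve(ds))
            n_comp = max(1, min(ds.n_genes, ds.n_samples - 1))
            views.append((ds, pccorr.compute_pca(ds, n_comp)))
        if strategy == "joint" and len(views) > 1:
            indices = pccorr.select_components_joint(views, method=method)
        else:
            indices = []
            for (ds, components), (mask_a, mask_b) in zip(views, masks):
                labels = np.where(mask_a, "a", np.where(mask_b, "b", "other"))
                indices.append(pccorr.select_component(components, labels, strategy))
        results, loadings = [], []
        for (ds, components), (mask_a, mask_b), k in zip(views, masks, indices):
            comp = pccorr.orient_to_groups(components[k - 1], mask_a, mask_b)
            logger.info("dataset %s: using PC%d", ds.name, k)
            results.append(pccorr.pccorr_matrix(ds, comp.processed))
            loadings.append(comp.processed)
        combined = pccorr.combine_pccorr(results, method)

        cutoff_cfg = cfg.get("cutoff", 0.75)
        cutoff_list = cutoff_cfg if isinstance(cutoff_cfg, list) else [cutoff_cfg]
        cutoffs = [
            pccorr.percentile_cutoff(combined, float(c["percentile"]))
            if isinstance(c, dict)
            else float(c)
            for c in cutoff_list
        ]
        networks = [pccorr.build_network(combined, c, loadings) for c in cutoffs]
        bundle["network"] = []
        for net in networks:
            tag = f"cutoff_{net.cutoff:.6g}"
            files = pccorr.export_network(net, outdir / tag)
            bundle["network"].append(
                {
                    "cutoff": net.cutoff,
                    "method": net.method,
                    "nodes": len(net.nodes),
                    "edges": len(net.edges),
                    "files": [str(f) for f in files],
                }
            )

    if "marker" not in stages:
        _write_results(bundle, outdir)
        return bundle

    # ---- marker ----------------------------------------------------------
    with _stage("marker"):
        inference_name = cfg.get("inference_dataset", prediction[0])
        inference_ds = by_name[inference_name]
        module_genes = cfg.get("marker_genes")
        if module_genes is None:
            # strictest cutoff whose network still has >= 2 nodes
            for net in sorted(networks, key=lambda n: -n.cutoff):
                if len(net.nodes) >= 2:
                    module_genes = select_module(net)
                    break
            else:
                module_genes = []
        module_genes = [g.strip().upper() for g in module_genes]
        bundle["module_genes"] = module_genes
        comb_marker = None
        if len(module_genes) >= 2:
            comb_marker = marker_mod.build_marker(inference_ds, module_genes)
            comb_marker.to_json(outdir / "marker.json")
            bundle["marker"] = {
                "genes": comb_marker.genes,
                "reference": comb_marker.reference,
                "align_flags": comb_marker.align_flags,
                "normalization": comb_marker.normalization,
            }
        else:
            logger.warning("module has fewer than 2 genes; no combinatorial marker")

    hypotheses = {
        name: [_comparison_from(e) for e in comps]
        for name, comps in cfg.get("hypotheses", {}).items()
    }
    if "evaluate" not in stages or not hypotheses:
        _write_results(bundle, outdir)
        return bundle

    # ---- evaluate (+ jvt) ------------------------------------------------
    sidedness = cfg.get("sidedness", "two_sided")
    operator = cfg.get("operator", "min")
    T = int(cfg.get("T", 10_000))
    run_jvt = "jvt" in stages
    with _stage("evaluate"):
        pool = evaluation.common_gene_pool(datasets)
        evaluation_table: dict[str, Any] = {}
        for h_idx, (h_name, comps) in enumerate(sorted(hypotheses.items())):
            markers: dict[str, Any] = {}
            for g_idx, gene in enumerate(module_genes):
                jr = evaluation.jvt_single(
                    gene, datasets, comps,
                    T=T, seed=_child_seed(seed, h_idx, g_idx),
                    sidedness=sidedness, operator=operator,
                )
                markers[gene] = _marker_entry(jr, include_p=run_jvt)
            if comb_marker is not None:
                jr = evaluation.jvt_combinatorial(
                    comb_marker.genes, datasets, comps,
                    T=T, seed=_child_seed(seed, h_idx, len(module_genes)),
                    sidedness=sidedness, operator=operator,
                    inference_dataset=inference_name,
                )
                markers["comb"] = _marker_entry(jr, include_p=run_jvt)
            evaluation_table[h_name] = {
                "comparisons": [
                    f"{c.dataset_name}:{'+'.join(sorted(c.group_a))}"
                    f"_vs_{'+'.join(sorted(c.group_b))}"
                    for c in comps
                ],
                "markers": markers,
            }
        bundle["pool_size"] = len(pool)
        bundle["operator"] = operator
        bundle["sidedness"] = sidedness
        bundle["T"] = T
        bundle["evaluation"] = evaluation_table

    _write_results(bundle, outdir)
    return bundle


def _marker_entry(jr: evaluation.JVTResult, include_p: bool) -> dict[str, Any]:
    entry: dict[str, Any] = {
        "per_comparison_auc": [round(r.auc, 6) for r in jr.per_comparison],
        "multiview": round(jr.observed, 6),
    }
    if include_p:
        entry.update(
            jvt_p=jr.p_value,
            jvt_p_smoothed=jr.p_smoothed,
            T=jr.T,
            sampling=jr.sampling,
            seed=jr.seed,
        )
    return entry


def _write_results(bundle: dict[str, Any], outdir: Path) -> None:
    (outdir / "results.json").write_text(json.dumps(bundle, indent=2, default=str))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize(bundle: str | Path | dict[str, Any], out: str | Path | None = None) -> str:
    """Render the per-hypothesis markers x {min AUC, JVT p} tables.

    Accepts a results dict or a bundle directory; writes one TSV per
    hypothesis next to the bundle (or under ``out``) and returns the
    rendered text report. Values are taken verbatim from the bundle.
    """
    if not isinstance(bundle, dict):
        path = Path(bundle) / "results.json"
        if not path.exists():
            raise FileNotFoundError(f"incomplete bundle: missing {path}")
        out = Path(out) if out is not None else Path(bundle)
        bundle = json.loads(path.read_text())
    elif out is not None:
        out = Path(out)

    lines = [f"config {bundle.get('config_hash', '?')}  seed {bundle.get('seed', '?')}"]
    for net in bundle.get("network", []):
        lines.append(
            f"network [{net['method']}] cutoff={net['cutoff']:.4g}: "
            f"{net['nodes']} nodes, {net['edges']} edges"
        )
    if bundle.get("module_genes"):
        lines.append("module: " + ", ".join(bundle["module_genes"]))

    for h_name, h in bundle.get("evaluation", {}).items():
        markers = h["markers"]
        if not markers:
            continue
        names = list(markers)
        op = bundle.get("operator", "min")
        header = ["measure"] + names
        rows = [[f"{op} AUC-ROC"] + [f"{markers[n]['multiview']:.2f}" for n in names]]
        if any("jvt_p" in markers[n] for n in names):
            rows.append(
                ["JVT p value"]
                + [
                    f"{markers[n]['jvt_p']:.2f}" if "jvt_p" in markers[n] else "-"
                    for n in names
                ]
            )
        lines.append("")
        lines.append(f"== {h_name} ==")
        widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
        for row in [header] + rows:
            lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
        if out is not None:
            tsv = Path(out) / f"table_{h_name}.tsv"
            with open(tsv, "w") as fh:
                fh.write("\t".join(header) + "\n")
                for row in rows:
                    fh.write("\t".join(row) + "\n")
    report = "\n".join(lines)
    if out is not None:
        (Path(out) / "report.txt").write_text(report + "\n")
    return report
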