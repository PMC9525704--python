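"""End-to-end orchestration: simulate -> preprocess -> select -> classify -> mine.

Two data modes mirror the two arms of the study design this pipeline serves:

* ``mirna-like`` — a few thousand features; the graph is built on all
  features retained after redundancy removal (beta defaults to 0.6).
* ``mrna-like`` — tens of thousands of features; an AMGM top-k pre-filter
  (k defaults to 1000) runs before graph construction (beta defaults to 0.5).

One master seed derives a stable per-stage seed, every artifact is written
under the run directory, and a manifest records the configuration snapshot
and the SHA-256 checksum of each artifact so that re-runs are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import amgm as amgm_mod
from . import graph as graph_mod
from . import rules as rules_mod
from .classify import ClassifierConfig, evaluate, fit_classifier
from .datasets import LabeledExpression, SimConfig, generate_cohort, read_cohort, write_cohort
from .preprocess import (
    fit_normalization,
    minmax_normalize,
    remove_redundant_features,
    split_holdout,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report", "stage_seed"]

MODE_DEFAULTS = {
    "mirna-like": {"beta": 0.6, "k": None},
    "mrna-like": {"beta": 0.5, "k": 1000},
}

#: Full edge lists are only materialized for graphs up to this many nodes.
EDGE_EXPORT_CAP = 200
#: At most this many rules per subtype are written to disk (strongest first).
RULE_EXPORT_CAP = 2000


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    mode: str = "mirna-like"
    sim: SimConfig | None = None
    input_path: str | None = None
    input_orientation: str = "samples"
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    k: int | None = None
    beta: float | None = None
    gamma: float = 0.3
    exact_mis_cap: int = graph_mod.DEFAULT_EXACT_MIS_CAP
    classifier: str = "sodae"
    classifier_config: ClassifierConfig | None = None
    min_support: float = 0.1
    max_length: int = 4
    min_lift: float = 1.1
    run_classify: bool = True
    run_rules: bool = True
    seed: int = 0
    outdir: str = "panelminer_run"

    def resolved_beta(self) -> float:
        return self.beta if self.beta is not None else MODE_DEFAULTS[self.mode]["beta"]

    def resolved_k(self) -> int | None:
        return self.k if self.k is not None else MODE_DEFAULTS[self.mode]["k"]

    def validate(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sim is None and self.input_path is None:
            raise ValueError("either a simulation config or an input path is required")


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    stages: dict[str, dict] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    outdir: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "artifacts": self.artifacts,
            "stages": self.stages,
            "timestamps": self.timestamps,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=_jsonable)

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            config=raw["config"],
            artifacts=raw["artifacts"],
            stages=raw["stages"],
            timestamps=raw.get("timestamps", {}),
            outdir=os.path.dirname(os.path.abspath(path)),
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = config.outdir
        os.makedirs(self.outdir, exist_ok=True)
        self.manifest = RunManifest(
            config=json.loads(json.dumps(dataclasses.asdict(config), default=_jsonable)),
            outdir=self.outdir,
        )

    def path(self, rel: str) -> str:
        return os.path.join(self.outdir, rel)

    def register(self, rel: str) -> None:
        self.manifest.artifacts[rel] = _sha256(self.path(rel))

    def write_frame(self, frame: pd.DataFrame, rel: str) -> None:
        frame.to_csv(self.path(rel), sep="\t", index=False)
        self.register(rel)

    def write_json(self, obj, rel: str) -> None:
        with open(self.path(rel), "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        self.register(rel)

    def stamp(self, stage: str) -> None:
        self.manifest.timestamps[stage] = time.time()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every enabled stage and return the completed manifest."""
    run = _Run(config)
    try:
        cohort = _stage_data(run)
        split, norm, removed = _stage_preprocess(run, cohort)
        panel, partition, scores = _stage_select(run, split, norm)
        if config.run_classify:
            _stage_classify(run, split, norm, panel)
        if config.run_rules:
            _stage_mine(run, cohort, norm, panel, removed)
    except Exception as exc:  # annotate failures with the stage that broke
        stage = run.manifest.stages.get("_current", "unknown")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    run.manifest.stages.pop("_current", None)
    run.manifest.save(run.path("manifest.json"))
    report(run.manifest)
    return run.manifest


def _stage_data(run: _Run) -> LabeledExpression:
    run.manifest.stages["_current"] = "data"
    run.stamp("data")
    cfg = run.config
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
        cohort = generate_cohort(sim)
        write_cohort(cohort, run.path("cohort.tsv"), orientation="samples")
        run.register("cohort.tsv")
        if os.path.exists(run.path("cohort.tsv.features.tsv")):
            run.register("cohort.tsv.features.tsv")
    else:
        cohort = read_cohort(cfg.input_path, orientation=cfg.input_orientation)
    run.manifest.stages["data"] = {
        "n_samples": cohort.n_samples,
        "n_features": cohort.n_features,
        "classes": {c: int(np.sum(cohort.labels == c)) for c in cohort.classes},
    }
    return cohort


def _stage_preprocess(run: _Run, cohort: LabeledExpression):
    run.manifest.stages["_current"] = "preprocess"
    run.stamp("preprocess")
    cfg = run.config
    reduced, removed = remove_redundant_features(cohort)
    split = split_holdout(reduced, cfg.fractions, seed=stage_seed(cfg.seed, "split"))
    norm = fit_normalization(split.train)
    membership = pd.concat(
        [
            pd.DataFrame({"sample_id": part.sample_ids, "partition": name})
            for name, part in split.parts.items()
        ]
    ).sort_values("sample_id")
    run.write_frame(membership, "split.tsv")
    run.write_frame(norm.to_frame(), "normalization.tsv")
    pd.Series(removed, name="feature_id").to_csv(
        run.path("removed_features.tsv"), sep="\t", index=False
    )
    run.register("removed_features.tsv")
    run.manifest.stages["preprocess"] = {
        "n_removed": len(removed),
        "n_retained": reduced.n_features,
        "partition_sizes": {k: v.n_samples for k, v in split.parts.items()},
    }
    return split, norm, removed


def _stage_select(run: _Run, split, norm):
    run.manifest.stages["_current"] = "select"
    run.stamp("select")
    cfg = run.config
    train_scaled = minmax_normalize(split.train, norm)
    scores = amgm_mod.amgm_scores(train_scaled)
    run.write_frame(scores.to_frame(), "amgm_scores.tsv")
    k = cfg.resolved_k()
    if k is not None:
        keep = amgm_mod.select_top_k(scores, min(k, len(scores.feature_ids)))
        graph_input = train_scaled.subset_features(keep)
    else:
        graph_input = train_scaled
    g = graph_mod.build_weight_matrix(graph_input, scores, cfg.resolved_beta())
    graph_mod.softmax_scale(g)
    partition = graph_mod.louvain_partition(g, seed=stage_seed(cfg.seed, "louvain"))
    adjacency = graph_mod.threshold_adjacency(g, cfg.gamma)
    panel = graph_mod.select_candidates(g, partition, adjacency, cfg.exact_mis_cap)
    run.write_frame(panel.to_frame(), "panel.tsv")
    communities = pd.DataFrame(
        sorted(partition.membership.items()), columns=["feature_id", "community"]
    )
    run.write_frame(communities, "communities.tsv")
    if g.n_nodes <= EDGE_EXPORT_CAP:
        run.write_frame(g.edge_list_frame(), "graph_edges.tsv")
    run.manifest.stages["select"] = {
        "k": k,
        "beta": cfg.resolved_beta(),
        "gamma": cfg.gamma,
        "n_nodes": g.n_nodes,
        "edge_count": g.edge_count,
        "n_communities": partition.n_communities,
        "modularity": partition.modularity,
        "panel_size": len(panel),
    }
    return panel, partition, scores


def _stage_classify(run: _Run, split, norm, panel) -> None:
    run.manifest.stages["_current"] = "classify"
    run.stamp("classify")
    cfg = run.config
    clf_cfg = cfg.classifier_config or ClassifierConfig()
    clf_cfg = dataclasses.replace(clf_cfg, seed=stage_seed(cfg.seed, "classify"))
    scaled = {name: minmax_normalize(part, norm) for name, part in split.parts.items()}
    scaled_split = dataclasses.replace(
        split, train=scaled["train"], validation=scaled["validation"], test=scaled["test"]
    )
    model = fit_classifier(scaled_split, panel.feature_ids, clf_cfg, cfg.classifier)
    metrics = {}
    for name, part in scaled.items():
        rep = evaluate(model, part.subset_features(panel.feature_ids), tag=name)
        run.write_json(rep.to_dict(), f"metrics_{name}.json")
        rep.confusion_frame().to_csv(run.path(f"confusion_{name}.tsv"), sep="\t")
        run.register(f"confusion_{name}.tsv")
        if name == "test":
            for cls, pts in rep.roc_points.items():
                run.write_frame(pts, f"roc_test_{cls}.tsv")
        metrics[name] = {
            "accuracy": rep.accuracy,
            "f1": {c: rep.per_class[c]["f1"] for c in rep.classes},
            "auc": {c: rep.per_class[c]["auc"] for c in rep.classes},
        }
    run.manifest.stages["classify"] = {
        "model": cfg.classifier,
        "architecture": list(getattr(model, "architecture_", ())),
        "metrics": metrics,
    }


def _stage_mine(run: _Run, cohort, norm, panel, removed) -> None:
    run.manifest.stages["_current"] = "mine"
    run.stamp("mine")
    cfg = run.config
    pooled = cohort.subset_features(norm.feature_ids)
    pooled_scaled = minmax_normalize(pooled, norm)
    db = rules_mod.discretize(pooled_scaled.subset_features(panel.feature_ids))
    summary: dict[str, dict] = {}
    total_rules = 0
    for subtype in db.classes:
        class_rules = rules_mod.class_association_rules(
            db, subtype, cfg.min_support, cfg.max_length, cfg.min_lift
        )
        total_rules += len(class_rules)
        table = rules_mod.repeat_counts(class_rules)
        run.write_frame(table, f"repeat_counts_{subtype}.tsv")
        # strongest-support rules first: high-support class rules are the
        # ones the repeat-count ranking and dependency networks build on
        class_rules = sorted(
            class_rules,
            key=lambda r: (-r.support, -r.lift, sorted(r.antecedent)),
        )
        exported = pd.DataFrame(
            {
                "antecedent": [
                    ";".join(f"{f}={lev}" for f, lev in sorted(r.antecedent))
                    for r in class_rules[:RULE_EXPORT_CAP]
                ],
                "consequent": [subtype] * min(len(class_rules), RULE_EXPORT_CAP),
                "support": [r.support for r in class_rules[:RULE_EXPORT_CAP]],
                "confidence": [r.confidence for r in class_rules[:RULE_EXPORT_CAP]],
                "lift": [r.lift for r in class_rules[:RULE_EXPORT_CAP]],
            }
        )
        run.write_frame(exported, f"rules_{subtype}.tsv")
        entry = {
            "n_class_rules": len(class_rules),
            "top_features": table.head(10).to_dict(orient="records"),
        }
        if len(table):
            anchor = str(table.iloc[0]["feature_id"])
            net = rules_mod.dependency_network(class_rules, anchor)
            run.write_frame(net, f"dependency_{subtype}.tsv")
            entry["anchor"] = anchor
        summary[subtype] = entry
    run.manifest.stages["mine"] = {
        "n_class_rules_total": total_rules,
        "min_support": cfg.min_support,
        "max_length": cfg.max_length,
        "min_lift": cfg.min_lift,
        "per_subtype": summary,
    }


def report(manifest: RunManifest) -> dict[str, str]:
    """Write summary.json and summary.txt from the manifest alone.

    The summary is a pure function of the manifest's stage records (no
    recomputation, no timestamps), so regenerating it is byte-identical.
    """
    stages = manifest.stages
    summary = {name: stages[name] for name in ("data", "preprocess", "select", "classify", "mine") if name in stages}
    gaps = [
        name
        for name in ("data", "preprocess", "select", "classify", "mine")
        if name not in stages
    ]
    if gaps:
        summary["missing_stages"] = gaps

    lines = ["panelminer run summary", "======================", ""]
    if "data" in stages:
        d = stages["data"]
        lines += [
            f"cohort: {d['n_samples']} samples x {d['n_features']} features",
            "classes: " + ", ".join(f"{c}={n}" for c, n in sorted(d["classes"].items())),
            "",
        ]
    if "preprocess" in stages:
        p = stages["preprocess"]
        sizes = p["partition_sizes"]
        lines += [
            f"redundancy removal: {p['n_removed']} features removed, {p['n_retained']} retained",
            f"split: train={sizes['train']}, validation={sizes['validation']}, test={sizes['test']}",
            "",
        ]
    if "select" in stages:
        s = stages["select"]
        lines += [
            f"graph: {s['n_nodes']} nodes, {s['edge_count']} weighted pairs "
            f"(beta={s['beta']}, gamma={s['gamma']}, k={s['k']})",
            f"louvain: {s['n_communities']} communities, modularity={s['modularity']:.4f}",
            f"candidate panel: {s['panel_size']} features",
            "",
        ]
    if "classify" in stages:
        c = stages["classify"]
        lines.append(f"classifier: {c['model']} (architecture {c['architecture']})")
        order = [p for p in ("train", "validation", "test") if p in c["metrics"]]
        for part in order:
            m = c["metrics"][part]
            f1s = ", ".join(f"{cls}:{v:.2f}" for cls, v in sorted(m["f1"].items()))
            lines.append(f"  {part}: accuracy={m['accuracy']:.1f}%  F1 [{f1s}]")
        lines.append("")
    else:
        lines += ["classification: absent (stage disabled)", ""]
    if "mine" in stages:
        m = stages["mine"]
        lines.append(
            f"rule mining: {m['n_class_rules_total']} class-consequent rules "
            f"(min_support={m['min_support']}, max_length={m['max_length']}, min_lift={m['min_lift']})"
        )
        for subtype, entry in sorted(m["per_subtype"].items()):
            tops = ", ".join(
                f"{t['feature_id']}({t['repeat_count']})" for t in entry["top_features"][:10]
            )
            lines.append(
                f"  {subtype}: {entry['n_class_rules']} class rules; top repeat counts: {tops or 'none'}"
            )
    else:
        lines.append("rule mining: absent (stage disabled)")
    text = "\n".join(lines) + "\n"

    json_path = os.path.join(manifest.outdir, "summary.json")
    txt_path = os.path.join(manifest.outdir, "summary.txt")
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    with open(txt_path, "w") as fh:
        fh.write(text)
    return {"summary.json": json_path, "summary.txt": txt_path}
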