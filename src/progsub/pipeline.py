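"""End-to-end orchestration.

Stages communicate through plain-text artifacts in a working directory, so
each stage is independently re-runnable and composable from the CLI:

    cohort/            simulated (or user-supplied) delimited-text tables
    included.csv       patients passing the cohort filters + exclusion funnel
    nodes.csv          node table (patid, date, stage, next_stage)
    features.txt       binary encounter-vector matrix
    graph.tsv(+nodes)  DPG edge list
    encoder_params.json, encoder_metrics.json, embeddings.txt
    kselect.csv        per-K silhouette / Davies-Bouldin screen
    assignments.csv    patient -> cluster
    transition_stats.csv, survival.json, prevalence.csv, chisq.csv
    prediction_report.json, attribution.csv
    manifest.json      config, seed, per-stage artifact hashes

Every artifact carries a schema-version header; matrices are delimited text
with a shape/dtype sidecar line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize as chz
from . import clustering as clu
from . import featurize as ftz
from . import gnn
from . import graph as gph
from . import predict as prd
from . import synthetic as syn

log = logging.getLogger("progsub")

SCHEMA_PREFIX = "# progsub-schema:"


@dataclass
class PipelineConfig:
    output_dir: str = "progsub_run"
    input_dir: str | None = None  # None -> simulate a cohort
    n_patients: int = 300
    n_subphenotypes: int = 4
    lookback_days: int = 91
    k_neighbors: int = 50
    variant: str = "magnet"
    embedding_size: int = 32
    loss: str = "focal"
    focal_gamma: float = 2.0
    epochs: int = 200
    k_min: int = 2
    k_max: int = 10
    n_init: int = 5
    top_n_features: int = 20
    model_family: str = "gradient-boosted-trees"
    resampling: str = "none"
    search_budget: int = 25
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# text matrix + csv helpers
# ---------------------------------------------------------------------------

def write_matrix(path: Path, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX} {name} v1\n")
        fh.write(f"# shape: {arr.shape[0]} {arr.shape[1]} {arr.dtype}\n")
        np.savetxt(fh, arr, fmt="%.10g")


def read_matrix(path: Path, name: str) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != f"{SCHEMA_PREFIX} {name} v1":
            raise ValueError(f"{path}: schema mismatch: {header!r}")
        shape_line = fh.readline().split()
        n, m, dtype = int(shape_line[2]), int(shape_line[3]), shape_line[4]
        arr = np.loadtxt(fh, ndmin=2)
    if arr.shape != (n, m):
        raise ValueError(f"{path}: shape mismatch {arr.shape} vs {(n, m)}")
    return arr.astype(dtype)


def write_csv(df: pd.DataFrame, path: Path, name: str, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX} {name} v1\n")
        df.to_csv(fh, index=index)


def read_csv(path: Path, name: str, **kwargs) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != f"{SCHEMA_PREFIX} {name} v1":
            raise ValueError(f"{path}: schema mismatch: {header!r}")
        return pd.read_csv(fh, **kwargs)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(workdir: Path, config: PipelineConfig) -> Path:
    spec = syn.CohortSpec(n_patients=config.n_patients,
                          n_subphenotypes=config.n_subphenotypes, seed=config.seed)
    timelines = syn.simulate_cohort(spec)
    cohort_dir = workdir / "cohort"
    syn.write_cohort_tables(timelines, cohort_dir)
    return cohort_dir


def _load_timelines(workdir: Path, config: PipelineConfig) -> list[syn.PatientTimeline]:
    cohort_dir = Path(config.input_dir) if config.input_dir else workdir / "cohort"
    if not (cohort_dir / "demographic.csv").exists():
        raise FileNotFoundError(f"missing input table: {cohort_dir / 'demographic.csv'}")
    return syn.read_cohort_tables(cohort_dir)


def stage_filter(workdir: Path, config: PipelineConfig) -> list[syn.PatientTimeline]:
    timelines = _load_timelines(workdir, config)
    included, counts = syn.apply_inclusion_criteria(timelines)
    df = pd.DataFrame({"patid": [t.patient_id for t in included]})
    write_csv(df, workdir / "included.csv", "included-patients")
    (workdir / "exclusion_counts.json").write_text(json.dumps(counts, indent=2))
    return included

def _included_timelines(workdir: Path, config: PipelineConfig) -> list[syn.PatientTimeline]:
    ids = set(read_csv(workdir / "included.csv", "included-patients")["patid"])
    return [t for t in _load_timelines(workdir, config) if t.patient_id in ids]


def stage_featurize(workdir: Path, config: PipelineConfig) -> None:
    included = _included_timelines(workdir, config)
    space = ftz.build_feature_space()
    vectors = []
    for t in included:
        if len(t.encounters) >= 2:
            vectors.extend(ftz.build_encounter_vectors(t, space,
                                                       lookback_days=config.lookback_days))
    nodes = pd.DataFrame({
        "patid": [v.patient_id for v in vectors],
        "date": [v.date.isoformat() for v in vectors],
        "stage": [v.stage for v in vectors],
        "next_stage": [v.next_stage or "" for v in vectors],
    })
    write_csv(nodes, workdir / "nodes.csv", "encounter-nodes")
    write_matrix(workdir / "features.txt", "encounter-features",
                 np.stack([v.vector for v in vectors]))
    (workdir / "feature_names.txt").write_text(
        f"{SCHEMA_PREFIX} feature-names v1\n" + "\n".join(space.names) + "\n")


def _load_vectors(workdir: Path) -> list[ftz.EncounterVector]:
    nodes = read_csv(workdir / "nodes.csv", "encounter-nodes", dtype=str,
                     keep_default_na=False)
    X = read_matrix(workdir / "features.txt", "encounter-features").astype(np.uint8)
    return [
        ftz.EncounterVector(
            patient_id=r.patid, date=date.fromisoformat(r.date), vector=X[i],
            stage=r.stage, next_stage=r.next_stage or None,
        )
        for i, r in enumerate(nodes.itertuples(index=False))
    ]


def stage_build_graph(workdir: Path, config: PipelineConfig) -> gph.ProgressionGraph:
    vectors = _load_vectors(workdir)
    g = gph.build_dpg(vectors, gph.GraphConfig(k=config.k_neighbors))
    gph.export_graph(g, workdir / "graph.tsv", format="tsv")
    return g


def _load_graph(workdir: Path) -> gph.ProgressionGraph:
    g = gph.import_graph(workdir / "graph.tsv")
    vectors = _load_vectors(workdir)
    order = sorted(range(len(vectors)),
                   key=lambda i: (vectors[i].patient_id, vectors[i].date, i))
    vecs = [vectors[i] for i in order]
    g.features = np.stack([v.vector for v in vecs])
    g.stages = [v.stage for v in vecs]
    g.next_stages = [v.next_stage for v in vecs]
    return g


def _encoder_config(config: PipelineConfig) -> gnn.EncoderConfig:
    return gnn.EncoderConfig(
        variant=config.variant, embedding_size=config.embedding_size,
        loss="focal" if config.loss == "focal" else "cross-entropy",
        focal_gamma=config.focal_gamma, epochs=config.epochs, seed=config.seed,
    )


def _params_to_json(obj):
    import numpy as _np

    from ._autodiff import Tensor
    if isinstance(obj, Tensor):
        return {"__tensor__": obj.value.tolist()}
    if isinstance(obj, dict):
        return {k: _params_to_json(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_params_to_json(v) for v in obj]
    return obj


def _params_from_json(obj):
    from ._autodiff import Tensor
    if isinstance(obj, dict) and "__tensor__" in obj:
        return Tensor(np.array(obj["__tensor__"]), requires_grad=True)
    if isinstance(obj, dict):
        return {k: _params_from_json(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_params_from_json(v) for v in obj]
    return obj


def stage_train(workdir: Path, config: PipelineConfig) -> dict:
    g = _load_graph(workdir)
    params, report, emb = gnn.train_encoder(g, _encoder_config(config))
    (workdir / "encoder_params.json").write_text(json.dumps(_params_to_json(params)))
    (workdir / "encoder_metrics.json").write_text(json.dumps(report, indent=2))
    write_matrix(workdir / "embeddings.txt", "node-embeddings", emb)
    return report


def stage_embed(workdir: Path, config: PipelineConfig) -> np.ndarray:
    g = _load_graph(workdir)
    params = _params_from_json(json.loads((workdir / "encoder_params.json").read_text()))
    emb, _ = gnn.encoder_forward(g, _encoder_config(config), params)
    write_matrix(workdir / "embeddings.txt", "node-embeddings", emb)
    return emb


def _load_sequences(workdir: Path):
    g = _load_graph(workdir)
    emb = read_matrix(workdir / "embeddings.txt", "node-embeddings")
    return clu.collect_sequences(emb, g), g


def _transition_days_for(sequences, timelines) -> np.ndarray:
    by_id = {t.patient_id: t for t in timelines}
    out = []
    for s in sequences:
        t = by_id.get(s.patient_id)
        if t and t.first_ad_date is not None and t.first_mci_date is not None:
            out.append((t.first_ad_date - t.first_mci_date).days)
        else:
            out.append(np.nan)
    return np.array(out, dtype=float)


def stage_select_k(workdir: Path, config: PipelineConfig) -> clu.KSelectionReport:
    sequences, _ = _load_sequences(workdir)
    timelines = _included_timelines(workdir, config)
    report = clu.select_k(
        sequences, k_range=range(config.k_min, config.k_max + 1), seed=config.seed,
        n_init=config.n_init, transition_days=_transition_days_for(sequences, timelines),
    )
    rows = pd.DataFrame([{k: v for k, v in r.items() if not isinstance(v, list)}
                         | {"cluster_sizes": ";".join(map(str, r["cluster_sizes"]))}
                         for r in report.rows])
    write_csv(rows, workdir / "kselect.csv", "k-selection")
    (workdir / "chosen_k.json").write_text(json.dumps({"chosen_k": report.chosen_k}))
    return report


def stage_cluster(workdir: Path, config: PipelineConfig, k: int | None = None) -> clu.ClusteringResult:
    sequences, _ = _load_sequences(workdir)
    if k is None:
        chosen = json.loads((workdir / "chosen_k.json").read_text())["chosen_k"]
        k = chosen if chosen is not None else config.n_subphenotypes
    res = clu.tskmeans(sequences, k, seed=config.seed, n_init=config.n_init)
    df = pd.DataFrame({
        "patid": [s.patient_id for s in sequences],
        "cluster": res.assignments,
    })
    write_csv(df, workdir / "assignments.csv", "cluster-assignments")
    return res


def stage_characterize(workdir: Path, config: PipelineConfig) -> dict:
    assignments = read_csv(workdir / "assignments.csv", "cluster-assignments")
    timelines = _included_timelines(workdir, config)
    by_id = {t.patient_id: t for t in timelines}
    ordered = [by_id[p] for p in assignments["patid"]]
    labels = assignments["cluster"].to_numpy()

    stats = chz.transition_stats(ordered, labels)
    write_csv(stats, workdir / "transition_stats.csv", "transition-stats")

    curves, stat, p = chz.km_logrank(ordered, labels)
    (workdir / "survival.json").write_text(json.dumps({
        "logrank_statistic": stat, "logrank_p": p,
        "curves": [{"cluster": c.cluster, "times": c.times.tolist(),
                    "survival": c.survival.tolist(), "at_risk": c.at_risk.tolist()}
                   for c in curves],
    }, indent=2))

    space = ftz.build_feature_space()
    vecs_by_patient: dict[str, list[np.ndarray]] = {}
    for t in ordered:
        if len(t.encounters) >= 2:
            evs = ftz.build_encounter_vectors(t, space, lookback_days=config.lookback_days)
            vecs_by_patient[t.patient_id] = np.stack([v.vector for v in evs])
    feats = chz.patient_feature_table(vecs_by_patient, space.names)
    feats = feats.loc[assignments["patid"]]
    prev = chz.prevalence_table(feats, labels, top_n=config.top_n_features)
    write_csv(prev, workdir / "prevalence.csv", "prevalence", index=True)
    tests, _top = chz.pairwise_chisq(feats[prev.index], labels)
    write_csv(tests, workdir / "chisq.csv", "chisq-tests")
    return {"logrank_p": p}


def stage_predict(workdir: Path, config: PipelineConfig) -> prd.ModelReport:
    assignments = read_csv(workdir / "assignments.csv", "cluster-assignments")
    amap = dict(zip(assignments["patid"], assignments["cluster"]))
    timelines = _included_timelines(workdir, config)
    space = ftz.build_feature_space()
    dataset = prd.build_baseline_features(timelines, amap, space)
    _, report = prd.fit_classifier(dataset, family=config.model_family,
                                   resampling=config.resampling,
                                   search_budget=config.search_budget, seed=config.seed)
    (workdir / "prediction_report.json").write_text(json.dumps({
        "family": report.family, "resampling": report.resampling,
        "best_params": {k: (v.item() if hasattr(v, "item") else v)
                        for k, v in report.best_params.items()},
        "metrics": report.metrics,
    }, indent=2))
    write_csv(report.attribution, workdir / "attribution.csv", "attribution", index=True)
    return report


def stage_report(workdir: Path) -> str:
    """Collate existing artifacts into a readable text report (no recompute)."""
    lines = ["progsub run report", "=" * 40]
    for name, path in [("exclusion funnel", "exclusion_counts.json"),
                       ("encoder metrics", "encoder_metrics.json"),
                       ("chosen K", "chosen_k.json"),
                       ("survival", "survival.json"),
                       ("prediction", "prediction_report.json")]:
        p = workdir / path
        if p.exists():
            payload = json.loads(p.read_text())
            if name == "survival":
                payload = {k: payload[k] for k in ("logrank_statistic", "logrank_p")}
            lines.append(f"\n[{name}]\n{json.dumps(payload, indent=2)}")
    for csv_name in ["kselect.csv", "transition_stats.csv", "prevalence.csv"]:
        p = workdir / csv_name
        if p.exists():
            lines.append(f"\n[{csv_name}]")
            lines.append(p.read_text().strip())
    text = "\n".join(lines) + "\n"
    (workdir / "report.txt").write_text(text)
    return text


_STAGES = ("simulate", "filter", "featurize", "build-graph", "train",
           "cluster-select", "cluster", "characterize", "predict")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order, writing all artifacts plus a manifest.

    Any stage failure aborts with the stage name; artifacts of completed
    stages are retained.
    """
    workdir = Path(config.output_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}}
    stage_fns = [
        ("simulate", lambda: stage_simulate(workdir, config) if config.input_dir is None
         else _load_timelines(workdir, config)),
        ("filter", lambda: stage_filter(workdir, config)),
        ("featurize", lambda: stage_featurize(workdir, config)),
        ("build-graph", lambda: stage_build_graph(workdir, config)),
        ("train", lambda: stage_train(workdir, config)),
        ("cluster-select", lambda: stage_select_k(workdir, config)),
        ("cluster", lambda: stage_cluster(workdir, config)),
        ("characterize", lambda: stage_characterize(workdir, config)),
        ("predict", lambda: stage_predict(workdir, config)),
    ]
    for name, fn in stage_fns:
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"elapsed_s": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", name, time.time() - t0)
    manifest["artifacts"] = {
        p.name: _file_hash(p) for p in sorted(workdir.glob("*")) if p.is_file()
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    stage_report(workdir)
    return workdir
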