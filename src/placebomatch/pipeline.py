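"""End-to-end orchestration: simulate -> fit -> predict -> evaluate.

The fitted artifact is a :class:`FittedPipeline` — standardizer, k-means
cluster model and per-cluster winning regressors — persisted as a zip
archive with a JSON manifest and a stored probe set that is re-predicted
at load time to guarantee the archive round-trips bit-exactly.

A single run seed fans out deterministically (numpy SeedSequence) to the
simulation, clustering/CV and query stages so each stage is independently
reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .cluster import ClusterModel, KScanReport, assign, kmeans_fit, scan_k
from .colors import delta_e, rgb_to_lab
from .dataio import PIGMENT_COLUMNS, GranuleSample, Standardizer
from .regress import (
    CompetitionConfig,
    CVScore,
    ClusterRegressors,
    RegressionBundle,
    compete,
    fit_final,
    predict_formula,
    r2,
)
from .synthetic import ForwardModel, forward_mix, generate_library, generate_queries

__all__ = ["RunConfig", "FittedPipeline", "run_fit", "run_predict", "run_all", "save_model", "load_model"]

_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Knobs for a full reproduction run."""

    seed: int = 42
    n_library: int = 323
    n_queries: int = 50
    noise_sd: float = 2.0
    design: str = "paperlike"
    k_min: int = 2
    k_max: int = 11
    force_k: int | None = None
    folds: int = 5
    repeats: int = 3
    grids: Mapping[str, Mapping[str, list]] | None = None
    families: Sequence[str] | None = None

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the run seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        names = ("simulate", "fit", "queries")
        return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


@dataclass
class FittedPipeline:
    """Everything needed to turn a query color into a pigment formula."""

    standardizer: Standardizer
    cluster_model: ClusterModel
    bundle: RegressionBundle
    kscan: KScanReport | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, color) -> "PigmentFormula":
        return predict_formula(self.bundle, self.cluster_model, self.standardizer, color)

    def cv_table(self) -> pd.DataFrame:
        rows = []
        for c, reg in sorted(self.bundle.clusters.items()):
            for s in reg.scores:
                rows.append(
                    {
                        "cluster": c,
                        "model": s.model_name,
                        "mean_rmse": s.mean_rmse,
                        "mean_r2": s.mean_r2,
                        "winner": s.model_name == reg.winner,
                    }
                )
        return pd.DataFrame(rows)


def run_fit(samples: Sequence[GranuleSample], config: RunConfig | None = None) -> FittedPipeline:
    """Standardize -> select k -> cluster -> per-cluster competition ->
    final refit. Training samples must all carry formulas."""
    config = config or RunConfig()
    if any(s.formula is None for s in samples):
        raise ValueError("training samples must all carry pigment formulas")
    fit_seed = config.stage_seeds()["fit"]

    colors = [s.color for s in samples]
    standardizer = Standardizer().fit(colors)
    Z = standardizer.transform(colors)
    Y = np.array([s.formula.doses() for s in samples])

    kscan = scan_k(Z, range(config.k_min, config.k_max + 1), seed=fit_seed)
    k = config.force_k if config.force_k is not None else kscan.chosen_k
    cmodel = kmeans_fit(Z, k, seed=fit_seed)
    labels = cmodel.labels

    comp_cfg = CompetitionConfig(folds=config.folds, repeats=config.repeats, seed=fit_seed)
    if config.grids is not None:
        comp_cfg.grids = config.grids
    if config.families is not None:
        comp_cfg.families = config.families

    Z_by, Y_by, tables = {}, {}, {}
    for c in range(k):
        idx = labels == c
        Z_by[c], Y_by[c] = Z[idx], Y[idx]
        tables[c] = compete(Z[idx], Y[idx], comp_cfg)
    bundle = fit_final(Z_by, Y_by, tables, comp_cfg)

    return FittedPipeline(
        standardizer=standardizer,
        cluster_model=cmodel,
        bundle=bundle,
        kscan=kscan,
        metadata={
            "n_training": len(samples),
            "seed": config.seed,
            "fit_seed": fit_seed,
            "sd_denominator": "n-1",
            "feature_space": "standardized RGB",
        },
    )


def run_predict(pipeline: FittedPipeline, queries: Sequence[GranuleSample]) -> pd.DataFrame:
    """One predicted formula row per query color (Tables are rendered at
    the 0.01 mg weighing precision; excipient fixed at 20.00 g)."""
    rows = []
    for q in queries:
        f = pipeline.predict(q.color)
        rows.append(
            {
                "sample_id": q.sample_id,
                **{col: getattr(f, col) for col in PIGMENT_COLUMNS},
                "excipient_g": f.excipient_g,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", *PIGMENT_COLUMNS, "excipient_g"])


def run_all(config: RunConfig | None = None) -> dict:
    """Full reproduction harness on synthetic data.

    Simulates a training library, fits the cluster-then-regress model,
    predicts held-out query colors, and scores (a) per-pigment dose
    recovery R^2 and (b) the round-trip color error: the predicted
    formula is pushed through the noise-free forward model and compared
    to the query color with delta E.
    """
    config = config or RunConfig()
    seeds = config.stage_seeds()
    fwd = ForwardModel(noise_sd=config.noise_sd, seed=seeds["simulate"])
    library = generate_library(fwd, n=config.n_library, design=config.design, seed=seeds["simulate"])
    pipeline = run_fit(library, config)

    queries, truths = generate_queries(fwd, n=config.n_queries, design=config.design, seed=seeds["queries"])
    predictions = run_predict(pipeline, queries)

    recovery_r2 = {}
    true_doses = np.array([t.doses() for t in truths])
    for j, col in enumerate(PIGMENT_COLUMNS):
        y = true_doses[:, j]
        recovery_r2[col] = r2(y, predictions[col].to_numpy()) if np.ptp(y) > 0 else None

    clean = ForwardModel(attenuation=fwd.attenuation, base_color=fwd.base_color, noise_sd=0.0)
    delta_es = []
    for q, (_, row) in zip(queries, predictions.iterrows()):
        pred_formula = pipeline.predict(q.color)
        rendered = forward_mix(clean, pred_formula)
        delta_es.append(delta_e(rgb_to_lab(q.color), rgb_to_lab(rendered)))
    delta_es = np.array(delta_es)

    return {
        "config": {
            "seed": config.seed,
            "n_library": config.n_library,
            "n_queries": config.n_queries,
            "noise_sd": config.noise_sd,
            "design": config.design,
        },
        "chosen_k": pipeline.cluster_model.k,
        "mean_silhouette": pipeline.cluster_model.mean_silhouette,
        "winners": {c: reg.winner for c, reg in pipeline.bundle.clusters.items()},
        "cv_table": pipeline.cv_table().to_dict("records"),
        "recovery_r2": recovery_r2,
        "round_trip": {
            "mean_delta_e": float(delta_es.mean()),
            "frac_below_6": float((delta_es < 6.0).mean()),
            "frac_le_3": float((delta_es <= 3.0).mean()),
        },
    }


# ---------------------------------------------------------------------------
# persistence


def save_model(pipeline: FittedPipeline, path: str | Path) -> None:
    """Write the fitted pipeline as a zip archive: JSON manifest,
    joblib-serialized estimators, and a 20-row probe set used to
    self-verify the archive at load time."""
    rng = np.random.default_rng(0)
    k = pipeline.cluster_model.k
    # probe colors spread across the training color range
    lo = pipeline.standardizer.inverse_transform(np.full(3, -2.0)).clip(0, 255)
    hi = pipeline.standardizer.inverse_transform(np.full(3, 2.0)).clip(0, 255)
    probes = rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi), size=(20, 3))
    Zp = pipeline.standardizer.transform(probes)
    probe_labels = assign(pipeline.cluster_model, Zp)
    probe_pred = np.vstack(
        [pipeline.bundle.predict_doses(int(c), z.reshape(1, -1))[0] for c, z in zip(probe_labels, Zp)]
    )

    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "package_version": __version__,
        "standardizer": {
            "mean": pipeline.standardizer.mean_.tolist(),
            "sd": pipeline.standardizer.sd_.tolist(),
        },
        "cluster_model": {
            **pipeline.cluster_model.to_jsonable(),
            "labels": pipeline.cluster_model.labels.tolist(),
        },
        "kscan": pipeline.kscan.to_jsonable() if pipeline.kscan else None,
        "bundle": {
            "folds": pipeline.bundle.folds,
            "repeats": pipeline.bundle.repeats,
            "seed": pipeline.bundle.seed,
            "clusters": {
                str(c): {
                    "winner": reg.winner,
                    "scores": [vars(s) for s in reg.scores],
                }
                for c, reg in pipeline.bundle.clusters.items()
            },
        },
        "metadata": pipeline.metadata,
        "probes": {
            "colors": probes.tolist(),
            "labels": probe_labels.tolist(),
            "doses": probe_pred.tolist(),
        },
    }
    estimators = {
        str(c): reg.estimators for c, reg in pipeline.bundle.clusters.items()
    }
    buf = io.BytesIO()
    joblib.dump(estimators, buf)
    with zipfile.ZipFile(Path(path), "w") as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("estimators.joblib", buf.getvalue())


def load_model(path: str | Path) -> FittedPipeline:
    """Load an archive and verify it: schema version must match and the
    stored probe set must re-predict within 1e-9."""
    try:
        with zipfile.ZipFile(Path(path)) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            estimators = joblib.load(io.BytesIO(zf.read("estimators.joblib")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as e:
        raise ValueError(f"corrupted model archive {path}: {e}") from e
    if manifest.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(
            f"model archive schema {manifest.get('schema_version')} != supported {_SCHEMA_VERSION}"
        )

    std = Standardizer(
        mean_=np.array(manifest["standardizer"]["mean"]),
        sd_=np.array(manifest["standardizer"]["sd"]),
    )
    cm = manifest["cluster_model"]
    cmodel = ClusterModel(
        k=cm["k"],
        centroids=np.array(cm["centroids"]),
        labels=np.array(cm["labels"]),
        sse=cm["sse"],
        mean_silhouette=cm["mean_silhouette"],
        seed=cm["seed"],
    )
    kscan = KScanReport(**manifest["kscan"]) if manifest.get("kscan") else None
    b = manifest["bundle"]
    clusters = {
        int(c): ClusterRegressors(
            winner=info["winner"],
            estimators=estimators[c],
            scores=[CVScore(**s) for s in info["scores"]],
        )
        for c, info in b["clusters"].items()
    }
    bundle = RegressionBundle(clusters=clusters, folds=b["folds"], repeats=b["repeats"], seed=b["seed"])
    pipeline = FittedPipeline(
        standardizer=std, cluster_model=cmodel, bundle=bundle, kscan=kscan, metadata=manifest["metadata"]
    )

    probes = np.array(manifest["probes"]["colors"])
    Zp = std.transform(probes)
    labels = assign(cmodel, Zp)
    if not np.array_equal(labels, np.array(manifest["probes"]["labels"])):
        raise ValueError("model archive failed probe verification: cluster assignments differ")
    pred = np.vstack([bundle.predict_doses(int(c), z.reshape(1, -1))[0] for c, z in zip(labels, Zp)])
    if np.max(np.abs(pred - np.array(manifest["probes"]["doses"]))) > 1e-9:
        raise ValueError("model archive failed probe verification: predictions drifted")
    return pipeline
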