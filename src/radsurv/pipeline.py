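"""End-to-end orchestration: simulate -> extract -> cluster -> select ->
evaluate -> report, with checkpointed stage outputs under one run directory.

Every artifact is traceable: the run directory holds the exact config
(YAML round-trip) and a manifest with the config hash and all seeds.
Feature extraction is the expensive stage, so each stage reads the previous
stage's files and can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cluster import cluster_association, two_way_cluster
from .features import ExtractionConfig, extract_all, feature_manifest
from .resampling import ResamplingSpec, compare_models, evaluate_three_models
from .selection import SelectionSpec, resampled_selection
from .survival import average_km, stratify_and_km
from .synthetic import CohortSpec, TextureParams, generate_cohort, load_cohort

log = logging.getLogger("radsurv")


@dataclass
class RunConfig:
    """Complete, explicit description of one pipeline run.

    Defaults are a desk-scale demo (74 phantoms, 100 selection resamples,
    50x3 outer / 10x3 inner) that completes on one CPU in well under 15
    minutes; the full-scale configuration (1000 selection resamples, 500x3
    outer / 100x3 inner) is expressed through the same spec objects.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    selection: SelectionSpec = field(
        default_factory=lambda: SelectionSpec(n_resamples=100)
    )
    resampling: ResamplingSpec = field(default_factory=ResamplingSpec)
    replication_mode: bool = False
    n_clusters: int = 4
    stages: tuple[str, ...] = (
        "simulate", "extract", "cluster", "select", "evaluate-survival",
        "evaluate-recurrence", "report",
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "texture_params" in c:
                c["texture_params"] = TextureParams(**c["texture_params"])
            for key in ("image_shape", "voxel_size_mm", "effect_sizes", "recurrence_slopes"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        if "extraction" in d:
            e = dict(d["extraction"])
            if "voxel_size_mm" in e:
                e["voxel_size_mm"] = tuple(e["voxel_size_mm"])
            d["extraction"] = ExtractionConfig(**e)
        if "selection" in d:
            d["selection"] = SelectionSpec(**d["selection"])
        if "resampling" in d:
            d["resampling"] = ResamplingSpec(**d["resampling"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple | list):
        return [_listify(v) for v in obj]
    return obj


def _tables(outdir: Path):
    features = pd.read_csv(outdir / "features.csv", index_col="patient_id")
    clinical = pd.read_csv(outdir / "cohort" / "clinical.csv", index_col="patient_id")
    survival = pd.read_csv(outdir / "cohort" / "survival.csv", index_col="patient_id")
    recurrence = pd.read_csv(outdir / "cohort" / "recurrence.csv", index_col="patient_id")
    return features, clinical, survival, recurrence


def _zscore_clean(features: pd.DataFrame) -> pd.DataFrame:
    """Drop all-NaN/constant columns, impute rare NaNs, z-score."""
    x = features.replace([np.inf, -np.inf], np.nan)
    keep = x.columns[x.notna().all() & (x.std(ddof=0) > 0)]
    x = x[keep]
    return (x - x.mean()) / x.std(ddof=0)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages, writing artifacts under ``outdir``.

    Stages not listed in ``config.stages`` are skipped; later stages then
    read the checkpointed outputs of earlier runs from ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "config_hash": config.config_hash(),
        "seeds": {
            "cohort": config.cohort.seed,
            "selection": config.selection.seed,
            "resampling": config.resampling.seed,
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logging.basicConfig(
        level=logging.INFO, format="%(levelname)s %(name)s: %(message)s"
    )

    if "simulate" in config.stages:
        log.info("simulating cohort (n=%d)", config.cohort.n_patients)
        cohort = generate_cohort(config.cohort)
        cohort.save(outdir / "cohort")

    if "extract" in config.stages:
        cohort = load_cohort(outdir / "cohort")
        log.info("extracting %d-patient feature panel", len(cohort.patients))
        rows = {}
        for p in cohort.patients:
            fv = extract_all(p.volume, p.mask, config.extraction, patient_id=p.patient_id)
            rows[p.patient_id] = fv.values
        feats = pd.DataFrame.from_dict(rows, orient="index")
        feats.index.name = "patient_id"
        feats.to_csv(outdir / "features.csv")
        (outdir / "feature_manifest.json").write_text(json.dumps(feature_manifest(), indent=2))

    if "cluster" in config.stages:
        features, clinical, *_ = _tables(outdir)
        norm = _zscore_clean(features)
        assign = two_way_cluster(norm, k_patients=config.n_clusters)
        assign.labels.to_csv(outdir / "clusters.csv")
        assoc = cluster_association(assign, clinical)
        assoc.to_csv(outdir / "cluster_association.csv")
        ordered = norm.iloc[
            [norm.index.get_loc(i) for i in assign.patient_order],
            [norm.columns.get_loc(c) for c in assign.feature_order],
        ]
        ordered.to_csv(outdir / "heatmap_matrix.csv")
        _render_heatmap(ordered, clinical.loc[ordered.index], outdir / "heatmap.png")
        log.info("cluster association:\n%s", assoc)

    if "select" in config.stages:
        features, clinical, survival, recurrence = _tables(outdir)
        spec = dataclasses.replace(
            config.selection, replication_mode=config.replication_mode
        )
        log.info("selecting survival signature (%d resamples)", spec.n_resamples)
        surv_report = resampled_selection(
            features, {"time": survival["time"], "event": survival["event"]},
            spec, endpoint="survival",
        )
        surv_report.to_json(outdir / "signature_survival.json")
        surv_report.to_csv(outdir / "signature_survival.csv")
        log.info("survival signature: %s", surv_report.final_signature)
        rec_report = resampled_selection(
            features, recurrence["recurrence"].to_numpy(), spec, endpoint="recurrence",
        )
        rec_report.to_json(outdir / "signature_recurrence.json")
        rec_report.to_csv(outdir / "signature_recurrence.csv")
        log.info("recurrence signature: %s", rec_report.final_signature)

    if "evaluate-survival" in config.stages:
        features, clinical, survival, _ = _tables(outdir)
        signature = json.loads((outdir / "signature_survival.json").read_text())["final_signature"]
        outcomes = {
            "time": survival["time"].to_numpy(),
            "event": survival["event"].to_numpy(),
        }
        results = evaluate_three_models(
            _zscore_clean(features), clinical, signature, outcomes, "cox",
            config.resampling,
        )
        _dump_results(results, outdir, "survival", outcomes)

    if "evaluate-recurrence" in config.stages:
        features, clinical, _, recurrence = _tables(outdir)
        signature = json.loads((outdir / "signature_recurrence.json").read_text())["final_signature"]
        labels = recurrence["recurrence"].to_numpy()
        results = evaluate_three_models(
            _zscore_clean(features), clinical, signature, labels, "classifier",
            config.resampling,
        )
        _dump_results(results, outdir, "recurrence", labels)

    if "report" in config.stages:
        report = {}
        for endpoint in ("survival", "recurrence"):
            path = outdir / f"metrics_{endpoint}.csv"
            if path.exists():
                dump = pd.read_csv(path)
                report[endpoint] = {
                    model: {
                        "mean": float(g["value"].mean()),
                        "sd": float(g["value"].std(ddof=1)),
                        "n": int(len(g)),
                    }
                    for model, g in dump.groupby("model")
                }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        log.info("report written: %s", json.dumps(report, indent=2))
    return outdir


def _render_heatmap(ordered: pd.DataFrame, clinical: pd.DataFrame, path: Path) -> None:
    """Clustered feature heatmap with integer-coded clinical tracks on top."""
    n_tracks = clinical.shape[1]
    fig, axes = plt.subplots(
        2, 1, figsize=(8, 6),
        gridspec_kw={"height_ratios": [n_tracks, 20]}, sharex=True,
    )
    axes[0].imshow(clinical.T.to_numpy(), aspect="auto", cmap="tab10",
                   interpolation="nearest")
    axes[0].set_yticks(range(n_tracks), clinical.columns, fontsize=6)
    axes[0].set_title("clinical tracks (integer codes)", fontsize=8)
    vmax = np.nanpercentile(np.abs(ordered.to_numpy()), 98)
    axes[1].imshow(ordered.T.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    axes[1].set_xlabel("patients (dendrogram order)")
    axes[1].set_ylabel("features (dendrogram order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _dump_results(results: dict, outdir: Path, endpoint: str, outcomes) -> None:
    rows = []
    for model, res in results.items():
        for v in res.values:
            rows.append({"model": model, "metric": res.metric_name, "value": v})
        for extra, vals in res.extra_metrics.items():
            for v in vals:
                rows.append({"model": model, "metric": extra, "value": v})
    pd.DataFrame(rows).to_csv(outdir / f"metrics_{endpoint}.csv", index=False)
    compare_models(results).to_csv(outdir / f"summary_{endpoint}.csv")
    # run log: per-fold tuned hyperparameters
    hp_rows = [
        {"model": model, "fold": i, **params}
        for model, res in results.items()
        for i, params in enumerate(res.chosen_params)
    ]
    pd.DataFrame(hp_rows).to_csv(outdir / f"hyperparameters_{endpoint}.csv", index=False)

    if endpoint == "survival":
        fig, axes = plt.subplots(1, len(results), figsize=(4 * len(results), 3.2))
        for ax, (model, res) in zip(np.atleast_1d(axes), results.items()):
            n = max(max(idx) for idx in res.fold_test_indices) + 1
            risk = res.average_patient_risk(n)
            try:
                km = stratify_and_km(risk, outcomes["time"], outcomes["event"])
            except ValueError:
                continue
            grid = np.unique(np.concatenate([km.low.times, km.high.times]))
            lo = average_km([km.low], grid)
            hi = average_km([km.high], grid)
            pd.DataFrame(
                {"time": grid, "low_risk": lo.survival, "high_risk": hi.survival}
            ).to_csv(outdir / f"km_{model}.csv", index=False)
            ax.step(lo.times, lo.survival, where="post", label="low risk")
            ax.step(hi.times, hi.survival, where="post", label="high risk")
            ax.set_title(f"{model} (log-rank p={km.logrank_p:.3g})")
            ax.set_xlabel("days")
            ax.set_ylabel("S(t)")
            ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "km_curves.png", dpi=120)
        plt.close(fig)
    else:
        for model, res in results.items():
            if not res.fold_risks:
                continue
            scores = np.concatenate(res.fold_risks)
            idx = np.concatenate(res.fold_test_indices)
            labels = np.asarray(outcomes)[idx]
            order = np.argsort(-scores, kind="stable")
            tp = np.cumsum(labels[order])
            fp = np.cumsum(1 - labels[order])
            pd.DataFrame(
                {
                    "fpr": fp / max(1, (labels == 0).sum()),
                    "tpr": tp / max(1, (labels == 1).sum()),
                    "precision": tp / np.maximum(tp + fp, 1),
                }
            ).to_csv(outdir / f"roc_pr_{model}.csv", index=False)
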