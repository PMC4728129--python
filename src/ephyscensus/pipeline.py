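"""End-to-end orchestration: simulate -> extract -> analyze -> report.

Each stage writes plain-text artifacts (CSV/JSON) into the run directory,
and a manifest records seeds, versions and per-stage shapes so a run can be
regenerated bit-identically from its config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import extract_all, step_trains
from .io import save_feature_matrix, save_recordings
from .model import CohortDesign, Condition, GroupSpec, Protocol, StageGroup
from .similarity import classical_mds, concat_step_trains, distance_matrix
from .simulate import DEFAULT_GROUP_SPECS, apply_missingness, iter_cohort
from . import stats


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Reproducible configuration of a full pipeline run."""

    # cohort design
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "s45_46:naive": 12, "s48_49:naive": 10, "s48_49:stimulated": 8})
    missing_rate: float = 0.18
    seed: int = 0
    # analysis settings
    alpha: float = 0.05
    n_components: int = 2
    n_imputations: int = 20
    n_subsamples: int = 10
    subsample_size: int = 50
    vp_cost_per_ms: float = 0.1
    out_dir: str = "run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def design(self) -> CohortDesign:
        groups = {}
        for key, n in self.group_sizes.items():
            stage, cond = key.split(":")
            gkey = (StageGroup(stage), Condition(cond))
            spec = DEFAULT_GROUP_SPECS.get(gkey, GroupSpec(n_cells=n))
            groups[gkey] = GroupSpec(n_cells=n, means=spec.means, sds=spec.sds)
        return CohortDesign(groups=groups, missing_rate=self.missing_rate,
                            seed=self.seed)


def simulate_stage(config: RunConfig, out: Path, save_traces: bool = False):
    """Generate the cohort, extract features per cell, keep step trains."""
    design = config.design()
    rows, labels, truth_rows = [], [], []
    step_train_store: dict[str, list] = {}
    sweep_len_ms = None
    recordings_store = {}
    for cell_id, params, recs in iter_cohort(design):
        feats = extract_all(recs, cell_id=cell_id)
        rows.append(feats.to_series())
        rec0 = recs[Protocol.CURRENT_STEPS]
        labels.append({"cell_id": cell_id, "stage_group": rec0.stage_group.value,
                       "condition": rec0.condition.value})
        trains = step_trains(rec0)
        order = np.argsort([s["current_pa"] for s in rec0.stimulus])
        sweep_len_ms = rec0.sweeps.shape[1] * 1000.0 / rec0.fs
        step_train_store[cell_id] = [trains[k].spike_times.tolist() for k in order]
        truth = asdict(params)
        truth["cell_id"] = cell_id
        truth_rows.append(truth)
        if save_traces:
            recordings_store[cell_id] = recs
    if not rows:
        raise PipelineError("simulate", "design produced no cells")
    matrix = pd.DataFrame(rows)
    matrix.index.name = "cell_id"
    labels = pd.DataFrame(labels).set_index("cell_id")
    matrix = apply_missingness(matrix, design.missing_rate, seed=design.seed + 1)
    save_feature_matrix(out / "features.csv", matrix, labels)
    labels.to_csv(out / "labels.csv")
    pd.DataFrame(truth_rows).set_index("cell_id").to_csv(out / "ground_truth.csv")
    (out / "step_trains.json").write_text(json.dumps(
        {"sweep_length_ms": sweep_len_ms, "trains": step_train_store}))
    if save_traces:
        save_recordings(out / "traces.h5", recordings_store)
    return matrix, labels, step_train_store, sweep_len_ms


def analyze_stage(config: RunConfig, out: Path, matrix: pd.DataFrame,
                  labels: pd.DataFrame, step_train_store=None,
                  sweep_len_ms: float | None = None) -> dict:
    artifacts: dict = {}
    # correlations + FDR
    corr = stats.pairwise_correlations(matrix)
    mask, thresh = stats.fdr_adjust(corr["p"].to_numpy(), alpha=config.alpha)
    corr["significant"] = mask
    corr.to_csv(out / "correlations.csv", index=False)
    artifacts["correlations"] = corr
    artifacts["fdr_threshold"] = thresh
    # principal variables
    cmat = matrix.corr(min_periods=3)
    shares = stats.explained_variance_single(cmat).sort_values(ascending=False)
    shares.rename("explained_share").to_csv(out / "principal_variables.csv")
    artifacts["principal_variables"] = shares
    # PCA with missing values + promax
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = stats.vbpca_fit(matrix, n_components=config.n_components)
        model = stats.promax_rotate(model)
    model.loadings.to_csv(out / "pca_loadings.csv")
    model.scores.to_csv(out / "pca_scores.csv")
    artifacts["pca"] = model
    # group comparisons on the stage groups of naive cells
    naive = labels["condition"] == Condition.NAIVE.value
    if naive.sum() >= 6 and labels.loc[naive, "stage_group"].nunique() >= 2:
        gc = stats.group_compare(matrix.loc[naive],
                                 labels.loc[naive, "stage_group"],
                                 alpha=config.alpha)
        gc.to_csv(out / "group_stats_development.csv")
        artifacts["group_stats_development"] = gc
    # naive vs stimulated contrast
    if (labels["condition"] == Condition.STIMULATED.value).sum() >= 3:
        gc2 = stats.group_compare(matrix, labels["condition"], alpha=config.alpha)
        gc2.to_csv(out / "group_stats_stimulation.csv")
        artifacts["group_stats_stimulation"] = gc2
        # projection of stimulated cells into the naive component space
        try:
            naive_model = stats.vbpca_fit(matrix.loc[naive],
                                          n_components=config.n_components)
            proj = stats.project(naive_model, matrix.loc[~naive])
            proj.to_csv(out / "projected_scores.csv")
            artifacts["projection"] = proj
        except ValueError:
            pass
    # 2D cloud sizes per group in component space
    cloud = {}
    for g, idx in labels.groupby(labels["stage_group"]).groups.items():
        pts = model.scores.loc[model.scores.index.intersection(idx)]
        if len(pts) >= 2:
            cloud[str(g)] = stats.cloud_median_distance(pts.to_numpy())
    (out / "cloud_sizes_2d.json").write_text(json.dumps(cloud, indent=1))
    artifacts["cloud_sizes_2d"] = cloud
    # VP distances + MDS of step-train outputs
    if step_train_store and len(step_train_store) >= 3 and sweep_len_ms:
        concat = {cid: concat_step_trains(
            [np.asarray(t) for t in trains], sweep_length_ms=sweep_len_ms)
            for cid, trains in step_train_store.items()}
        dm = distance_matrix(concat, q=config.vp_cost_per_ms)
        dm.to_frame().to_csv(out / "vp_distances.csv")
        coords = classical_mds(dm)
        coords.to_csv(out / "vp_mds.csv")
        artifacts["vp_distances"] = dm
        artifacts["vp_mds"] = coords
    return artifacts


def run_pipeline(config: RunConfig, save_traces: bool = False) -> dict:
    """Full run: returns the artifact dict and writes everything to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    try:
        matrix, labels, trains, sweep_ms = simulate_stage(config, out, save_traces)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", str(exc)) from exc
    try:
        artifacts = analyze_stage(config, out, matrix, labels, trains, sweep_ms)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("analyze", str(exc)) from exc
    artifacts["features"] = matrix
    artifacts["labels"] = labels
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_cells": int(matrix.shape[0]),
        "n_variables": int(matrix.shape[1]),
        "missing_fraction": float(matrix.isna().to_numpy().mean()),
        "stages": ["simulate", "extract", "analyze"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = manifest
    return artifacts


def report(artifacts: dict, top_n: int = 10) -> str:
    """Human-readable run summary: top correlations, variable ranking,
    per-group cloud sizes and significant group differences."""
    if not artifacts or "correlations" not in artifacts:
        raise ValueError("no analysis artifacts to report on")
    lines = ["# Electrophysiological census summary", ""]
    m = artifacts.get("manifest", {})
    if m:
        lines.append(f"{m['n_cells']} cells x {m['n_variables']} variables; "
                     f"{100 * m['missing_fraction']:.1f}% of observations missing.")
    corr = artifacts["correlations"]
    sig = corr[corr["significant"]].sort_values("r", key=np.abs, ascending=False)
    lines.append(f"\n## Correlations: {len(sig)} of {len(corr)} pairs significant "
                 f"after FDR (implied p threshold "
                 f"{artifacts.get('fdr_threshold', float('nan')):.2e})")
    for _, row in sig.head(top_n).iterrows():
        lines.append(f"  {row['var_a']} ~ {row['var_b']}: r = {row['r']:+.2f} "
                     f"(n = {row['n']})")
    pv = artifacts["principal_variables"]
    lines.append("\n## Principal variables (share of total variance explained)")
    for name, share in pv.head(top_n).items():
        lines.append(f"  {name}: {100 * share:.1f}%")
    model = artifacts.get("pca")
    if model is not None:
        ev = ", ".join(f"C{k + 1} {100 * v:.1f}%" for k, v in enumerate(model.explained))
        lines.append(f"\n## PCA with missing values: explained {ev}")
    cloud = artifacts.get("cloud_sizes_2d") or {}
    if cloud:
        lines.append("\n## Median pairwise 2D distance per stage group")
        for g, v in cloud.items():
            lines.append(f"  {g}: {v:.2f}")
    for key, label in (("group_stats_development", "development"),
                       ("group_stats_stimulation", "stimulation")):
        gc = artifacts.get(key)
        if gc is None or "p_anova" not in gc and "p_mw" not in gc:
            continue
        pcol = "p_anova" if "p_anova" in gc else "p_mw"
        hits = gc[gc[pcol] < 0.05].sort_values(pcol)
        lines.append(f"\n## Variables changing with {label} ({pcol} < 0.05)")
        for var, row in hits.iterrows():
            eta = row.get("eta_sq", np.nan)
            extra = f", eta^2 = {eta:.2f}" if np.isfinite(eta) else ""
            lines.append(f"  {var}: p = {row[pcol]:.2e}{extra}")
    return "\n".join(lines) + "\n"
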