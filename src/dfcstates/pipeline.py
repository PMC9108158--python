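"""End-to-end pipeline driver.

Runs the full analysis — optional cohort simulation, motion QC, sliding-
window connectivity, state clustering with optional elbow scan, strength
ordering, incomplete-subject exclusion, per-state summaries, and group
statistics — and writes every artifact as TSV/JSON into one results
directory, stamped with a hash of the configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .clustering import (
    StateModel,
    assign_windows,
    filter_incomplete_subjects,
    kmeans_l1,
    order_states,
    select_k,
    state_names,
)
from .dfc import RoiTimeSeries, WindowParams, compute_dynamic_fc
from .metrics import (
    NETWORKS,
    default_parcellation,
    global_mean_fc,
    network_mean_fc,
    occurrence_counts,
    subject_state_mean_fc,
)
from .qc import MotionTrace, framewise_displacement, motion_exclusion
from .stats import StatResult, one_way_anova, pairwise_bonferroni, partial_correlation
from .synthetic import SyntheticConfig, simulate_cohort

logger = logging.getLogger("dfcstates")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; validated before computation."""

    out_dir: str | Path
    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None  # pre-extracted time series + manifest
    window_len_volumes: int = 15
    step_volumes: int = 1
    k: int | None = None
    k_scan: tuple[int, int] | None = (2, 8)
    n_init: int = 10
    pooling: str = "per-group"  # or "pooled"
    network_mode: str = "within"
    top_fraction: float = 0.005
    covariates: tuple[str, ...] = ("age", "education_years", "fd_mean")
    max_trans_mm: float = 3.0
    max_rot_deg: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic config or input_dir required")
        if self.pooling not in ("per-group", "pooled"):
            raise ValueError("pooling must be 'per-group' or 'pooled'")
        if self.network_mode not in ("within", "to_all"):
            raise ValueError("network_mode must be 'within' or 'to_all'")
        if self.k is None and self.k_scan is None:
            raise ValueError("either a fixed k or a k_scan range is required")
        WindowParams(self.window_len_volumes, self.step_volumes)
        if self.synthetic is not None and (
            self.window_len_volumes > self.synthetic.n_volumes
        ):
            raise ValueError("window length exceeds the configured volume count")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    selected_k: dict[str, int]
    ratio_curves: dict[str, dict[int, float]]
    models: dict[str, StateModel]
    summary: pd.DataFrame
    stats: dict
    counts: dict[str, int]
    config_hash: str


def _stat_to_dict(res: StatResult) -> dict:
    return {
        "statistic": res.statistic,
        "df": list(res.df) if isinstance(res.df, tuple) else res.df,
        "p": res.p_value,
        "adjusted_p": res.adjusted_p,
        "comparison": res.comparison,
        "n": res.n,
    }


def _load_inputs(config: PipelineConfig):
    """Either simulate the cohort or read it from ``input_dir``."""
    if config.synthetic is not None:
        subjects, manifest, _truth = simulate_cohort(config.synthetic)
        parcellation = default_parcellation(config.synthetic.n_rois)
        motions: dict[str, MotionTrace] = {}
        return subjects, manifest, parcellation, motions
    input_dir = Path(config.input_dir)
    parcellation = dio.read_parcellation(input_dir / "parcellation.tsv")
    manifest = dio.read_manifest(input_dir / "manifest.tsv")
    subjects = []
    motions = {}
    for sid in manifest["subject_id"]:
        subjects.append(
            dio.read_time_series(
                input_dir / "timeseries" / f"{sid}.tsv", parcellation=parcellation
            )
        )
        motion_path = input_dir / "motion" / f"{sid}.tsv"
        if motion_path.exists():
            motions[sid] = dio.read_motion_trace(motion_path)
    return subjects, manifest, parcellation, motions


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute simulate -> QC -> dFC -> clustering -> metrics -> stats."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the analysis configuration only, so identical analyses written to
    # different directories carry the same stamp
    chash = dio.config_hash(
        {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    )
    dio.write_json({"config": config.as_dict(), "config_hash": chash},
                   out / "config.json")

    subjects, manifest, parcellation, motions = _load_inputs(config)
    dio.write_parcellation(parcellation, out / "parcellation.tsv")
    n_in = len(subjects)
    logger.info("subjects in: %d", n_in)

    # ---- motion QC ------------------------------------------------------
    kept_subjects: list[RoiTimeSeries] = []
    excluded_motion: list[str] = []
    fd_rows = []
    for ts in subjects:
        trace = motions.get(ts.subject_id)
        if trace is not None:
            if not motion_exclusion(trace, config.max_trans_mm, config.max_rot_deg):
                excluded_motion.append(ts.subject_id)
                continue
            fd_rows.append(
                {"subject_id": ts.subject_id,
                 "fd_mean": framewise_displacement(trace).mean_fd}
            )
        kept_subjects.append(ts)
    if fd_rows:
        fd_df = pd.DataFrame(fd_rows)
        manifest = manifest.drop(columns=["fd_mean"], errors="ignore").merge(
            fd_df, on="subject_id"
        )
    manifest = manifest[~manifest["subject_id"].isin(excluded_motion)]
    dio_manifest = out / "manifest.tsv"
    manifest.to_csv(dio_manifest, sep="\t", index=False)
    logger.info("excluded by motion: %d", len(excluded_motion))

    # ---- dynamic FC ------------------------------------------------------
    params = WindowParams(config.window_len_volumes, config.step_volumes)
    windowed = {ts.subject_id: compute_dynamic_fc(ts, params) for ts in kept_subjects}
    group_of = dict(zip(manifest["subject_id"], manifest["group"]))

    # ---- clustering ------------------------------------------------------
    scopes: dict[str, list[str]]
    if config.pooling == "per-group":
        scopes = {
            g: [s for s in windowed if group_of[s] == g]
            for g in manifest["group"].unique()
        }
    else:
        scopes = {"pooled": list(windowed)}

    rng = np.random.default_rng(config.seed)
    models: dict[str, StateModel] = {}
    selected_k: dict[str, int] = {}
    ratio_curves: dict[str, dict[int, float]] = {}
    for scope, sids in scopes.items():
        samples = np.vstack([windowed[s].data for s in sids])
        scope_seed = int(rng.integers(2**31 - 1))
        if config.k is not None:
            model = kmeans_l1(samples, config.k, n_init=config.n_init, seed=scope_seed)
            selected_k[scope] = config.k
            ratio_curves[scope] = {}
        else:
            scan = select_k(
                samples, config.k_scan, n_init=config.n_init, seed=scope_seed
            )
            model = scan.models[scan.best_k]
            selected_k[scope] = scan.best_k
            ratio_curves[scope] = scan.ratio_curve
        models[scope] = order_states(model)
        logger.info("scope %s: k=%d, cost=%.3f", scope, selected_k[scope], model.cost)

    k_by_scope = selected_k if config.k is None else {s: config.k for s in scopes}

    # ---- assignment and exclusion ---------------------------------------
    assignments: dict[str, np.ndarray] = {}
    scope_of: dict[str, str] = {}
    for scope, sids in scopes.items():
        for s in sids:
            assignments[s] = assign_windows(models[scope], windowed[s].data)
            scope_of[s] = scope
    kept_ids, excluded_states = filter_incomplete_subjects(
        {s: assignments[s] for s in assignments},
        max(k_by_scope.values()),
    )
    logger.info("excluded (incomplete states): %d", len(excluded_states))
    logger.info("analyzed: %d", len(kept_ids))

    assign_rows = []
    for s, labels in assignments.items():
        for w, lab in enumerate(labels):
            assign_rows.append(
                {"subject_id": s, "window_index": w, "ordered_label": int(lab)}
            )
    pd.DataFrame(assign_rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    for scope, model in models.items():
        pd.DataFrame(
            model.centroids,
            columns=[f"e{i}" for i in range(model.centroids.shape[1])],
        ).to_csv(out / f"centroids_{scope}.tsv", sep="\t", index=False)
        dio.write_json(
            {
                "scope": scope,
                "k": model.k,
                "n_init": model.n_init,
                "cost": model.cost,
                "strengths": model.strengths,
                "order": model.order,
                "pooling": config.pooling,
                "config_hash": chash,
            },
            out / f"model_{scope}.json",
        )

    # ---- per-subject per-state summaries --------------------------------
    rows = []
    for s in kept_ids:
        k = k_by_scope[scope_of[s]]
        labels = assignments[s]
        counts = occurrence_counts(labels, k)
        names = state_names(k)
        for state in range(k):
            mean_fc = subject_state_mean_fc(
                windowed[s].data, labels, state, parcellation.n_rois
            )
            row = {
                "subject_id": s,
                "group": group_of[s],
                "state": names[state],
                "state_rank": state,
                "occurrences": int(counts[state]),
                "global_mean": global_mean_fc(mean_fc),
            }
            for net in NETWORKS:
                row[f"{net.lower()}_mean"] = network_mean_fc(
                    mean_fc, parcellation, net, mode=config.network_mode
                )
            rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "state_summaries.tsv", sep="\t", index=False)

    # ---- statistics ------------------------------------------------------
    stats_report: dict = {"config_hash": chash, "anova": {}, "partial_correlation": {}}
    manifest_kept = manifest[manifest["subject_id"].isin(kept_ids)]
    groups_present = [g for g in manifest_kept["group"].unique()]
    score_col = "composite_score" if "composite_score" in manifest.columns else None

    measures = ["global_mean"] + [f"{n.lower()}_mean" for n in NETWORKS]
    for state in summary["state"].unique():
        sub = summary[summary["state"] == state]
        for measure in measures:
            by_group = [
                sub.loc[sub["group"] == g, measure].to_numpy() for g in groups_present
            ]
            if len(by_group) < 2 or any(len(v) < 2 for v in by_group):
                continue
            key = f"{state}:{measure}"
            omnibus = one_way_anova(by_group, comparison=key)
            pairs = pairwise_bonferroni(by_group, names=groups_present)
            stats_report["anova"][key] = {
                "omnibus": _stat_to_dict(omnibus),
                "pairwise": [_stat_to_dict(p) for p in pairs],
            }

    if score_col is not None:
        merged = summary.merge(
            manifest_kept[["subject_id", score_col, *config.covariates]],
            on="subject_id",
        )
        samples = {"all": tuple(groups_present)}
        for i, a in enumerate(groups_present):
            for b in groups_present[i + 1:]:
                samples[f"{a}+{b}"] = (a, b)
        for state in summary["state"].unique():
            for measure in measures:
                for label, gset in samples.items():
                    sub = merged[
                        (merged["state"] == state) & (merged["group"].isin(gset))
                    ]
                    if len(sub) <= len(config.covariates) + 2:
                        continue
                    res = partial_correlation(
                        sub[measure],
                        sub[score_col],
                        sub[list(config.covariates)],
                        comparison=f"{state}:{measure}:{label}",
                    )
                    stats_report["partial_correlation"][
                        f"{state}:{measure}:{label}"
                    ] = _stat_to_dict(res)

    counts = {
        "subjects_in": n_in,
        "excluded_motion": len(excluded_motion),
        "excluded_states": len(excluded_states),
        "analyzed": len(kept_ids),
    }
    assert counts["subjects_in"] == (
        counts["excluded_motion"] + counts["excluded_states"] + counts["analyzed"]
    )
    stats_report["counts"] = counts
    stats_report["selected_k"] = selected_k
    stats_report["ratio_curves"] = {
        s: {str(k): v for k, v in c.items()} for s, c in ratio_curves.items()
    }
    dio.write_json(stats_report, out / "stats.json")

    return PipelineResult(
        out_dir=out,
        selected_k=selected_k,
        ratio_curves=ratio_curves,
        models=models,
        summary=summary,
        stats=stats_report,
        counts=counts,
        config_hash=chash,
    )
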