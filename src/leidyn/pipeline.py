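"""End-to-end orchestration: filter/phase -> eigenvectors -> clustering ->
condition arrays -> state metrics -> permutation statistics.

The in-memory entry point is :func:`analyze_cohort`; :func:`run_pipeline`
wraps it with file I/O driven by a :class:`RunConfig` (typically loaded from
a YAML file by the CLI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import io as lio
from . import metrics as mx
from . import signal as sig
from . import states as st
from . import stats as ps

__all__ = ["RunConfig", "PipelineResult", "analyze_cohort", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31 (name hashed with seed)."""
    h = np.uint64(global_seed)
    for ch in stage.encode():
        h = (h * np.uint64(31)) + np.uint64(ch)
    return int(h % np.uint64(2**31 - 1))


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    manifest: str | None = None
    out_dir: str = "leidyn_out"
    tr: float = 0.6
    band: tuple[float, float] = sig.DEFAULT_BAND
    filter_order: int = sig.DEFAULT_ORDER
    front_trim: int = sig.DEFAULT_TRIM
    back_trim: int = sig.DEFAULT_TRIM
    k: int | None = None  # fixed k; None selects by Dunn over k_range
    k_range: tuple[int, int] = (3, 15)
    n_restarts: int = st.DEFAULT_RESTARTS
    dunn_subsample: int | None = st.DEFAULT_DUNN_SUBSAMPLE
    shift_tr: int = ev.DEFAULT_SHIFT_TR
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    transpose_bold: bool = False
    run_stats: bool = False


@dataclass
class PipelineResult:
    """All per-stage artifacts of one run, in memory."""

    model: st.ClusterModel
    dunn_table: pd.DataFrame | None
    metrics: pd.DataFrame
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _metrics_for_shift(
    recordings,
    timelines,
    model: st.ClusterModel,
    cfg: RunConfig,
    shift: int,
    warnings_acc: dict,
) -> list[pd.DataFrame]:
    tables = []
    for rec, tl in zip(recordings, timelines):
        cond = ev.events_to_condition_array(
            tl, cfg.tr, rec.n_volumes, cfg.front_trim, cfg.back_trim
        )
        warnings_acc["dropped_episodes"] += cond.n_dropped_episodes
        warnings_acc["merged_episodes"] += cond.n_merged_episodes
        if shift:
            cond = ev.shift_condition_array(cond, shift)
            warnings_acc["shift_truncations"] += int(cond.truncated_by_shift)
        states_seq = model.labels_for(rec.subject_id)
        try:
            w0, w1 = ev.analysis_window(states_seq, cond)
        except ValueError:
            warnings_acc["empty_windows"] += 1
            continue
        tables.append(
            mx.subject_condition_metrics(
                rec.subject_id,
                rec.group,
                states_seq[w0:w1],
                ev.ConditionArray(cond.labels[w0:w1], shift_applied=cond.shift_applied),
                model.k,
                cfg.tr,
                shift=shift,
            )
        )
    return tables


def analyze_cohort(recordings, timelines, cfg: RunConfig) -> PipelineResult:
    """Run the full analysis on in-memory recordings and event timelines."""
    # stage 1: phases and leading eigenvectors per subject
    eig_sets = []
    for rec in recordings:
        ph = sig.phases_for_subject(
            rec,
            low=cfg.band[0],
            high=cfg.band[1],
            order=cfg.filter_order,
            front_trim=cfg.front_trim,
            back_trim=cfg.back_trim,
        )
        eig_sets.append((rec.subject_id, st.eigenvectors_for_phases(ph.phases)))
    pooled, index = st.concatenate_eigenvectors(eig_sets)

    # stage 2: clustering into PL states
    cluster_seed = stage_seed(cfg.seed, "cluster")
    if cfg.k is not None:
        model = st.kmeans_states(
            pooled, cfg.k, n_restarts=cfg.n_restarts, seed=cluster_seed, index=index
        )
        model.dunn = st.dunn_index(
            pooled, model.labels, subsample=cfg.dunn_subsample, seed=cluster_seed
        )
        dunn_table = None
    else:
        model, dunn_table = st.select_optimal_k(
            pooled,
            range(cfg.k_range[0], cfg.k_range[1] + 1),
            n_restarts=cfg.n_restarts,
            seed=cluster_seed,
            dunn_subsample=cfg.dunn_subsample,
            index=index,
        )

    # stages 3-4: condition arrays (unshifted + hemodynamic shift) and metrics
    warnings_acc = dict(
        dropped_episodes=0, merged_episodes=0, shift_truncations=0, empty_windows=0
    )
    tables = _metrics_for_shift(recordings, timelines, model, cfg, 0, warnings_acc)
    if cfg.shift_tr:
        tables += _metrics_for_shift(
            recordings, timelines, model, cfg, cfg.shift_tr, warnings_acc
        )
    metrics = mx.assemble_metrics(tables)

    # stage 5: permutation statistics (optional; heavy)
    anova: dict[str, pd.DataFrame] = {}
    if cfg.run_stats:
        for metric, within in (
            ("switch_freq", ("condition",)),
            ("occupancy", ("condition", "state")),
            ("dwell_time", ("condition", "state")),
        ):
            sub = metrics[(metrics["metric"] == metric) & (metrics["shift"] == 0)]
            sub, n_imp = ps.impute_metric_cells(sub)
            spec = ps.AnovaSpec(
                within=within,
                n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, f"anova-{metric}"),
                alpha=cfg.alpha,
            )
            res = ps.perm_rm_anova(sub, spec)
            anova[metric] = pd.DataFrame([vars(r) for r in res]).assign(imputed=n_imp)

    report = dict(
        n_subjects=len(recordings),
        n_pooled_rows=int(pooled.shape[0]),
        retained_volumes_per_subject=[
            rec.n_volumes - cfg.front_trim - cfg.back_trim for rec in recordings
        ],
        k=model.k,
        dunn=float(model.dunn),
        seed=cfg.seed,
        cluster_seed=cluster_seed,
        warnings=warnings_acc,
    )
    return PipelineResult(
        model=model, dunn_table=dunn_table, metrics=metrics, anova=anova, report=report
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-driven run: load the manifest, analyse, write artifacts."""
    if cfg.manifest is None:
        raise ValueError("RunConfig.manifest is required for a file-driven run")
    recordings, timelines = lio.load_cohort(
        cfg.manifest, tr=cfg.tr, transpose=cfg.transpose_bold
    )
    result = analyze_cohort(recordings, timelines, cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_table(out / "metrics.tsv", result.metrics)
    centro = pd.DataFrame(
        result.model.centroids,
        index=[f"PL{i + 1}" for i in range(result.model.k)],
    )
    centro.insert(0, "state", centro.index)
    lio.write_table(out / "centroids.tsv", centro)
    if result.dunn_table is not None:
        lio.write_table(out / "dunn_by_k.tsv", result.dunn_table)
    for metric, table in result.anova.items():
        lio.write_table(out / f"anova_{metric}.tsv", table)
    pd.Series(
        {k: str(v) for k, v in result.report.items()}
    ).to_csv(out / "run_report.tsv", sep="\t", header=False)
    return result
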