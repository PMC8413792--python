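"""End-to-end pipeline: QC -> preprocess -> networks -> metrics -> statistics.

`run_pipeline` executes the whole analysis from a serialisable
`PipelineConfig` (either on SNIRF files in an input directory or on a
freshly simulated cohort) and writes the results tables, ANOVA summaries,
Delta-WD/brain-behaviour report and channel-wise contrast maps to an output
directory.  `analyze_cohort` is the in-memory core used by the command-line
driver, the analysis scripts and the tests.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
import time

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import graph_metrics as gm
from .montage import SLEEP_STATES, TASK_STATES, Recording
from .preprocess import QCReport, preprocess_recording, subject_qc
from .simulate import SimulationSpec, generate_cohort
from .snirf_io import (
    read_scores_csv, read_snirf, write_results_table, write_scores_csv,
    write_snirf,
)
from .stats import (
    CohortResults, brain_behavior_correlation, channelwise_contrast_map,
    delta_wd, dunnett_vs_rest, kendalls_w, log_transform, rm_anova,
    score_changes, shapiro_per_cell, CONTRASTS,
)


@dataclasses.dataclass
class PipelineConfig:
    """Serializable description of one full pipeline run."""

    input_dir: str | None = None       # directory of .snirf files + scores.csv
    simulate_subjects: int | None = None  # generate a cohort instead of reading
    seed: int = 0
    out_dir: str = "results"
    # preprocessing
    wavelet_enabled: bool = True
    wavelet_family: str = "db2"
    wavelet_iqr_factor: float = 1.5
    filter_order: int = 5
    filter_fc_hz: float = 0.4
    dpf: float = 6.0
    cbsi: bool = True
    # quality control
    qc_cv_threshold: float = 0.075
    qc_channel_fraction: float = 0.80
    # thresholding grids
    absolute_grid: tuple[float, ...] = conn.ABSOLUTE_GRID
    cost_grid: tuple[float, ...] = conn.COST_GRID
    surrogate_alpha: float = conn.SURROGATE_ALPHA
    # statistics
    log_epsilon: float = 1e-6
    dunnett_draws: int = 100_000

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["absolute_grid"] = list(self.absolute_grid)
        d["cost_grid"] = list(self.cost_grid)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key in ("absolute_grid", "cost_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def simulate(spec: SimulationSpec, out_dir: str | os.PathLike) -> list[str]:
    """Write a synthetic cohort to disk as SNIRF files plus a scores CSV."""
    cohort = generate_cohort(spec)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for rec in cohort.recordings:
        path = os.path.join(out_dir, f"{rec.subject_id}_{rec.sleep_state}.snirf")
        write_snirf(rec, path)
        paths.append(path)
    scores = cohort.cognitive_scores
    write_scores_csv(scores, os.path.join(out_dir, "scores.csv"))
    truth = {
        sid: {k: float(v) for k, v in d.items()}
        for sid, d in cohort.ground_truth["subjects"].items()
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as f:
        json.dump(truth, f, indent=2, sort_keys=True)
    return paths


def load_cohort(input_dir: str | os.PathLike) -> tuple[list[Recording], pd.DataFrame | None]:
    paths = sorted(glob.glob(os.path.join(input_dir, "*.snirf")))
    if not paths:
        raise FileNotFoundError(f"no .snirf files in {input_dir}")
    recordings = [read_snirf(p) for p in paths]
    scores_path = os.path.join(input_dir, "scores.csv")
    scores = read_scores_csv(scores_path) if os.path.exists(scores_path) else None
    return recordings, scores


def run_qc(recordings: list[Recording], config: PipelineConfig
           ) -> tuple[list[Recording], list[QCReport]]:
    """Exclude subjects with any session failing the CV rule."""
    reports = [
        subject_qc(rec, cv_threshold=config.qc_cv_threshold,
                   channel_fraction_threshold=config.qc_channel_fraction)
        for rec in recordings
    ]
    bad_subjects = {r.subject_id for r in reports if r.excluded}
    kept = [rec for rec in recordings if rec.subject_id not in bad_subjects]
    return kept, reports


def analyze_recording(
    rec: Recording, config: PipelineConfig
) -> tuple[list[dict], np.ndarray]:
    """All per-state network metrics of one session.

    Returns long-table rows and the (task_state, channel) local weighted
    density array from surrogate-thresholded networks.
    """
    hemo = preprocess_recording(
        rec, use_wavelet=config.wavelet_enabled, use_cbsi=config.cbsi,
        iqr_factor=config.wavelet_iqr_factor, wavelet=config.wavelet_family,
        filter_order=config.filter_order, fc_hz=config.filter_fc_hz,
        dpf={760.0: config.dpf, 850.0: config.dpf},
    )
    segments = conn.extract_segments(hemo.hbt.shape[0], rec.fs_hz, rec.events)
    rows: list[dict] = []
    local_wd = np.zeros((len(TASK_STATES), rec.montage.n_channels))
    base = {"subject": rec.subject_id, "sleep_state": rec.sleep_state}
    for t_idx, seg in enumerate(segments):
        cm = conn.pearson_matrix(
            conn.segment_signal(hemo, seg), label=seg.label,
            subject_id=rec.subject_id, sleep_state=rec.sleep_state,
        )
        cell = {**base, "task_state": seg.label}

        for tau in config.absolute_grid:
            b = conn.binarize(conn.threshold_absolute(cm, tau))
            rows.append({**cell, "scheme": "absolute", "parameter": tau,
                         "metric": "avg_degree", "value": gm.average_degree(b)})

        net_s = conn.threshold_surrogate(cm, config.surrogate_alpha)
        b_s = conn.binarize(net_s)
        rows.append({**cell, "scheme": "surrogate",
                     "parameter": config.surrogate_alpha,
                     "metric": "avg_degree", "value": gm.average_degree(b_s)})
        rows.append({**cell, "scheme": "surrogate",
                     "parameter": config.surrogate_alpha,
                     "metric": "WD", "value": gm.global_density(net_s)})
        local_wd[t_idx] = gm.local_density(net_s)

        integ = gm.cost_integrated_metrics(cm, config.cost_grid)
        rows.append({**cell, "scheme": "cost", "parameter": 0.0,
                     "metric": "C_sum", "value": integ["clustering_sum"]})
        rows.append({**cell, "scheme": "cost", "parameter": 0.0,
                     "metric": "E_sum", "value": integ["efficiency_sum"]})
    return rows, local_wd


def analyze_cohort(
    recordings: list[Recording], config: PipelineConfig
) -> tuple[CohortResults, np.ndarray, list[str]]:
    """Network metrics for every session of a QC-passed cohort.

    Returns the long results table, the local weighted densities as an array
    of shape (subject, sleep, task, channel), and the ordered subject ids.
    """
    subjects: list[str] = []
    for rec in recordings:
        if rec.subject_id not in subjects:
            subjects.append(rec.subject_id)
    n_ch = recordings[0].montage.n_channels
    local = np.full((len(subjects), 2, len(TASK_STATES), n_ch), np.nan)
    rows: list[dict] = []
    for rec in recordings:
        rec_rows, rec_local = analyze_recording(rec, config)
        rows.extend(rec_rows)
        s = subjects.index(rec.subject_id)
        local[s, SLEEP_STATES.index(rec.sleep_state)] = rec_local
    if np.isnan(local).any():
        missing = [subjects[s] for s in range(len(subjects))
                   if np.isnan(local[s]).any()]
        raise ValueError(f"subjects missing a session: {missing}")
    return CohortResults(table=pd.DataFrame(rows)), local, subjects


def surrogate_metric_table(
    recordings: list[Recording], config: PipelineConfig | None = None
) -> CohortResults:
    """Reduced metric set: surrogate-thresholded degree and strength only.

    Used by calibration and power simulations, which run many cohorts and
    only need the surrogate-scheme global metrics; skips the absolute and
    cost grids.
    """
    config = config or PipelineConfig()
    rows: list[dict] = []
    for rec in recordings:
        hemo = preprocess_recording(
            rec, use_wavelet=config.wavelet_enabled, use_cbsi=config.cbsi,
            iqr_factor=config.wavelet_iqr_factor, wavelet=config.wavelet_family,
            filter_order=config.filter_order, fc_hz=config.filter_fc_hz,
        )
        segments = conn.extract_segments(hemo.hbt.shape[0], rec.fs_hz, rec.events)
        for seg in segments:
            cm = conn.pearson_matrix(conn.segment_signal(hemo, seg))
            net = conn.threshold_surrogate(cm, config.surrogate_alpha)
            cell = {"subject": rec.subject_id, "sleep_state": rec.sleep_state,
                    "task_state": seg.label, "scheme": "surrogate",
                    "parameter": config.surrogate_alpha}
            rows.append({**cell, "metric": "avg_degree",
                         "value": gm.average_degree(conn.binarize(net))})
            rows.append({**cell, "metric": "WD",
                         "value": gm.global_density(net)})
    return CohortResults(table=pd.DataFrame(rows))


def cohort_statistics(
    results: CohortResults,
    local_wd: np.ndarray,
    scores: pd.DataFrame | None,
    config: PipelineConfig,
) -> dict:
    """The full statistical battery on one cohort's metric tables."""
    out: dict = {"anova": {}}
    logged = log_transform(results, epsilon=config.log_epsilon)

    # absolute-thresholded average node degree: threshold as a third factor
    abs_d = logged.select("absolute", "avg_degree")
    abs_d = abs_d.rename(columns={"parameter": "threshold"})
    out["anova"]["absolute_avg_degree_3way"] = rm_anova(
        abs_d, within=("sleep_state", "task_state", "threshold"))

    # surrogate-thresholded degree and connection strength: 2-way design
    for metric, name in (("avg_degree", "surrogate_avg_degree"),
                         ("WD", "surrogate_WD")):
        sel = logged.select("surrogate", metric)
        out["anova"][name] = rm_anova(sel)
        out[f"shapiro_{name}"] = shapiro_per_cell(sel)

    # cost-integrated segregation/integration summaries
    for metric, name in (("C_sum", "cost_clustering"), ("E_sum", "cost_efficiency")):
        out["anova"][name] = rm_anova(logged.select("cost", metric))

    # Dunnett post hocs vs rest on the surrogate degree, per sleep state
    sel = logged.select("surrogate", "avg_degree")
    out["dunnett"] = {
        state: dunnett_vs_rest(sel, state, n_draws=config.dunnett_draws)
        for state in SLEEP_STATES
    }

    # Delta-WD and brain-behaviour correlations (raw, untransformed scale)
    wd = results.select("surrogate", "WD")
    out["delta_wd"] = delta_wd(wd)
    if scores is not None and len(out["delta_wd"].per_subject) >= 3:
        out["brain_behavior"] = brain_behavior_correlation(
            out["delta_wd"], score_changes(scores))

    # channel-wise contrasts and between-subject concordance
    out["contrast_maps"] = {
        c: channelwise_contrast_map(local_wd, c) for c in CONTRASTS
    }
    task_minus_rest = local_wd[:, :, 1:, :].mean(axis=2) - local_wd[:, :, 0, :]
    sd_effect = task_minus_rest[:, 1, :] - task_minus_rest[:, 0, :]
    out["kendalls_w"] = kendalls_w(sd_effect)
    return out


def _anova_to_dict(res) -> dict:
    return {
        name: {
            "F": e.f, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
            "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg,
            "mauchly_w": None if not np.isfinite(e.mauchly_w) else e.mauchly_w,
            "mauchly_p": None if not np.isfinite(e.mauchly_p) else e.mauchly_p,
            "p_reported": e.p_reported,
        }
        for name, e in res.effects.items()
    }


def run_pipeline(config: PipelineConfig) -> str:
    """Execute every stage and write all artifacts to ``config.out_dir``."""
    t_start = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    with open(os.path.join(config.out_dir, "config.json"), "w") as f:
        f.write(config.to_json())

    if config.simulate_subjects is not None:
        spec = SimulationSpec(n_subjects=config.simulate_subjects,
                              seed=config.seed)
        cohort = generate_cohort(spec)
        recordings, scores = cohort.recordings, cohort.cognitive_scores
        log(f"simulated cohort of {config.simulate_subjects} subjects "
            f"(seed {config.seed})")
    elif config.input_dir is not None:
        recordings, scores = load_cohort(config.input_dir)
        log(f"loaded {len(recordings)} recordings from {config.input_dir}")
    else:
        raise ValueError("config needs input_dir or simulate_subjects")

    t0 = time.time()
    kept, qc_reports = run_qc(recordings, config)
    excluded = sorted({r.subject_id for r in qc_reports if r.excluded})
    log(f"qc: excluded subjects {excluded or 'none'} "
        f"({time.time() - t0:.1f}s)")
    pd.DataFrame([
        {"subject": r.subject_id, "sleep_state": r.sleep_state,
         "fraction_bad": r.fraction_bad, "excluded": r.excluded,
         "max_cv": float(np.max(r.per_channel_cv))}
        for r in qc_reports
    ]).to_csv(os.path.join(config.out_dir, "qc_report.tsv"),
              sep="\t", index=False)

    t0 = time.time()
    results, local_wd, subjects = analyze_cohort(kept, config)
    log(f"metrics: {len(results.table)} rows for {len(subjects)} subjects "
        f"({time.time() - t0:.1f}s)")
    write_results_table(results, os.path.join(config.out_dir, "metrics.tsv"))

    t0 = time.time()
    stats = cohort_statistics(results, local_wd, scores, config)
    log(f"statistics ({time.time() - t0:.1f}s)")

    with open(os.path.join(config.out_dir, "anova.json"), "w") as f:
        json.dump({k: _anova_to_dict(v) for k, v in stats["anova"].items()},
                  f, indent=2, sort_keys=True)
    for state, table in stats["dunnett"].items():
        table.to_csv(os.path.join(config.out_dir, f"dunnett_{state}.tsv"),
                     sep="\t", index=False)
    stats["delta_wd"].per_subject.to_csv(
        os.path.join(config.out_dir, "delta_wd.tsv"), sep="\t", index=False)
    if "brain_behavior" in stats:
        stats["brain_behavior"].to_csv(
            os.path.join(config.out_dir, "brain_behavior.tsv"),
            sep="\t", index=False)
    for name, table in stats["contrast_maps"].items():
        table.to_csv(os.path.join(config.out_dir, f"contrast_{name}.tsv"),
                     sep="\t", index=False)
    with open(os.path.join(config.out_dir, "kendalls_w.json"), "w") as f:
        json.dump({"kendalls_w": stats["kendalls_w"]}, f, indent=2)

    log(f"total {time.time() - t_start:.1f}s")
    with open(os.path.join(config.out_dir, "run.log"), "w") as f:
        f.write("\n".join(log_lines) + "\n")
    return config.out_dir
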