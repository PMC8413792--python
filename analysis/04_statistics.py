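#!/usr/bin/env python
"""Repeated-measures statistics and brain-behaviour analysis of the cohort.

Reads results/metrics.tsv and results/local_wd.tsv, log-transforms the
metrics, and runs: the two-way (sleep x task) RM-ANOVA on surrogate degree
and weighted density, the threshold-augmented three-way model on
absolute-threshold degree, the cost-integrated clustering/efficiency
ANOVAs, Dunnett post hocs against rest, the Delta-WD statistic and its
correlation with cognitive-score changes, channel-wise FDR-corrected
contrast maps, and Kendall's W concordance.  Writes anova.json, dunnett,
delta_wd, brain_behavior and contrast tables under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from fnirs_fc.montage import SLEEP_STATES, TASK_STATES
from fnirs_fc.pipeline import PipelineConfig, _anova_to_dict, cohort_statistics
from fnirs_fc.snirf_io import read_scores_csv
from fnirs_fc.stats import CohortResults

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    wide = pd.read_csv(os.path.join(BASE, "metrics.tsv"), sep="\t")
    long = wide.melt(
        id_vars=["subject", "sleep_state", "task_state", "scheme", "parameter"],
        var_name="metric", value_name="value").dropna(subset=["value"])
    results = CohortResults(table=long)
    long_wd = pd.read_csv(os.path.join(BASE, "local_wd.tsv"), sep="\t")
    subjects = list(pd.unique(long_wd["subject"]))
    n_ch = long_wd["channel"].max() + 1
    local_wd = np.zeros((len(subjects), 2, len(TASK_STATES), n_ch))
    for (sid, sleep, task), grp in long_wd.groupby(
            ["subject", "sleep_state", "task_state"]):
        local_wd[subjects.index(sid), SLEEP_STATES.index(sleep),
                 TASK_STATES.index(task)] = \
            grp.sort_values("channel")["wd_loc"].to_numpy()
    scores = read_scores_csv(os.path.join(BASE, "cohort", "scores.csv"))

    config = PipelineConfig(seed=2021)
    stats = cohort_statistics(results, local_wd, scores, config)

    with open(os.path.join(BASE, "anova.json"), "w") as f:
        json.dump({k: _anova_to_dict(v) for k, v in stats["anova"].items()},
                  f, indent=2, sort_keys=True)
    for state, table in stats["dunnett"].items():
        table.to_csv(os.path.join(BASE, f"dunnett_{state}.tsv"),
                     sep="\t", index=False, float_format="%.6g")
    stats["delta_wd"].per_subject.to_csv(
        os.path.join(BASE, "delta_wd.tsv"), sep="\t", index=False,
        float_format="%.6g")
    stats["brain_behavior"].to_csv(
        os.path.join(BASE, "brain_behavior.tsv"), sep="\t", index=False,
        float_format="%.6g")
    for name, table in stats["contrast_maps"].items():
        table.to_csv(os.path.join(BASE, f"contrast_{name}.tsv"),
                     sep="\t", index=False, float_format="%.6g")

    print("sleep x task interaction (log surrogate avg degree): "
          f"p = {stats['anova']['surrogate_avg_degree']['sleep_state*task_state'].p_reported:.4f}")
    print("sleep x task interaction (log surrogate weighted density): "
          f"p = {stats['anova']['surrogate_WD']['sleep_state*task_state'].p_reported:.4f}")
    print("task main effect (log surrogate avg degree): "
          f"p = {stats['anova']['surrogate_avg_degree']['task_state'].p_reported:.6f}")
    bb = stats["brain_behavior"].set_index("test")
    for test in bb.index:
        print(f"Delta-WD vs {test} change: r = {bb.loc[test, 'r']:+.3f}, "
              f"p = {bb.loc[test, 'p']:.4f} (n = {int(bb.loc[test, 'n'])})")
    print(f"Kendall's W (channel-wise SD effect concordance): "
          f"{stats['kendalls_w']:.4f}")
    n_sig = int((stats["contrast_maps"]["sd_effect"]["p_fdr"] < 0.05).sum())
    print(f"channels significant after FDR (SD effect): {n_sig} / {int(n_ch)}")


if __name__ == "__main__":
    main()
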