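#!/usr/bin/env python
"""Subject-level quality control of the simulated cohort.

Reads the SNIRF sessions written by 01_simulate_cohort.py, computes the
coefficient of variation of raw intensity per channel, and applies the
exclusion rule (CV > 7.5% in more than 80% of channels).  Writes
results/qc_report.tsv.  On the clean default cohort no subject should be
excluded; rerun 01 with a degraded fixture to see the rule fire.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from fnirs_fc.pipeline import load_cohort
from fnirs_fc.preprocess import subject_qc

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    recordings, _ = load_cohort(os.path.join(BASE, "cohort"))
    rows = []
    for rec in recordings:
        rep = subject_qc(rec)
        rows.append({
            "subject": rep.subject_id, "sleep_state": rep.sleep_state,
            "median_cv": float(np.median(rep.per_channel_cv)),
            "fraction_bad": rep.fraction_bad, "excluded": rep.excluded,
        })
    table = pd.DataFrame(rows)
    out = os.path.join(BASE, "qc_report.tsv")
    table.to_csv(out, sep="\t", index=False, float_format="%.4f")
    n_excl = table["excluded"].sum()
    print(table.to_string(index=False))
    print(f"\n{n_excl} session(s) excluded; report in {out}")


if __name__ == "__main__":
    main()
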