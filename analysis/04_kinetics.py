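#!/usr/bin/env python
"""Response kinetics of the pooled 70-90 dB SRAF time course.

Estimates time-to-peak, half-decay and the earliest detectable frame on
(a) a noise-free single-subject trace and (b) the noisy 6-subject average,
plus the frame-wise SRAF-vs-background significance table (paired t with
Holm adjustment over the post-stimulus frames).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from wideca.recovery import noiseless_kinetics, recovery_config
from wideca.synthetic import default_roi_set
from wideca.workflow import run_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    RESULTS.mkdir(exist_ok=True)

    rows = []
    clean = noiseless_kinetics()
    rows.append({"trace": "noiseless", "roi": "SRAF", "earliest_ms": clean.earliest_response_ms,
                 "time_to_peak_ms": clean.time_to_peak_ms, "half_decay_ms": clean.half_decay_ms,
                 "censored": clean.half_decay_censored})
    print(f"noiseless trace: time-to-peak {clean.time_to_peak_ms:.0f} ms, "
          f"half-decay {clean.half_decay_ms:.0f} ms, earliest {clean.earliest_response_ms:.0f} ms")

    res = run_study(recovery_config(1), default_roi_set())
    for roi, kin in res.kinetics.items():
        rows.append({"trace": "6-subject average", "roi": roi, "earliest_ms": kin.earliest_response_ms,
                     "time_to_peak_ms": kin.time_to_peak_ms, "half_decay_ms": kin.half_decay_ms,
                     "censored": kin.half_decay_censored})
    noisy = res.kinetics["SRAF"]
    print(f"6-subject average (seed 1): time-to-peak {noisy.time_to_peak_ms:.0f} ms, "
          f"half-decay {noisy.half_decay_ms:.0f} ms")

    pd.DataFrame(rows).to_csv(RESULTS / "kinetics.csv", index=False, float_format="%.3f")
    res.timepoint_table.to_csv(RESULTS / "timepoint_significance_seed1.csv", index=False,
                               float_format="%.6g")
    first = res.timepoint_table.loc[res.timepoint_table.significant, "frame_start_ms"]
    print(f"first significant frame starts at {first.iloc[0]:.0f} ms post-onset "
          f"(Holm-adjusted p over {len(res.timepoint_table)} frames)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
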