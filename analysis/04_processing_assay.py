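#!/usr/bin/env python
"""Substrate capture success and tail-insertion kinetics, with and without Ub4.

Simulates single-molecule substrate-processing movies at the packaged
per-encounter success probabilities, classifies every encounter with the
band state machine, and compares tail-insertion time distributions between
conditions with the Gehan-Breslow-Wilcoxon test (the published wild-type
effect: capture success doubles from 3.7% to 7.8% and the insertion time
constant drops from 1.64 to 1.39 s in the presence of K48-Ub4 chains).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import proteofret as pf
from proteofret.defaults import default_acquisition, processing_condition
from proteofret.events import SUCCESSFUL


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-events", type=int, default=2000)
    ap.add_argument("--conditions", nargs="*", default=["WT", "WT+Ub4"])
    args = ap.parse_args()

    acq = default_acquisition()
    summary, taus = {}, {}
    for i, name in enumerate(args.conditions):
        pp = processing_condition(name)
        traces = pf.simulate_processing_cohort(pp, acq=acq,
                                               n_events=args.n_events,
                                               seed=args.seed + i,
                                               condition=name)
        events = pf.extract_events(traces)
        pct, se = pf.capture_success(events)
        t = np.array([e.tau_ins for e in events if e.event_class == SUCCESSFUL])
        taus[name] = t
        summary[name] = {"capture_pct": pct, "capture_se": se,
                         "tau_ins_s": t.mean(), "tau_ins_se": t.std(ddof=1) / np.sqrt(t.size),
                         "n_events": len(events), "n_successful": t.size}
        print(f"{name:10s} capture {pct:.2f} +/- {se:.2f}%  "
              f"tau_ins {t.mean():.2f} s  ({t.size} successful / "
              f"{len(events)} encounters)")

    args.out.mkdir(parents=True, exist_ok=True)
    survival = {}
    for name, t in taus.items():
        c = pf.survival_curve(t)
        survival[name] = pd.DataFrame({"time_s": c.times,
                                       "survival": c.survival})
    if len(args.conditions) == 2:
        a, b = (taus[c] for c in args.conditions)
        stat, p = pf.gehan_breslow_wilcoxon(a, b)
        print(f"\nGehan-Breslow-Wilcoxon {args.conditions[0]} vs "
              f"{args.conditions[1]}: statistic {stat:.2f}, p = {p:.2g}")

    pf.run_report(processing=summary, survival=survival, out_dir=args.out)
    print(f"summary -> {args.out / 'processing_summary.tsv'}")


if __name__ == "__main__":
    main()
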