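#!/usr/bin/env python
"""Generate example synthetic cohorts and write them in the on-disk formats.

Produces a small conformational-dynamics cohort (with ground-truth
sidecars), one substrate-processing movie, and a triplicate FP time course,
demonstrating every input format the pipeline consumes.  Trace files are
sizeable (2000 frames each), so everything goes to scratch/ by default.
"""

import argparse
from pathlib import Path

import pandas as pd

import proteofret as pf
from proteofret.defaults import (bulk_condition, default_acquisition,
                                 default_fret_levels, dynamics_condition,
                                 processing_condition)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("scratch/cohorts"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-traces", type=int, default=20)
    args = ap.parse_args()

    acq, levels = default_acquisition(), default_fret_levels()

    for name in ("WT", "WT+Ub4"):
        cond = dynamics_condition(name)
        traces = pf.simulate_dynamics_cohort(
            cond.forward_rate(), cond.backward_rate(), args.n_traces,
            acq=acq, levels=levels, seed=args.seed, condition=name,
            ligand_conc=cond.ligand_conc)
        out = args.out / "dynamics" / name.replace("+", "_plus_")
        pf.write_traces(traces, out, ground_truth=True)
        print(f"{name}: {len(traces)} dynamics traces -> {out}")

    pp = processing_condition("WT+Ub4")
    tr = pf.simulate_processing_trace(pp, acq=acq, seed=args.seed,
                                      condition="WT+Ub4")
    out = args.out / "processing"
    pf.write_traces([tr], out, ground_truth=True)
    print(f"processing movie with {len(tr.true_events)} encounters -> {out}")

    bp = bulk_condition("GS/SspB-dReceptor")
    rows = []
    for rep in range(3):
        tc = pf.simulate_fp_timecourse(bp, seed=args.seed + rep)
        for t, v in zip(tc.time, tc.polarization):
            rows.append({"time_min": t, "value_mP": v, "well": f"A{rep + 1}"})
    fp_path = args.out / "fp_gs_substrate.tsv"
    fp_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(fp_path, sep="\t", index=False)
    print(f"FP triplicate ({len(rows)} rows) -> {fp_path}")


if __name__ == "__main__":
    main()
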