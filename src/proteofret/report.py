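"""Run-level summary report: one human-readable document plus delimited twins.

Mirrors the figure-level summaries of the experimental study: a per-condition
transition-rate table, a capture-success / tail-insertion table, and a bulk
degradation-rate table.  Sections for analyses that were not run are marked
absent rather than failing.  The report body is deterministic for a given
set of inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dwells import RateEstimate
from .pipeline import DynamicsResult

FORMAT_VERSION = 1


def run_report(
    dynamics: Sequence[DynamicsResult] | None = None,
    processing: Mapping[str, Mapping[str, float]] | None = None,
    bulk: Mapping[str, RateEstimate] | None = None,
    survival: Mapping[str, pd.DataFrame] | None = None,
    out_dir: Path | None = None,
) -> str:
    """Assemble the summary document; optionally write it and its TSV twins.

    ``processing`` maps condition -> {capture_pct, capture_se, tau_ins_s,
    tau_ins_se, n_events}; ``survival`` maps condition -> DataFrame with
    columns time_s, survival.
    """
    if dynamics is None and processing is None and bulk is None:
        raise ValueError("at least one analysis output is required")
    lines = [f"# proteofret run report (format_version: {FORMAT_VERSION})", ""]
    tables: dict[str, pd.DataFrame] = {}

    lines.append("## Conformational dynamics (s1 <-> non-s1 rates)")
    if dynamics:
        df = pd.DataFrame(
            [{"condition": r.condition,
              "k_f_s^-1": round(r.k_f.estimate, 4), "k_f_se": round(r.k_f.se, 4),
              "k_b_s^-1": round(r.k_b.estimate, 4), "k_b_se": round(r.k_b.se, 4),
              "n_traces": r.n_traces_used, "n_transitions": r.n_transitions,
              "qc_pass": r.qc_report.n_pass, "qc_fail": r.qc_report.n_fail}
             for r in dynamics])
        tables["dynamics_rates"] = df
        lines += [df.to_string(index=False), ""]
    else:
        lines += ["(absent)", ""]

    lines.append("## Substrate processing (capture success, tail insertion)")
    if processing:
        df = pd.DataFrame(
            [{"condition": c, **{k: round(v, 4) for k, v in row.items()}}
             for c, row in sorted(processing.items())])
        tables["processing_summary"] = df
        lines += [df.to_string(index=False), ""]
    else:
        lines += ["(absent)", ""]

    lines.append("## Bulk degradation (multiple-turnover rates)")
    if bulk:
        df = pd.DataFrame(
            [{"condition": c, "rate_min^-1": round(r.estimate, 4),
              "se": round(r.se, 4), "n": r.n}
             for c, r in sorted(bulk.items())])
        tables["bulk_rates"] = df
        lines += [df.to_string(index=False), ""]
    else:
        lines += ["(absent)", ""]

    body = "\n".join(lines)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.txt").write_text(body)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        if survival:
            for cond, df in survival.items():
                safe = cond.replace("/", "_")
                df.to_csv(out_dir / f"survival_{safe}.tsv", sep="\t", index=False)
    return body
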