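"""Plain-text trace file format.

One trace per file: a ``# key: value`` metadata header followed by exactly
three tab-separated columns (frame, donor, acceptor).  Floats are written
with ``repr`` so a write -> read round trip is bit-exact.  ``write_traces``
writes a directory of ``<trace_id>.tsv`` files (plus optional ground-truth
sidecars for synthetic traces); ``read_traces`` accepts a file or directory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import AcquisitionParams, IntensityTrace

FORMAT_VERSION = 1
_REQUIRED = ("format_version", "trace_id", "frame_interval_s", "condition",
             "ligand_conc_uM", "total_intensity", "noise_sd", "background",
             "donor_bleach_mean_s", "acceptor_bleach_mean_s")


class TraceParseError(ValueError):
    pass


def write_trace(trace: IntensityTrace, path: Path) -> None:
    acq = trace.acq
    meta = {
        "format_version": FORMAT_VERSION,
        "trace_id": trace.trace_id,
        "frame_interval_s": acq.frame_interval,
        "condition": trace.condition,
        "ligand_conc_uM": trace.ligand_conc,
        "total_intensity": acq.total_intensity,
        "noise_sd": acq.noise_sd,
        "background": acq.background,
        "donor_bleach_mean_s": acq.donor_bleach_mean,
        "acceptor_bleach_mean_s": acq.acceptor_bleach_mean,
    }
    lines = [f"# {k}: {v!r}" if isinstance(v, float) else f"# {k}: {v}"
             for k, v in meta.items()]
    lines.append("frame\tdonor\tacceptor")
    for i, (d, a) in enumerate(zip(trace.donor, trace.acceptor)):
        lines.append(f"{i}\t{float(d)!r}\t{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: Path) -> IntensityTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    donor: list[float] = []
    acceptor: list[float] = []
    expect_frame = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise TraceParseError(f"{path}:{lineno}: malformed header line")
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = v.strip()
            continue
        if line.startswith("frame"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TraceParseError(
                f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            frame = int(parts[0])
            donor.append(float(parts[1]))
            acceptor.append(float(parts[2]))
        except ValueError as exc:
            raise TraceParseError(f"{path}:{lineno}: {exc}") from exc
        if frame != expect_frame:
            raise TraceParseError(
                f"{path}:{lineno}: frame index {frame}, expected {expect_frame}")
        expect_frame += 1

    missing = [k for k in _REQUIRED if k not in meta]
    if missing:
        raise TraceParseError(f"{path}: missing metadata keys: {missing}")
    if not donor:
        raise TraceParseError(f"{path}: no data rows")
    acq = AcquisitionParams(
        frame_interval=float(meta["frame_interval_s"]),
        n_frames=len(donor),
        total_intensity=float(meta["total_intensity"]),
        noise_sd=float(meta["noise_sd"]),
        background=float(meta["background"]),
        donor_bleach_mean=float(meta["donor_bleach_mean_s"]),
        acceptor_bleach_mean=float(meta["acceptor_bleach_mean_s"]),
    )
    return IntensityTrace(
        donor=np.array(donor), acceptor=np.array(acceptor), acq=acq,
        condition=meta["condition"], ligand_conc=float(meta["ligand_conc_uM"]),
        trace_id=meta["trace_id"],
    )


def write_traces(traces: Sequence[IntensityTrace], out_dir: Path,
                 ground_truth: bool = False) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tr in traces:
        p = out_dir / f"{tr.trace_id}.tsv"
        write_trace(tr, p)
        paths.append(p)
        if ground_truth:
            side = {
                "trace_id": tr.trace_id,
                "donor_bleach_time": tr.donor_bleach_time,
                "acceptor_bleach_time": tr.acceptor_bleach_time,
                "true_events": tr.true_events,
            }
            if tr.true_path is not None:
                side["true_path"] = {
                    "states": tr.true_path.states,
                    "entry_times": tr.true_path.entry_times.tolist(),
                    "exit_times": tr.true_path.exit_times.tolist(),
                }
            (out_dir / f"{tr.trace_id}.truth.json").write_text(
                json.dumps(side, indent=1))
    return paths


def read_traces(path: Path) -> list[IntensityTrace]:
    path = Path(path)
    if path.is_dir():
        return [read_trace(p) for p in sorted(path.glob("*.tsv"))]
    return [read_trace(path)]
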