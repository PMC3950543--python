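"""Tabular I/O for relaxation traces and parameter files.

Each trace is one CSV with columns ``time_s, strain, stress_MPa,
measure``; a directory of traces carries a ``manifest.json`` sidecar
with per-trace metadata (sample id, donor id, strain level, seed) and,
for synthetic datasets, the generating ground truth.  Parameters are
flat JSON: hyperelastic files with keys ``mu_MPa, k_MPa, alpha``;
Prony files with ``gamma`` and ``tau_s`` lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constitutive import HyperelasticParams
from .synthetic import RelaxationDataset
from .viscoelastic import PronySeries, StressTrace

__all__ = [
    "read_traces",
    "write_traces",
    "read_hyperelastic_params",
    "write_json",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = ("time_s", "strain", "stress_MPa", "measure")


class DataError(ValueError):
    """Malformed trace data (bad header, non-monotone time, bad values)."""


def write_traces(dataset: RelaxationDataset, outdir) -> Path:
    """Write one CSV per trace plus a manifest.json; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(dataset.traces):
        sid = tr.sample_id or f"S{i:03d}"
        level = tr.strain_level if tr.strain_level is not None else float(tr.strain[0])
        fname = f"{sid}_strain{round(1000 * level):03d}.csv"
        pd.DataFrame({
            "time_s": tr.times,
            "strain": tr.strain,
            "stress_MPa": tr.stress,
            "measure": tr.measure,
        }).to_csv(outdir / fname, index=False, float_format="%.17g")
        entries.append({
            "file": fname,
            "sample_id": tr.sample_id,
            "donor_id": tr.donor_id,
            "strain_level": level,
        })
    manifest = {"seed": dataset.seed, "traces": entries}
    if dataset.population:
        manifest["truth"] = {
            s.sample_id: {"hp": s.hp.to_dict(), "prony": s.ps.to_dict(),
                          "width_mm": s.geometry.width_mm,
                          "thickness_mm": s.geometry.thickness_mm,
                          "gauge_length_mm": s.geometry.gauge_length_mm}
            for s in dataset.population
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _read_one(path: Path) -> StressTrace:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    times = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise DataError(f"{path}: line {bad[0] + 3}: non-increasing time")
    stress = df["stress_MPa"].to_numpy(dtype=float)
    neg = np.nonzero(stress < 0)[0]
    if neg.size:
        raise DataError(f"{path}: line {neg[0] + 2}: negative stress")
    measure = str(df["measure"].iloc[0]) if "measure" in df.columns else "nominal"
    return StressTrace(
        times=times,
        stress=stress,
        strain=df["strain"].to_numpy(dtype=float),
        measure=measure,
    )


def read_traces(path) -> RelaxationDataset:
    """Read a directory of trace CSVs (or a single CSV) into a dataset.

    Validates the header, strictly increasing times and non-negative
    stress, attaching file context to every error.  Metadata are taken
    from manifest.json when present; a manifest entry whose file is
    missing (or a trace absent from the manifest) is an error.
    """
    path = Path(path)
    if path.is_file():
        return RelaxationDataset(traces=[_read_one(path)])
    files = sorted(p for p in path.glob("*.csv"))
    if not files:
        raise DataError(f"no traces found in {path}")
    manifest = {}
    mpath = path / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        by_file = {e["file"]: e for e in manifest.get("traces", [])}
        orphans = sorted(set(by_file) - {p.name for p in files})
        if orphans:
            raise DataError(f"{mpath}: manifest lists missing trace file(s): {orphans}")
        extra = sorted({p.name for p in files} - set(by_file))
        if extra:
            raise DataError(f"{mpath}: trace file(s) absent from manifest: {extra}")
    else:
        by_file = {}
    traces = []
    for p in files:
        tr = _read_one(p)
        meta = by_file.get(p.name, {})
        if meta:
            tr.sample_id = meta.get("sample_id")
            tr.donor_id = meta.get("donor_id")
            tr.strain_level = meta.get("strain_level")
        else:
            tr.strain_level = float(tr.strain[0])
        traces.append(tr)
    return RelaxationDataset(traces=traces, seed=manifest.get("seed"))


def read_hyperelastic_params(path) -> HyperelasticParams:
    """Read a flat JSON parameter file with keys mu_MPa, k_MPa, alpha."""
    return HyperelasticParams.from_dict(json.loads(Path(path).read_text()))


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=float))
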