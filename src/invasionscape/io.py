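"""On-disk schemas shared across the pipeline.

Single-cell CSV (bit-exact contract): header
``cell_id,clone,dose_ng_ml,replicate,compartment,fluor_au`` with
compartment in {seeded, invaded}, UTF-8, LF line endings, '.' decimal
separator, values at full float precision.  Landscapes are two-column
TSV (z, w) with a JSON sidecar for the support mask and fit metadata;
summaries and invasiveness tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flowstats import SampleSummary
from .landscape import InvasivenessRecord, Landscape
from .synthgen import ExpressionSample

__all__ = [
    "write_cells_csv",
    "read_cells_csv",
    "write_landscape",
    "read_landscape",
    "write_summary_tsv",
    "write_invasiveness_tsv",
    "read_invasiveness_tsv",
    "read_counts_tsv",
]

CELLS_HEADER = ["cell_id", "clone", "dose_ng_ml", "replicate", "compartment", "fluor_au"]


def write_cells_csv(samples: Iterable[ExpressionSample], path) -> None:
    """Write expression samples in the single-cell CSV schema."""
    frames = []
    offset = 0
    for s in samples:
        n = len(s.values)
        frames.append(pd.DataFrame({
            "cell_id": np.arange(offset, offset + n),
            "clone": s.clone,
            "dose_ng_ml": s.dose,
            "replicate": s.replicate,
            "compartment": s.compartment,
            "fluor_au": s.values,
        }))
        offset += n
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=CELLS_HEADER))
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_cells_csv(path) -> list[ExpressionSample]:
    """Read the single-cell CSV into one sample per condition group."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CELLS_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"cells CSV is missing columns: {sorted(missing)}")
    samples = []
    keys = ["clone", "dose_ng_ml", "replicate", "compartment"]
    for (clone, dose, rep, comp), grp in df.groupby(keys, sort=True):
        samples.append(ExpressionSample(values=grp["fluor_au"].to_numpy(float),
                                        clone=str(clone), dose=float(dose),
                                        compartment=str(comp), replicate=int(rep)))
    return samples


def write_landscape(landscape: Landscape, tsv_path, meta_path=None) -> None:
    """Two-column (z, w) TSV plus a JSON sidecar with mask and metadata."""
    pd.DataFrame({"z": landscape.z_grid, "w": landscape.w}).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    if meta_path is None:
        meta_path = Path(tsv_path).with_suffix(".meta.json")
    payload = {"support_mask": landscape.support_mask.astype(int).tolist(),
               "meta": _jsonable(landscape.meta)}
    Path(meta_path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_landscape(tsv_path, meta_path=None) -> Landscape:
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    mask, meta = None, {}
    if meta_path is None:
        candidate = Path(tsv_path).with_suffix(".meta.json")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        payload = json.loads(Path(meta_path).read_text(encoding="utf-8"))
        mask = np.asarray(payload.get("support_mask"), dtype=bool)
        meta = payload.get("meta", {})
    return Landscape(df["z"].to_numpy(float), df["w"].to_numpy(float),
                     support_mask=mask, meta=meta)


def write_summary_tsv(summaries: Sequence[SampleSummary], path) -> None:
    rows = [{
        "clone": s.clone, "dose": s.dose, "compartment": s.compartment,
        "replicate": s.replicate, "n": s.n, "mfi": s.mfi, "cv": s.cv,
        "log10_mean": s.log10_mean, "log10_sd": s.log10_sd, "n_dropped": s.n_dropped,
    } for s in summaries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g", lineterminator="\n")


def write_invasiveness_tsv(records: Sequence[InvasivenessRecord], path) -> None:
    pd.DataFrame([{"dose": r.dose, "replicate": r.replicate, "v": r.v}
                  for r in records]).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g", lineterminator="\n")


def read_invasiveness_tsv(path) -> list[InvasivenessRecord]:
    df = pd.read_csv(path, sep="\t")
    return [InvasivenessRecord(dose=float(r.dose), v=float(r.v), replicate=int(r.replicate))
            for r in df.itertuples()]


def read_counts_tsv(path) -> pd.DataFrame:
    """Per-condition field counts: condition, field_index, count, seeded_n."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "field_index", "count", "seeded_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV is missing columns: {sorted(missing)}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
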