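"""Reading and writing trial tables and result bundles.

The trial table is a delimited text file with a header row and the
columns ``trial_index, combo_label, nop, ipi_ms, pw_ms, amplitude_ma,
response``; ``ipi_ms`` is empty exactly when ``nop`` is 1.  Result
bundles are hierarchical JSON with full-precision floats and a schema
version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, Trial
from .model import Stimulus

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "save_bundle", "load_bundle"]

COLUMNS = (
    "trial_index",
    "combo_label",
    "nop",
    "ipi_ms",
    "pw_ms",
    "amplitude_ma",
    "response",
)

SCHEMA_VERSION = 1


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as a trial table (CSV); round-trips losslessly."""
    rows = []
    for t in dataset:
        s = t.stimulus
        rows.append(
            {
                "trial_index": t.index,
                "combo_label": s.combo_label,
                "nop": s.NoP,
                "ipi_ms": "" if s.IPI is None else repr(s.IPI),
                "pw_ms": repr(s.PW),
                "amplitude_ma": repr(s.A),
                "response": t.response,
            }
        )
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)


def read_dataset(path, design_label: str | None = None) -> Dataset:
    """Read and validate a trial table.

    Malformed rows raise with the 1-based file line number (the header is
    line 1); inconsistent temporal properties within one combination
    raise naming the combination label.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    trials = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            nop = int(row.nop)
            ipi_raw = row.ipi_ms.strip()
            ipi = None if ipi_raw == "" else float(ipi_raw)
            if nop == 1 and ipi is not None:
                raise ValueError("ipi_ms must be empty when nop = 1")
            response = int(row.response)
            if response not in (0, 1):
                raise ValueError(f"response must be 0 or 1, got {row.response}")
            stim = Stimulus(
                A=float(row.amplitude_ma),
                NoP=nop,
                IPI=ipi,
                PW=float(row.pw_ms),
                combo_label=row.combo_label,
            )
            trials.append(Trial(stim, response, index=int(row.trial_index)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    if design_label is None:
        design_label = path.stem
    return Dataset(tuple(trials), design_label=design_label)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if isinstance(obj, float):
        return obj
    return str(obj)


def save_bundle(bundle: dict, path) -> None:
    """Serialise a result bundle as schema-versioned JSON.

    Floats are written with ``repr`` precision (17 significant digits).
    """
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_jsonify(bundle))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_bundle(path) -> dict:
    return json.loads(Path(path).read_text())
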