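"""Reading and writing the package's file formats.

Measurements are whitespace-delimited text with three numeric columns
``time  Rab5  Rab7`` (lines starting with ``#`` are comments).  On read, the
time axis may be shifted by a constant so that the data aligns with the
conventions of earlier studies of the same measurements (default shift
828.56 s).  Catalogs, rankings and summaries are plain CSV; run metadata is
JSON.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .criteria import SWITCH_WINDOW, Dataset
from .errors import ParseError
from .model_space import SLOTS, ModelStructure, complexity
from .ode_sim import Trajectory

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_trajectory",
    "write_catalog",
    "read_annotation",
    "write_run_metadata",
    "DEFAULT_TIME_SHIFT",
]

#: constant added to measurement times on read, aligning the recorded time
#: axis (switch at 0) with the simulation clock used in earlier studies
DEFAULT_TIME_SHIFT = 828.56


def read_measurements(
    path,
    *,
    time_shift: float = 0.0,
    columns: Sequence[int] = (0, 1, 2),
    persistence_window: float = SWITCH_WINDOW,
    t_s: float | None = None,
) -> Dataset:
    """Parse a space-delimited measurement file into a Dataset.

    ``columns`` maps (time, Rab5, Rab7) onto file column indices.  Parse
    problems raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    times, rab5, rab7 = [], [], []
    needed = max(columns) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cells = stripped.split()
            if len(cells) < needed:
                raise ParseError(
                    path, lineno, f"expected at least {needed} columns, found {len(cells)}"
                )
            try:
                row = [float(cells[c]) for c in columns]
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric cell: {exc}") from None
            times.append(row[0])
            rab5.append(row[1])
            rab7.append(row[2])
    if not times:
        raise ParseError(path, 0, "file contains no data rows")
    times = np.asarray(times) + time_shift
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise ParseError(path, bad, "time column is not strictly increasing")
    return Dataset.from_arrays(
        times, rab5, rab7, t_s=t_s, persistence_window=persistence_window
    )


def write_measurements(path, dataset: Dataset, *, header: bool = True) -> None:
    """Write a dataset in the same space-delimited dialect the reader accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("# t Rab5 Rab7\n")
        for t, a, b in zip(dataset.times, dataset.rab5, dataset.rab7):
            fh.write(f"{t:.10g} {a:.10g} {b:.10g}\n")


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Export a trajectory as CSV (t, hidden states, observed outputs)."""
    trajectory.to_frame().to_csv(path, index=False, float_format="%.6g")


def write_catalog(path, structures: Sequence[ModelStructure]) -> None:
    """Write the structure catalog CSV (one row per candidate)."""
    import pandas as pd

    rows = []
    for s in structures:
        rows.append(
            {
                "structure_id": s.index,
                "label": s.label,
                **{slot: s.slot_choice_name(slot) for slot in SLOTS},
                "C": complexity(s),
                "n_parameters": s.n_parameters,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotation(path) -> dict[int, str]:
    """Read a two-column CSV (structure_id, label) into a mapping."""
    import pandas as pd

    df = pd.read_csv(path)
    id_col, label_col = df.columns[:2]
    return {int(i): str(l) for i, l in zip(df[id_col], df[label_col])}


def write_run_metadata(path, config: Mapping) -> None:
    """Record everything needed to reproduce a run (config, seeds, versions)."""
    import rabswitch

    meta = {
        "config": {k: _jsonable(v) for k, v in config.items()},
        "versions": {
            "rabswitch": rabswitch.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
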