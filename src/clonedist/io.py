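"""Reading clone-count tables and writing distributions with provenance.

CSV (or TSV) is the interchange format: count tables have a ``size,count``
header; distribution outputs are two-column ``support,probability`` tables
preceded by a single ``#``-prefixed JSON provenance header carrying the
parameters, package version and seed of the run.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence, Tuple, Union

from .fate_estimation import CloneSizeCounts

__all__ = ["read_counts_table", "write_distribution", "read_distribution"]

PathLike = Union[str, Path]


def read_counts_table(path: PathLike) -> CloneSizeCounts:
    """Read a ``size,count`` table (comma or tab delimited, header required).

    Duplicate sizes are summed with a warning; malformed, non-integer or
    negative entries raise with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty counts table")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.reader(lines, delimiter=delimiter)
    header = [h.strip().lower() for h in next(reader)]
    if header[:2] != ["size", "count"]:
        raise ValueError(f"{path}: expected header 'size,count', got {header}")
    counts: Dict[int, int] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {row}")
        try:
            size = int(row[0])
            count = int(row[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer entry in {row}") from exc
        if size < 2 or count < 0:
            raise ValueError(
                f"{path}:{lineno}: sizes must be >= 2 and counts >= 0, got {row}"
            )
        if size in counts:
            warnings.warn(f"{path}:{lineno}: duplicate size {size}; counts summed")
        counts[size] = counts.get(size, 0) + count
    if not counts:
        raise ValueError(f"{path}: no data rows")
    return CloneSizeCounts(counts=counts)


def _provenance(params: Optional[Mapping[str, Any]]) -> Dict[str, Any]:
    from . import __version__

    header = {"package": "clonedist", "version": __version__}
    if params:
        header.update(params)
    return header


def write_distribution(
    support: Sequence[Any],
    probs: Sequence[Any],
    path: PathLike,
    fmt: str = "csv",
    params: Optional[Mapping[str, Any]] = None,
    normalization_tol: float = 1e-9,
) -> None:
    """Write a (support, probability) table with a JSON provenance header.

    Refuses to write a vector whose mass deviates from 1 by more than
    ``normalization_tol`` (distributions are always written normalized).
    """
    if len(support) != len(probs):
        raise ValueError("support and probs must have equal length")
    total = float(sum(float(p) for p in probs))
    if abs(total - 1.0) > normalization_tol:
        raise ValueError(f"refusing to write unnormalized distribution (mass {total})")
    path = Path(path)
    header = _provenance(params)
    if fmt == "json":
        payload = {
            "params": header,
            "support": [int(s) for s in support],
            "probs": [float(p) for p in probs],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"fmt must be csv, tsv or json, got {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    rows = [f"{int(s)}{sep}{float(p)!r}" for s, p in zip(support, probs)]
    body = f"# {json.dumps(header)}\n" + f"support{sep}probability\n" + "\n".join(rows)
    path.write_text(body + "\n")


def read_distribution(path: PathLike) -> Tuple[list, list, Dict[str, Any]]:
    """Read back a distribution written by :func:`write_distribution` (CSV/TSV)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    params: Dict[str, Any] = {}
    if lines and lines[0].startswith("#"):
        params = json.loads(lines[0].lstrip("# "))
        lines = lines[1:]
    sep = "\t" if "\t" in lines[0] else ","
    support, probs = [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        s, p = ln.split(sep)
        support.append(int(s))
        probs.append(float(p))
    return support, probs, params
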