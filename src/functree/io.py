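"""Readers and writers for labeled curve collections.

Two plain-text layouts are supported:

* the UCR/UEA ``.ts`` format — header lines starting with ``@``, then a
  ``@data`` section with one series per line, values comma-separated and the
  class label after a ``:``;
* label-first delimited text (the ECG200/ECG5000 layout) — one row per
  series, the first column holding the class label and the remaining T
  columns the signal values, separated by whitespace (``tsv``) or commas
  (``csv``).

Both assume every series is observed on the same, equally long grid; the
grid is taken as 0..T−1 since neither format carries timestamps for the
equal-length case.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .curves import CurveSet

__all__ = ["read_curves", "write_curves"]

log = logging.getLogger(__name__)

_FORMATS = ("ts", "tsv", "csv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in _FORMATS else "tsv"


def read_curves(path, format: str | None = None) -> CurveSet:
    """Read a :class:`CurveSet` from ``path``.

    ``format`` is one of ``ts``, ``tsv``, ``csv``; inferred from the file
    suffix when omitted.  All series must have the same length (a common
    grid is assumed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    text = path.read_text()
    if fmt == "ts":
        curves = _parse_ts(text, str(path))
    else:
        curves = _parse_delimited(text, str(path), delimiter="," if fmt == "csv" else None)
    counts = {}
    if curves.labels is not None:
        cls, n = np.unique(curves.labels, return_counts=True)
        counts = dict(zip(cls.tolist(), n.tolist()))
    log.info(
        "read %d curves of length %d from %s (classes: %s)",
        curves.n_curves, curves.n_points, path, counts,
    )
    return curves


def _parse_float(token: str, where: str):
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric value {token!r} at {where}") from None


def _parse_ts(text: str, name: str) -> CurveSet:
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            if line.lower().startswith("@data"):
                in_data = True
            continue
        if not in_data:
            raise ValueError(f"{name}:{lineno}: data before the @data marker")
        if ":" in line:
            series_part, label = line.rsplit(":", 1)
            labels.append(label.strip())
        else:
            series_part = line
        rows.append(
            [_parse_float(tok, f"{name}:{lineno}") for tok in series_part.split(",")]
        )
    return _assemble(rows, labels, name)


def _parse_delimited(text: str, name: str, delimiter: str | None) -> CurveSet:
    rows: list[list[float]] = []
    labels: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split(delimiter)
        if len(tokens) < 2:
            raise ValueError(f"{name}:{lineno}: expected a label and at least one value")
        labels.append(tokens[0])
        rows.append(
            [
                _parse_float(tok, f"{name}:{lineno} column {j + 2}")
                for j, tok in enumerate(tokens[1:])
            ]
        )
    return _assemble(rows, labels, name)


def _assemble(rows, labels, name: str) -> CurveSet:
    if not rows:
        raise ValueError(f"{name}: empty file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(
            f"{name}: unequal lengths {sorted(lengths)}; all series must share a grid"
        )
    values = np.asarray(rows, dtype=float)
    grid = np.arange(values.shape[1], dtype=float)
    lab = np.asarray(labels) if labels else None
    if lab is not None and lab.shape[0] != values.shape[0]:
        lab = None
    return CurveSet(grid, values, lab)


def _fmt(v: float) -> str:
    return repr(float(v))


def write_curves(curves: CurveSet, path, format: str | None = None) -> None:
    """Write ``curves`` to ``path`` in one of the supported layouts.

    Values are written with full float precision so a read-back round-trip
    is exact.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    labels = curves.labels
    lines: list[str] = []
    if fmt == "ts":
        lines.append("@problemName functree_export")
        lines.append("@timeStamps false")
        lines.append("@univariate true")
        lines.append("@equalLength true")
        lines.append(f"@seriesLength {curves.n_points}")
        if labels is not None:
            lines.append("@classLabel true " + " ".join(np.unique(labels)))
        else:
            lines.append("@classLabel false")
        lines.append("@data")
        for i in range(curves.n_curves):
            row = ",".join(_fmt(v) for v in curves.values[i])
            if labels is not None:
                row += f":{labels[i]}"
            lines.append(row)
    else:
        sep = "," if fmt == "csv" else "\t"
        for i in range(curves.n_curves):
            label = labels[i] if labels is not None else "?"
            lines.append(sep.join([str(label)] + [_fmt(v) for v in curves.values[i]]))
    path.write_text("\n".join(lines) + "\n")
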