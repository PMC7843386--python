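"""Reading, validating and writing single-case experimental design (SCED) data.

A two-phase SCED series is a single subject's outcome measured at consecutive
integer time points 1..n, split into a baseline phase (A) and an intervention
phase (B).  The *design change-point* is the first time point of the
intervention phase; both phases must contain at least three observations so
that a statistical pattern can be discerned in each.

Input files are plain CSV with columns ``time,value[,phase]``; comma
separator, dot decimal, UTF-8.  Missing or irregular time points are rejected
rather than imputed because the AR(1) likelihood downstream assumes equally
spaced observations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SCEDSeries",
    "ResultBundle",
    "SCEDError",
    "SCEDParseError",
    "SCEDFormatError",
    "SCEDValidationError",
    "load_series",
    "save_series",
    "write_results",
    "settings_hash",
    "MIN_PHASE_LENGTH",
]

#: Minimum observations per phase (WWC-style rule; also the change-point
#: prior support boundary).
MIN_PHASE_LENGTH = 3


class SCEDError(ValueError):
    """Base class for SCED input errors."""


class SCEDParseError(SCEDError):
    """A value in the input file could not be parsed as a number."""


class SCEDFormatError(SCEDError):
    """The file layout (columns, phase blocks) is invalid."""


class SCEDValidationError(SCEDError):
    """The series violates a structural invariant (length, phase sizes ...)."""


@dataclass(frozen=True)
class SCEDSeries:
    """A validated single-subject two-phase outcome series.

    Parameters
    ----------
    values
        Outcome values y_1..y_n in outcome units, one per time point.
    design_cp
        1-based index of the FIRST intervention-phase observation, so the
        baseline occupies time points ``1 .. design_cp - 1``.
    label
        Free-text identifier carried through to result files.
    times
        Optional explicit time index; must be the consecutive integers
        ``1..n`` (anything else is rejected).
    """

    values: np.ndarray
    design_cp: int
    label: str = ""
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise SCEDValidationError("values must be one-dimensional")
        n = v.size
        if n < 2 * MIN_PHASE_LENGTH:
            raise SCEDValidationError(
                f"series has {n} observations; at least {2 * MIN_PHASE_LENGTH} "
                f"are required ({MIN_PHASE_LENGTH} per phase)"
            )
        if not np.all(np.isfinite(v)):
            raise SCEDValidationError("all outcome values must be finite")
        t = self.times
        if t is None:
            t = np.arange(1, n + 1)
        else:
            t = np.asarray(t)
            if t.shape != (n,) or not np.array_equal(t, np.arange(1, n + 1)):
                raise SCEDValidationError(
                    "times must be the consecutive integers 1..n "
                    "(gaps or irregular spacing are not supported)"
                )
        cp = int(self.design_cp)
        if not (MIN_PHASE_LENGTH + 1 <= cp <= n - MIN_PHASE_LENGTH + 1):
            raise SCEDValidationError(
                f"design_cp={cp} leaves fewer than {MIN_PHASE_LENGTH} "
                f"observations in a phase (valid range: "
                f"{MIN_PHASE_LENGTH + 1}..{n - MIN_PHASE_LENGTH + 1})"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t.astype(int))
        object.__setattr__(self, "design_cp", cp)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_baseline(self) -> int:
        return self.design_cp - 1

    @property
    def n_intervention(self) -> int:
        return self.n - self.design_cp + 1

    def baseline(self) -> np.ndarray:
        return self.values[: self.design_cp - 1]

    def intervention(self) -> np.ndarray:
        return self.values[self.design_cp - 1 :]

    def phase_labels(self) -> np.ndarray:
        """Return 'A'/'B' labels per time point (design partition)."""
        return np.where(self.times < self.design_cp, "A", "B")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "value": self.values, "phase": self.phase_labels()}
        )


def load_series(
    path: str | Path, design_cp: int | None = None, label: str | None = None
) -> SCEDSeries:
    """Read a ``time,value[,phase]`` CSV into a validated :class:`SCEDSeries`.

    The design change-point is taken from ``design_cp`` or derived from a
    ``phase`` column (exactly two distinct labels in contiguous blocks; the
    change-point is the first index of the second block).  When both are
    available they must agree.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # malformed CSV
        raise SCEDFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("time", "value"):
        if col not in df.columns:
            raise SCEDFormatError(f"{path}: required column {col!r} missing")
    try:
        values = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
        times = pd.to_numeric(df["time"], errors="raise").to_numpy()
    except (ValueError, TypeError) as exc:
        raise SCEDParseError(f"{path}: non-numeric entry: {exc}") from exc

    derived_cp: int | None = None
    if "phase" in df.columns:
        phase = df["phase"].astype(str).str.strip().to_numpy()
        labels = list(dict.fromkeys(phase))  # order of first appearance
        if len(labels) != 2:
            raise SCEDFormatError(
                f"{path}: phase column must contain exactly two distinct "
                f"labels, found {labels}"
            )
        changes = np.flatnonzero(phase[1:] != phase[:-1])
        if changes.size != 1:
            raise SCEDFormatError(
                f"{path}: phase labels must form two contiguous blocks"
            )
        derived_cp = int(changes[0]) + 2  # 1-based first index of second block

    if design_cp is None and derived_cp is None:
        raise SCEDFormatError(
            f"{path}: no phase column and no design change-point supplied"
        )
    if design_cp is not None and derived_cp is not None and int(design_cp) != derived_cp:
        raise SCEDFormatError(
            f"{path}: supplied design_cp={design_cp} disagrees with the phase "
            f"column (first intervention point {derived_cp})"
        )
    cp = int(design_cp) if design_cp is not None else int(derived_cp)  # type: ignore[arg-type]
    return SCEDSeries(
        values=values,
        design_cp=cp,
        label=label if label is not None else path.stem,
        times=times,
    )


def save_series(series: SCEDSeries, path: str | Path) -> None:
    """Write a series back to ``time,value,phase`` CSV (full float precision)."""
    series.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result bundles


@dataclass
class ResultBundle:
    """Flat, method-agnostic summary rows plus provenance.

    Each row is a mapping with at least ``parameter`` and ``estimate``;
    optional ``lower``/``upper`` interval bounds and extra named columns
    (e.g. Monte-Carlo p-values) are carried through verbatim.
    """

    series_label: str
    method: str  # "bucp" | "sma"
    rows: list[dict[str, Any]] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("bucp", "sma"):
            raise ValueError(f"unknown method tag {self.method!r}")

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("empty result bundle")
        for row in self.rows:
            if "parameter" not in row or "estimate" not in row:
                raise ValueError(f"result row missing parameter/estimate: {row}")
            lo, hi = row.get("lower"), row.get("upper")
            if lo is not None and hi is not None and not (lo <= hi):
                raise ValueError(f"interval bounds out of order in row {row}")


def _fmt(x: Any) -> Any:
    """Fixed 6-significant-digit float formatting for bit-stable output."""
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.6g}")
    return x


def write_results(bundle: ResultBundle, path: str | Path) -> tuple[Path, Path]:
    """Write a bundle as a flat CSV plus a JSON mirror.

    ``path`` may carry a ``.csv``/``.json`` suffix or none; both files are
    written next to each other with the same stem.  Output is bit-identical
    for identical bundles (floats rendered at 6 significant digits).
    """
    bundle.validate()
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)

    rows = [{k: _fmt(v) for k, v in row.items()} for row in bundle.rows]
    columns = ["parameter", "estimate", "lower", "upper"]
    for row in rows:
        for k in row:
            if k not in columns:
                columns.append(k)
    frame = pd.DataFrame(rows).reindex(columns=columns)
    csv_path = base.with_suffix(".csv")
    frame.to_csv(csv_path, index=False)

    payload = {
        "series_label": bundle.series_label,
        "method": bundle.method,
        "provenance": {k: _fmt(v) for k, v in bundle.provenance.items()},
        "rows": rows,
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def settings_hash(*objects: Any) -> str:
    """Stable short hash of configuration objects, for provenance records."""

    def convert(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    blob = json.dumps([convert(o) for o in objects], sort_keys=True, default=convert)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
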