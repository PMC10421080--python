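"""Reading and writing aligned LC-MS feature tables and hit tables.

Feature tables arrive as CSV exports from peak-picking software; this module
maps configurable column dialects onto the package's canonical peak frame
(``peak_id``, ``mz``, ``rt``, ``intensity``; RT in minutes). Real exports
carry footer rows, blanks and non-numeric cells, so parsing drops invalid
rows and reports them rather than failing. Raw spectra (mzML) are upstream
of this package and are never parsed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pair_finder import HitTable

__all__ = [
    "DIALECTS",
    "EmptyTableError",
    "Peak",
    "PeakTable",
    "HIT_COLUMNS",
    "read_peak_table",
    "write_peak_table",
    "read_hit_table",
    "write_hit_table",
]

PEAK_COLUMNS = ["peak_id", "mz", "rt", "intensity"]

#: Column maps per dialect: canonical name -> source header. ``peak_id`` may
#: be None, in which case the row position becomes the id. The MS-DIAL map
#: targets the alignment-export headers of ver. 4.x; headers drift across
#: versions, so a custom map can always be passed instead.
DIALECTS: dict[str, dict[str, str | None]] = {
    "generic": {"peak_id": None, "mz": "mz", "rt": "rt", "intensity": "intensity"},
    "msdial": {
        "peak_id": "Alignment ID",
        "mz": "Average Mz",
        "rt": "Average Rt(min)",
        "intensity": "Height",
    },
}

ROLES = ("pre_binding", "post_binding", "other")


class EmptyTableError(ValueError):
    """A feature table contained no valid peak rows after filtering."""


@dataclass(frozen=True)
class Peak:
    """One aligned LC-MS feature."""

    peak_id: int | str
    mz: float
    rt: float
    intensity: float


@dataclass
class PeakTable:
    """An aligned feature table for one sample.

    ``peaks`` holds one row per feature with columns ``peak_id, mz, rt,
    intensity`` (RT in minutes). ``provenance`` records where the table came
    from and how many rows were dropped on load.
    """

    sample_label: str
    role: str = "other"
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLUMNS))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peaks frame missing columns {missing}")
        if self.peaks["peak_id"].duplicated().any():
            raise ValueError("peak_ids must be unique within a table")

    def __len__(self) -> int:
        return len(self.peaks)


def _resolve_columns(header: list[str], colmap: dict[str, str | None]) -> dict[str, str | None]:
    """Match a column map against a CSV header, case/space-insensitively."""
    lookup = {h.strip().lower(): h for h in header}
    resolved: dict[str, str | None] = {}
    missing = []
    for canon in PEAK_COLUMNS:
        src = colmap.get(canon)
        if src is None:
            resolved[canon] = None
            if canon != "peak_id":
                missing.append(canon)
            continue
        actual = lookup.get(src.strip().lower())
        if actual is None:
            if canon == "peak_id":
                resolved[canon] = None
            else:
                missing.append(src)
        else:
            resolved[canon] = actual
    if missing:
        raise ValueError(f"required column(s) {missing} absent from header {header}")
    return resolved


def read_peak_table(path: str | Path, dialect: str | dict[str, str | None] = "generic",
                    role: str = "other", sample_label: str | None = None) -> PeakTable:
    """Read a CSV feature table into a :class:`PeakTable`.

    ``dialect`` is either a key of :data:`DIALECTS` or a custom column map
    ``{"mz": ..., "rt": ..., "intensity": ..., "peak_id": ...}``. Rows whose
    m/z, RT or intensity is missing, non-numeric, or violates the peak
    invariants (mz > 0, rt >= 0, intensity >= 0) are dropped and counted in
    ``provenance``. A table with no valid rows raises
    :class:`EmptyTableError`.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)} "
                "(or pass a column map)"
            ) from None
        dialect_name = dialect
    else:
        colmap = dict(dialect)
        dialect_name = "custom"

    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except OSError as exc:
        raise OSError(f"cannot read peak table {path}: {exc}") from exc

    resolved = _resolve_columns(list(raw.columns), colmap)

    out = pd.DataFrame(index=raw.index)
    for canon in ("mz", "rt", "intensity"):
        out[canon] = pd.to_numeric(raw[resolved[canon]], errors="coerce")
    valid = (
        out["mz"].notna() & out["rt"].notna() & out["intensity"].notna()
        & (out["mz"] > 0) & (out["rt"] >= 0) & (out["intensity"] >= 0)
    )
    n_total = len(raw)
    n_dropped = int((~valid).sum())
    out = out[valid]

    if resolved["peak_id"] is not None:
        ids: pd.Series = raw.loc[out.index, resolved["peak_id"]]
        peak_ids = ids.astype(str).values
    else:
        peak_ids = out.index.to_numpy()
    frame = pd.DataFrame({
        "peak_id": peak_ids,
        "mz": out["mz"].to_numpy(float),
        "rt": out["rt"].to_numpy(float),
        "intensity": out["intensity"].to_numpy(float),
    }).reset_index(drop=True)

    if frame.empty:
        raise EmptyTableError(
            f"{path}: no valid peak rows remain ({n_dropped} of {n_total} dropped)"
        )

    return PeakTable(
        sample_label=sample_label if sample_label is not None else path.stem,
        role=role,
        peaks=frame,
        provenance={
            "source": str(path),
            "dialect": dialect_name,
            "rows_total": n_total,
            "rows_kept": len(frame),
            "rows_dropped": n_dropped,
        },
    )


def write_peak_table(table: PeakTable, path: str | Path,
                     dialect: str | dict[str, str | None] = "generic") -> Path:
    """Write a :class:`PeakTable` as CSV in the given dialect."""
    path = Path(path)
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}") from None
    else:
        colmap = dict(dialect)
    out = pd.DataFrame()
    for canon in PEAK_COLUMNS:
        src = colmap.get(canon)
        if src is not None:
            out[src] = table.peaks[canon].values
        elif canon != "peak_id":
            out[canon] = table.peaks[canon].values
    out.to_csv(path, index=False)
    return path


#: Hit-table CSV schema: m/z, RT and intensity of both peaks of each pair,
#: the pair quality metrics, and the inferred untagged parent m/z.
HIT_COLUMNS = [
    "light_id", "heavy_id", "n_tags",
    "light_mz", "heavy_mz", "light_rt", "heavy_rt",
    "light_intensity", "heavy_intensity",
    "ppm_error", "rt_delta", "intensity_rel_diff",
    "inferred_parent_mz",
]


def write_hit_table(hits: "HitTable | pd.DataFrame", path: str | Path) -> Path:
    """Write a hit table as CSV (header-only when there are no hits)."""
    path = Path(path)
    frame = hits if isinstance(hits, pd.DataFrame) else hits.hits
    try:
        frame.loc[:, HIT_COLUMNS].to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise OSError(f"cannot write hit table {path}: {exc}") from exc
    return path


def read_hit_table(path: str | Path, sample_label: str = "",
                   role: str = "other") -> "HitTable":
    """Read a hit table CSV written by :func:`write_hit_table`."""
    from .pair_finder import HitTable  # deferred: avoids an import cycle

    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in HIT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing column(s) {missing}")
    frame = frame.loc[:, HIT_COLUMNS]
    for col in ("light_id", "heavy_id"):
        frame[col] = frame[col].astype(str)
    return HitTable(sample_label=sample_label or path.stem, role=role,
                    policy=None, hits=frame)
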