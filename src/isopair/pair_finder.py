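"""Detection of light/heavy isotopologue twin peaks in one feature table.

A compound carrying ``n`` tags appears as two co-eluting ions split by
``n x pair_delta / z`` m/z (~3.0101 for one propanoyl tag at charge 1) with
near 1:1 intensity, because the extract was acylated with an equimolar
light/heavy acid mixture. The detector shifts the table by the expected
split and joins it back against itself under three tolerances: m/z (ppm
against the expected heavy position), retention time, and relative
intensity difference. Natural-isotope M+3 satellites sit at the same m/z
spacing but at ~1 % of the monoisotopic intensity, so the intensity filter
is what rejects them.

The production join sorts by m/z and window-scans (near linearithmic);
:func:`brute_force_pairs` is the exhaustive all-pairs reference used to
validate it in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_model import PROPANOYL, TagDefinition
from .peaktable_io import HIT_COLUMNS, PeakTable

__all__ = [
    "TolerancePolicy",
    "PairHit",
    "HitTable",
    "intensity_rel_diff",
    "find_labeled_pairs",
    "brute_force_pairs",
    "deduplicate_hits",
]


@dataclass(frozen=True)
class TolerancePolicy:
    """Pair-detection tolerances, interpreted as half-widths.

    Defaults are the screening settings for high-resolution Orbitrap data:
    +/-3 ppm m/z, +/-0.05 min RT co-elution, and at most a 33 % relative
    intensity difference between the twins. ``n_tags_searched`` is the set
    of tag multiplicities to scan (singly tagged by default; multiply
    tagged search is opt-in).
    """

    mz_ppm: float = 3.0
    rt_window: float = 0.05
    intensity_max_rel_diff: float = 0.33
    n_tags_searched: frozenset[int] = frozenset({1})
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mz_ppm <= 0:
            raise ValueError("mz_ppm must be > 0")
        if self.rt_window <= 0:
            raise ValueError("rt_window must be > 0")
        if not 0 < self.intensity_max_rel_diff <= 1:
            raise ValueError("intensity_max_rel_diff must be in (0, 1]")
        ns = frozenset(int(n) for n in self.n_tags_searched)
        if not ns or any(n < 1 for n in ns):
            raise ValueError("n_tags_searched must be a non-empty set of positive ints")
        object.__setattr__(self, "n_tags_searched", ns)
        if int(self.charge) < 1:
            raise ValueError("charge must be a positive integer")
        object.__setattr__(self, "charge", int(self.charge))


@dataclass(frozen=True)
class PairHit:
    """One matched light/heavy pair (row view of a hit table)."""

    light_id: str
    heavy_id: str
    n_tags: int
    light_mz: float
    heavy_mz: float
    light_rt: float
    heavy_rt: float
    light_intensity: float
    heavy_intensity: float
    ppm_error: float
    rt_delta: float
    intensity_rel_diff: float
    inferred_parent_mz: float


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        HIT_COLUMNS,
        [str, str, int, float, float, float, float, float, float,
         float, float, float, float],
    )})


@dataclass
class HitTable:
    """Detected isotopologue pairs for one sample.

    ``hits`` has one row per (light, heavy, n_tags) pair with both peaks'
    m/z, RT and intensity, the quality metrics, and the inferred untagged
    parent m/z (light m/z minus n x light tag addition).
    """

    sample_label: str
    role: str = "other"
    policy: TolerancePolicy | None = None
    hits: pd.DataFrame = field(default_factory=_empty_hits)

    def __len__(self) -> int:
        return len(self.hits)

    def pair_keys(self) -> set[tuple[str, str, int]]:
        """The hit set as (light_id, heavy_id, n_tags) triples."""
        return set(zip(self.hits["light_id"], self.hits["heavy_id"],
                       self.hits["n_tags"].astype(int)))

    def iter_hits(self):
        for row in self.hits.itertuples(index=False):
            yield PairHit(**row._asdict())

    @property
    def counts(self) -> dict[str, int]:
        return {
            "n_hits": len(self.hits),
            "n_light_peaks": self.hits["light_id"].nunique(),
            "n_heavy_peaks": self.hits["heavy_id"].nunique(),
        }


def intensity_rel_diff(a: np.ndarray | float, b: np.ndarray | float):
    """Symmetric relative intensity difference |a-b| / max(a, b), in [0, 1].

    Defined as 0 when both intensities are 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, np.abs(a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def _assemble_hits(table: PeakTable, light_idx: np.ndarray, heavy_idx: np.ndarray,
                   n_tags: np.ndarray, tag: TagDefinition,
                   policy: TolerancePolicy) -> pd.DataFrame:
    peaks = table.peaks
    ids = peaks["peak_id"].astype(str).to_numpy()
    mz = peaks["mz"].to_numpy(float)
    rt = peaks["rt"].to_numpy(float)
    inten = peaks["intensity"].to_numpy(float)

    expected = mz[light_idx] + n_tags * tag.pair_delta / policy.charge
    frame = pd.DataFrame({
        "light_id": ids[light_idx],
        "heavy_id": ids[heavy_idx],
        "n_tags": n_tags.astype(int),
        "light_mz": mz[light_idx],
        "heavy_mz": mz[heavy_idx],
        "light_rt": rt[light_idx],
        "heavy_rt": rt[heavy_idx],
        "light_intensity": inten[light_idx],
        "heavy_intensity": inten[heavy_idx],
        "ppm_error": 1e6 * (mz[heavy_idx] - expected) / expected,
        "rt_delta": rt[heavy_idx] - rt[light_idx],
        "intensity_rel_diff": intensity_rel_diff(inten[light_idx], inten[heavy_idx]),
        "inferred_parent_mz": mz[light_idx]
        - n_tags * tag.light_addition / policy.charge,
    })
    # canonical order so the result is independent of input row order
    frame = frame.sort_values(
        ["light_id", "heavy_id", "n_tags"], kind="stable"
    ).reset_index(drop=True)
    return frame


def find_labeled_pairs(table: PeakTable, tag: TagDefinition = PROPANOYL,
                       policy: TolerancePolicy | None = None) -> HitTable:
    """Find all light/heavy isotopologue pairs in one feature table.

    Every peak is a candidate light twin; for each searched tag count ``n``
    the expected heavy position is ``mz + n x pair_delta / charge`` and any
    peak within the ppm, RT and intensity tolerances of that position forms
    a hit. All qualifying pairs are reported (a peak may appear in several;
    see :func:`deduplicate_hits`). The join is a sorted-m/z window scan,
    O((N + H) log N) rather than all-pairs.
    """
    if policy is None:
        policy = TolerancePolicy()
    peaks = table.peaks
    if len(peaks) < 2:
        return HitTable(table.sample_label, table.role, policy)

    mz = peaks["mz"].to_numpy(float)
    rt = peaks["rt"].to_numpy(float)
    inten = peaks["intensity"].to_numpy(float)
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]

    light_parts, heavy_parts, n_parts = [], [], []
    n_peaks = len(mz)
    for n in sorted(policy.n_tags_searched):
        if n > tag.max_tags_per_compound:
            continue
        expected = mz + n * tag.pair_delta / policy.charge
        tol = expected * policy.mz_ppm * 1e-6
        lo = np.searchsorted(mz_sorted, expected - tol, side="left")
        hi = np.searchsorted(mz_sorted, expected + tol, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        light_idx = np.repeat(np.arange(n_peaks), counts)
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        heavy_idx = order[np.repeat(lo, counts) + offsets]

        keep = (
            (np.abs(rt[heavy_idx] - rt[light_idx]) <= policy.rt_window)
            & (intensity_rel_diff(inten[light_idx], inten[heavy_idx])
               <= policy.intensity_max_rel_diff)
            & (mz[heavy_idx] > mz[light_idx])
        )
        light_parts.append(light_idx[keep])
        heavy_parts.append(heavy_idx[keep])
        n_parts.append(np.full(int(keep.sum()), n))

    if not light_parts:
        return HitTable(table.sample_label, table.role, policy)
    hits = _assemble_hits(
        table,
        np.concatenate(light_parts),
        np.concatenate(heavy_parts),
        np.concatenate(n_parts),
        tag, policy,
    )
    return HitTable(table.sample_label, table.role, policy, hits)


def brute_force_pairs(table: PeakTable, tag: TagDefinition = PROPANOYL,
                      policy: TolerancePolicy | None = None) -> HitTable:
    """Exhaustive all-pairs reference with the same contract as
    :func:`find_labeled_pairs`; intended for small tables in tests."""
    if policy is None:
        policy = TolerancePolicy()
    peaks = table.peaks
    if len(peaks) < 2:
        return HitTable(table.sample_label, table.role, policy)

    mz = peaks["mz"].to_numpy(float)
    rt = peaks["rt"].to_numpy(float)
    inten = peaks["intensity"].to_numpy(float)

    light_parts, heavy_parts, n_parts = [], [], []
    for n in sorted(policy.n_tags_searched):
        if n > tag.max_tags_per_compound:
            continue
        expected = mz[:, None] + n * tag.pair_delta / policy.charge
        ppm = 1e6 * (mz[None, :] - expected) / expected
        ok = (
            (np.abs(ppm) <= policy.mz_ppm)
            & (np.abs(rt[None, :] - rt[:, None]) <= policy.rt_window)
            & (intensity_rel_diff(inten[:, None], inten[None, :])
               <= policy.intensity_max_rel_diff)
            & (mz[None, :] > mz[:, None])
        )
        li, hi_ = np.nonzero(ok)
        light_parts.append(li)
        heavy_parts.append(hi_)
        n_parts.append(np.full(len(li), n))

    light_idx = np.concatenate(light_parts)
    if len(light_idx) == 0:
        return HitTable(table.sample_label, table.role, policy)
    hits = _assemble_hits(table, light_idx, np.concatenate(heavy_parts),
                          np.concatenate(n_parts), tag, policy)
    return HitTable(table.sample_label, table.role, policy, hits)


def deduplicate_hits(hits: HitTable, strategy: str = "keep_all") -> HitTable:
    """Resolve multiple hits sharing one light peak.

    ``keep_all`` returns the input unchanged. ``best_ppm`` keeps, per light
    peak, the hit with minimal |ppm_error|, breaking ties by smaller
    |rt_delta| and then smaller heavy m/z.
    """
    if strategy == "keep_all":
        return hits
    if strategy != "best_ppm":
        raise ValueError(f"unknown deduplication strategy {strategy!r}")
    if len(hits) == 0:
        return hits
    frame = hits.hits.copy()
    frame["_app"] = frame["ppm_error"].abs()
    frame["_art"] = frame["rt_delta"].abs()
    frame = frame.sort_values(["_app", "_art", "heavy_mz"], kind="stable")
    frame = frame.drop_duplicates(subset=["light_id"], keep="first")
    frame = frame.drop(columns=["_app", "_art"])
    frame = frame.sort_values(["light_id", "heavy_id", "n_tags"],
                              kind="stable").reset_index(drop=True)
    return HitTable(hits.sample_label, hits.role, hits.policy, frame)
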