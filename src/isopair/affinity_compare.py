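"""Pre- vs post-cell-affinity hit-table comparison.

The same pair detector runs on the tagged extract before incubation with
cells ("pre") and on the cell lysate after binding and washing ("post").
A pair present in both tables — light-peak m/z within +/-4 ppm and RT
within +/-0.5 min across runs — marks a compound retained by the cells
(an *enriched* hit). Pairs seen only post-incubation suggest cellular
metabolism of a tagged parent. The cross-run tolerances are deliberately
looser than the within-run pair tolerances because m/z calibration and
RT drift between injections exceed within-spectrum errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pair_finder import HitTable

__all__ = [
    "MatchPolicy",
    "EnrichmentReport",
    "match_hit_tables",
    "enrichment_fraction",
    "post_only_hits",
]


@dataclass(frozen=True)
class MatchPolicy:
    """Cross-run matching tolerances (half-widths): +/-4 ppm, +/-0.5 min."""

    mz_ppm: float = 4.0
    rt_window: float = 0.5

    def __post_init__(self) -> None:
        if self.mz_ppm <= 0 or self.rt_window <= 0:
            raise ValueError("MatchPolicy tolerances must be > 0")


@dataclass
class EnrichmentReport:
    """Partition of pre and post hits into matched / pre-only / post-only.

    ``matched`` pairs each matched pre hit (``pre_`` columns) with its post
    hit (``post_`` columns) plus the match metrics. Every pre hit is either
    matched or in ``pre_only``; every post hit is matched or in
    ``post_only``.
    """

    matched: pd.DataFrame
    pre_only: pd.DataFrame
    post_only: pd.DataFrame
    policy: MatchPolicy
    pre_label: str = "pre"
    post_label: str = "post"

    @property
    def n_pre(self) -> int:
        return len(self.matched) + len(self.pre_only)

    @property
    def n_post(self) -> int:
        return len(self.matched) + len(self.post_only)

    @property
    def enrichment_fraction(self) -> float:
        """Fraction of extract pairs re-identified after the cell assay."""
        return len(self.matched) / self.n_pre if self.n_pre else 0.0

    def summary(self) -> dict[str, float | int]:
        return {
            "pre_hits": self.n_pre,
            "post_hits": self.n_post,
            "matched": len(self.matched),
            "pre_only": len(self.pre_only),
            "post_only": len(self.post_only),
            "enrichment_fraction": self.enrichment_fraction,
        }


def _symmetric_ppm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # ppm against the mean of the two m/z values, so match(a,b) == match(b,a)
    mean = 0.5 * (a + b)
    return 1e6 * np.abs(a - b) / mean


def match_hit_tables(pre: HitTable, post: HitTable,
                     policy: MatchPolicy | None = None) -> EnrichmentReport:
    """Cross-reference two hit tables on the light peak's m/z and RT.

    Candidate matches are pairs whose light m/z agree within ``mz_ppm``
    (evaluated symmetrically, against the mean of the two values) and whose
    light RTs agree within ``rt_window``; the heavy peaks then agree
    automatically within the combined tolerances because both tables share
    the tag delta. Assignment is one-to-one and greedy: candidates are taken
    in order of increasing |ppm|, ties broken by |RT delta|, so the report
    is deterministic and partitions both hit sets.
    """
    if policy is None:
        policy = MatchPolicy()
    pre_df = pre.hits.reset_index(drop=True)
    post_df = post.hits.reset_index(drop=True)

    if len(pre_df) and len(post_df):
        pre_mz = pre_df["light_mz"].to_numpy(float)
        pre_rt = pre_df["light_rt"].to_numpy(float)
        post_mz = post_df["light_mz"].to_numpy(float)
        post_rt = post_df["light_rt"].to_numpy(float)

        order = np.argsort(post_mz, kind="stable")
        post_mz_sorted = post_mz[order]
        # window on the mean-referenced ppm: widen slightly and re-check exactly
        tol = pre_mz * policy.mz_ppm * 1e-6 * (1 + policy.mz_ppm * 1e-6)
        lo = np.searchsorted(post_mz_sorted, pre_mz - tol, side="left")
        hi = np.searchsorted(post_mz_sorted, pre_mz + tol, side="right")
        counts = hi - lo
        total = int(counts.sum())
        pre_idx = np.repeat(np.arange(len(pre_df)), counts)
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        post_idx = order[np.repeat(lo, counts) + offsets]

        ppm = _symmetric_ppm(pre_mz[pre_idx], post_mz[post_idx])
        rt_delta = post_rt[post_idx] - pre_rt[pre_idx]
        ok = (ppm <= policy.mz_ppm) & (np.abs(rt_delta) <= policy.rt_window)
        cand = pd.DataFrame({
            "pre_idx": pre_idx[ok],
            "post_idx": post_idx[ok],
            "match_ppm": ppm[ok],
            "match_rt_delta": rt_delta[ok],
        }).sort_values(
            ["match_ppm", "match_rt_delta", "pre_idx", "post_idx"],
            key=lambda s: s.abs() if s.name == "match_rt_delta" else s,
            kind="stable",
        )

        pre_taken: set[int] = set()
        post_taken: set[int] = set()
        keep_rows = []
        for row in cand.itertuples(index=False):
            if row.pre_idx in pre_taken or row.post_idx in post_taken:
                continue
            pre_taken.add(row.pre_idx)
            post_taken.add(row.post_idx)
            keep_rows.append(row)
        assignments = pd.DataFrame(keep_rows, columns=cand.columns)
    else:
        assignments = pd.DataFrame(
            columns=["pre_idx", "post_idx", "match_ppm", "match_rt_delta"])
        pre_taken, post_taken = set(), set()

    if len(assignments):
        matched = pd.concat(
            [
                pre_df.loc[assignments["pre_idx"]].add_prefix("pre_").reset_index(drop=True),
                post_df.loc[assignments["post_idx"]].add_prefix("post_").reset_index(drop=True),
                assignments[["match_ppm", "match_rt_delta"]].reset_index(drop=True),
            ],
            axis=1,
        ).sort_values("pre_light_mz", kind="stable").reset_index(drop=True)
    else:
        matched = pd.DataFrame(
            columns=[f"pre_{c}" for c in pre_df.columns]
            + [f"post_{c}" for c in post_df.columns]
            + ["match_ppm", "match_rt_delta"])

    pre_only = pre_df.loc[~pre_df.index.isin(pre_taken)].reset_index(drop=True)
    post_only = post_df.loc[~post_df.index.isin(post_taken)].reset_index(drop=True)
    return EnrichmentReport(matched=matched, pre_only=pre_only,
                            post_only=post_only, policy=policy,
                            pre_label=pre.sample_label,
                            post_label=post.sample_label)


def enrichment_fraction(report: EnrichmentReport) -> float:
    """Matched pairs divided by total pre-incubation pairs (0 if none)."""
    return report.enrichment_fraction


def post_only_hits(report: EnrichmentReport) -> HitTable:
    """Pairs detected only after incubation: candidate cell-derived
    metabolites of tagged parents."""
    return HitTable(sample_label=f"{report.post_label}_only",
                    role="post_binding", policy=None,
                    hits=report.post_only.reset_index(drop=True))
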