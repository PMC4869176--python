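"""Cluster differential sites into differentially methylated regions (DMRs).

A DMR is a maximal run of consecutive differential sites on one chromosome in
which each inter-site gap (between site start coordinates) is at most
``max_gap`` bp; runs with fewer than ``min_sites`` members are discarded.
Non-differential sites are invisible to the gap rule: only the sites that
passed the per-site call participate in chaining. Both CpG and CpH sites are
eligible. Runs are kept whole rather than tiled into fixed windows, so region
boundaries reflect the actual location of the differential sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DMR:
    chrom: str
    start: int  # first member-site position
    end: int  # last member-site position + 1 (half-open)
    sites: pd.DataFrame  # member DifferentialSite rows
    direction_class: str  # hypo | hyper | mixed
    unidirectional: bool
    cpg_fraction: float  # CpG share of member sites
    mean_diff: float  # mean member diff, percentage points

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DmrSummary:
    """Cohort-level DMR summary; fractions are None when undefined (no DMRs,
    or no unidirectional DMRs for fraction_hypo)."""

    n_dmrs: int
    fraction_unidirectional: float | None
    fraction_hypo: float | None  # among unidirectional DMRs
    fraction_cpg_sites: float | None  # over all member sites
    median_span: float | None


def chain_positions(positions: np.ndarray, min_sites: int, max_gap: int
                    ) -> list[tuple[int, int]]:
    """Split sorted positions into maximal runs with consecutive gaps
    <= max_gap; return (start_index, end_index) slices of runs with at least
    min_sites members."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(positions)]])
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_sites]


def classify_direction(diffs) -> str:
    """hypo if every member diff < 0, hyper if every diff > 0, else mixed.
    A zero diff cannot occur in a called site (|diff| >= min_diff > 0)."""
    d = np.asarray(diffs, dtype=float)
    assert len(d) > 0, "direction of an empty region is undefined"
    assert not np.any(d == 0), "zero member diff: upstream call is inconsistent"
    if np.all(d < 0):
        return "hypo"
    if np.all(d > 0):
        return "hyper"
    return "mixed"


def _make_dmr(chrom: str, members: pd.DataFrame) -> DMR:
    direction = classify_direction(members["diff"].to_numpy())
    return DMR(
        chrom=chrom,
        start=int(members["pos"].iloc[0]),
        end=int(members["pos"].iloc[-1]) + 1,
        sites=members.reset_index(drop=True),
        direction_class=direction,
        unidirectional=direction != "mixed",
        cpg_fraction=float((members["context"] == "CpG").mean()),
        mean_diff=float(members["diff"].mean()),
    )


def cluster_sites(dm_sites: pd.DataFrame, min_sites: int = 4,
                  max_gap: int = 1_000) -> list[DMR]:
    """Cluster differential sites (rows with is_dm true, sorted by chrom/pos)
    into DMRs. Raises if the input is unsorted: sorting is the caller's
    contract."""
    if min_sites < 1 or max_gap <= 0:
        raise ValueError("min_sites >= 1 and max_gap > 0 required")
    if len(dm_sites) == 0:
        return []
    if "is_dm" in dm_sites.columns and not dm_sites["is_dm"].all():
        dm_sites = dm_sites[dm_sites["is_dm"]]
    dmrs: list[DMR] = []
    for chrom, group in dm_sites.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"dm_sites not sorted by position on {chrom}")
        for s, e in chain_positions(pos, min_sites, max_gap):
            dmrs.append(_make_dmr(chrom, group.iloc[s:e]))
    return dmrs


def summarize_dmrs(dmrs: list[DMR]) -> DmrSummary:
    """Direction, context and span summary over a DMR list."""
    if not dmrs:
        return DmrSummary(0, None, None, None, None)
    uni = [d for d in dmrs if d.unidirectional]
    n_cpg = sum(int(round(d.cpg_fraction * d.n_sites)) for d in dmrs)
    n_sites = sum(d.n_sites for d in dmrs)
    fraction_hypo = (
        sum(d.direction_class == "hypo" for d in uni) / len(uni) if uni else None
    )
    return DmrSummary(
        n_dmrs=len(dmrs),
        fraction_unidirectional=len(uni) / len(dmrs),
        fraction_hypo=fraction_hypo,
        fraction_cpg_sites=n_cpg / n_sites,
        median_span=float(np.median([d.span for d in dmrs])),
    )


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Flatten a DMR list into a per-region table (one row per DMR)."""
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_sites": d.n_sites,
                "direction_class": d.direction_class,
                "unidirectional": d.unidirectional,
                "cpg_fraction": d.cpg_fraction,
                "mean_diff": d.mean_diff,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "n_sites", "direction_class",
                 "unidirectional", "cpg_fraction", "mean_diff"],
    )
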