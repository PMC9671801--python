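"""LD-based definition of non-overlapping genomic regions.

Per metabolite, sentinel variants (largest -log10 P among the remaining
candidates) are peeled iteratively; each sentinel's interval spans the
positional range of candidates in LD with it (r^2 >= 0.1), or sentinel
+/- 500 kb when it has no LD partner.  Sentinel intervals from all metabolites
are then pooled: intervals whose sentinels are in LD (r^2 > 0.6) are merged,
250 kb is added to both ends, and overlapping intervals are merged repeatedly
until all regions are pairwise disjoint.  Coordinates are 1-based closed;
BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "SentinelInterval",
    "parse_vid",
    "metabolite_regions",
    "merge_regions",
    "assign_members",
    "define_regions",
    "regions_to_bed",
]

LD_REGION_R2 = 0.1
LD_SENTINEL_MERGE_R2 = 0.6
ISOLATED_HALF_WINDOW = 500_000
MERGE_PAD = 250_000


def parse_vid(vid: str) -> tuple[str, int]:
    """(chrom, pos) from a ``chrom:pos:ref:alt`` variant id."""
    chrom, pos, *_ = vid.split(":")
    return chrom, int(pos)


@dataclass
class SentinelInterval:
    chrom: str
    start: int
    end: int
    sentinel: str           # variant id
    metabolite: str
    mlog10p: float


@dataclass
class Region:
    id: str
    chrom: str
    start: int
    end: int
    sentinels: list[SentinelInterval] = field(default_factory=list)
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def _tie_key(row: pd.Series) -> tuple:
    # ties in -log10 P broken by smaller position, then allele lexicographic
    return (-row["mlog10p"], row["pos"], row["variant"])


def metabolite_regions(candidates: pd.DataFrame,
                       ld: pd.DataFrame,
                       isolated_half_window: int = ISOLATED_HALF_WINDOW,
                       ld_r2: float = LD_REGION_R2) -> list[SentinelInterval]:
    """Sentinel peeling for one metabolite.

    ``candidates`` needs columns variant, chrom, pos, mlog10p (one metabolite
    only, already past the candidate filter); every variant must appear in the
    LD matrix ``ld``.
    """
    missing = set(candidates["variant"]) - set(ld.index)
    if missing:
        raise KeyError(f"candidates absent from LD matrix: {sorted(missing)[:5]}")
    met = candidates["metabolite"].iloc[0] if "metabolite" in candidates else ""
    remaining = candidates.copy()
    out: list[SentinelInterval] = []
    while len(remaining):
        order = remaining.apply(_tie_key, axis=1).sort_values().index
        sent = remaining.loc[order[0]]
        same_chrom = remaining[remaining["chrom"] == sent["chrom"]]
        r2 = ld.loc[sent["variant"], same_chrom["variant"]].to_numpy(dtype=float)
        partners = same_chrom.loc[np.nan_to_num(r2) >= ld_r2]
        if len(partners) <= 1:  # only the sentinel itself
            start = max(1, int(sent["pos"]) - isolated_half_window)
            end = int(sent["pos"]) + isolated_half_window
            covered = [sent.name]
        else:
            start = int(partners["pos"].min())
            end = int(partners["pos"].max())
            covered = list(partners.index)
        out.append(SentinelInterval(
            chrom=str(sent["chrom"]), start=start, end=end,
            sentinel=str(sent["variant"]), metabolite=str(met),
            mlog10p=float(sent["mlog10p"])))
        remaining = remaining.drop(index=covered)
    return out


def merge_regions(intervals: list[SentinelInterval],
                  sentinel_ld: pd.DataFrame,
                  pad: int = MERGE_PAD,
                  sentinel_r2: float = LD_SENTINEL_MERGE_R2) -> list[Region]:
    """Pool sentinel intervals from all metabolites into disjoint regions.

    Union-find over sentinels in LD (r^2 > ``sentinel_r2``, within
    chromosome), pad both ends of every merged interval by ``pad`` bp, then
    merge any overlapping (closed-interval) ranges until disjoint.
    """
    if not intervals:
        return []
    parent = list(range(len(intervals)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            if a.sentinel in sentinel_ld.index and b.sentinel in sentinel_ld.columns:
                r2 = sentinel_ld.loc[a.sentinel, b.sentinel]
                if np.isfinite(r2) and r2 > sentinel_r2:
                    assert a.chrom == b.chrom  # LD is within-chromosome only
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)

    padded: list[tuple[str, int, int, list[int]]] = []
    for members in groups.values():
        chrom = intervals[members[0]].chrom
        start = max(1, min(intervals[i].start for i in members) - pad)
        end = max(intervals[i].end for i in members) + pad
        padded.append((chrom, start, end, members))

    # sweep-merge overlapping closed intervals per chromosome
    padded.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[tuple[str, int, int, list[int]]] = []
    for chrom, start, end, members in padded:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] + members)
        else:
            merged.append((chrom, start, end, list(members)))

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    merged.sort(key=lambda t: (chrom_key(t[0]), t[1]))
    out = []
    for k, (chrom, start, end, members) in enumerate(merged, start=1):
        sentinels = sorted((intervals[i] for i in members),
                           key=lambda s: (-s.mlog10p, s.sentinel))
        out.append(Region(id=f"R{k}", chrom=chrom, start=start, end=end,
                          sentinels=sentinels))
    return out


def assign_members(regions: list[Region], candidates: pd.DataFrame) -> None:
    """Attach every candidate variant to the unique region containing it."""
    seen: dict[str, str] = {}
    for _, row in candidates.drop_duplicates("variant").iterrows():
        for reg in regions:
            if reg.contains(str(row["chrom"]), int(row["pos"])):
                if row["variant"] not in reg.members:
                    reg.members.append(row["variant"])
                seen[row["variant"]] = reg.id
                break
    for reg in regions:
        reg.members.sort(key=parse_vid)


def define_regions(candidates: pd.DataFrame,
                   ld: pd.DataFrame,
                   isolated_half_window: int = ISOLATED_HALF_WINDOW,
                   pad: int = MERGE_PAD) -> list[Region]:
    """Candidate associations (all metabolites) -> final disjoint regions.

    ``candidates`` is the output of the candidate filter with chrom/pos and
    mlog10p columns attached (one row per variant x metabolite).
    """
    intervals: list[SentinelInterval] = []
    for _, group in candidates.groupby("metabolite", sort=True):
        intervals.extend(metabolite_regions(group, ld,
                                            isolated_half_window=isolated_half_window))
    sentinels = sorted({iv.sentinel for iv in intervals})
    present = [s for s in sentinels if s in ld.index]
    sentinel_ld = ld.loc[present, present]
    regions = merge_regions(intervals, sentinel_ld, pad=pad)
    assign_members(regions, candidates)
    return regions


def regions_to_bed(regions: list[Region]) -> pd.DataFrame:
    """BED-like frame: 0-based half-open coordinates, sentinel list joined."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start - 1 for r in regions],
        "end": [r.end for r in regions],
        "id": [r.id for r in regions],
        "sentinels": [",".join(dict.fromkeys(s.sentinel for s in r.sentinels))
                      for r in regions],
    })
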