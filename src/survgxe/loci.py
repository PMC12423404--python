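"""Locus definition: LD clumping, merging, extension, and gene annotation.

Per-variant signals are collapsed into independent loci with PLINK-style
greedy clumping (ascending p-value; a variant joins the best existing index
within the physical window at r^2 above threshold, otherwise founds its own
clump), followed by span-based merging of nearby clumps and optional
interval extension. Coordinates are 1-based inclusive internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "Locus", "ld_r2", "clump", "merge_clumps", "extend_loci",
    "overlap_known", "nearest_gene",
]


@dataclass
class Locus:
    """A genomic interval holding an index (minimum-p) variant and members."""

    chrom: str
    start: int
    end: int
    index_variant: str
    members: list[str]
    min_p: float
    source: str = ""
    member_pos: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must not exceed end")
        if self.index_variant not in self.members:
            raise ValueError("index variant must be a member of its locus")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def ld_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete (both non-missing) samples; NaN when degenerate."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors must share the sample set")
    ok = ~(np.isnan(d1) | np.isnan(d2))
    x, y = d1[ok], d2[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    results: pd.DataFrame,
    genos: GenotypeMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_bp: int = 250_000,
    p_col: str = "p_spa",
    source: str = "",
) -> list[Locus]:
    """Greedy LD clumping of a score-test table.

    Variants with p below ``p_threshold`` are visited by ascending p (ties
    broken by position then id). A variant joins the first (best-p) existing
    index on its chromosome that lies within ``window_bp`` (index-to-variant
    distance) and has in-sample r^2 at or above ``r2_threshold``; otherwise
    it founds a new clump — including when it sits inside the window of an
    index it is not correlated with.
    """
    idx_map = genos.variant_index()
    sig = results.loc[results[p_col] < p_threshold]
    missing = [vid for vid in sig["id"] if vid not in idx_map]
    if missing:
        raise KeyError(f"variants missing from genotype matrix: {missing[:5]}")
    order = sig.sort_values([p_col, "pos", "id"], kind="stable")
    clumps: list[dict] = []  # in creation order == ascending index p
    for _, row in order.iterrows():
        vid, chrom, pos, p = row["id"], str(row["chrom"]), int(row["pos"]), float(row[p_col])
        g = genos.dosages[:, idx_map[vid]]
        joined = False
        for c in clumps:
            if c["chrom"] != chrom or abs(pos - c["index_pos"]) > window_bp:
                continue
            r2 = ld_r2(g, genos.dosages[:, idx_map[c["index"]]])
            if np.isfinite(r2) and r2 >= r2_threshold:
                c["members"].append(vid)
                c["member_pos"][vid] = pos
                joined = True
                break
        if not joined:
            clumps.append({"chrom": chrom, "index": vid, "index_pos": pos,
                           "min_p": p, "members": [vid], "member_pos": {vid: pos}})
    return [
        Locus(
            chrom=c["chrom"],
            start=min(c["member_pos"].values()),
            end=max(c["member_pos"].values()),
            index_variant=c["index"],
            members=list(c["members"]),
            min_p=c["min_p"],
            source=source,
            member_pos=dict(c["member_pos"]),
        )
        for c in clumps
    ]


def _merge_group(group: list[Locus]) -> Locus:
    best = min(group, key=lambda l: (l.min_p, l.start, l.index_variant))
    members: list[str] = []
    member_pos: dict[str, int] = {}
    for l in group:
        for m in l.members:
            if m not in member_pos:
                members.append(m)
                member_pos[m] = l.member_pos.get(m, l.start)
    return Locus(
        chrom=group[0].chrom,
        start=min(l.start for l in group),
        end=max(l.end for l in group),
        index_variant=best.index_variant,
        members=members,
        min_p=min(l.min_p for l in group),
        source=group[0].source,
        member_pos=member_pos,
    )


def merge_clumps(clumps: list[Locus], gap_bp: int = 250_000) -> list[Locus]:
    """Merge clumps whose member spans lie within ``gap_bp`` of each other
    (transitively, per chromosome). Idempotent."""
    out: list[Locus] = []
    by_chrom: dict[str, list[Locus]] = {}
    for c in clumps:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end))
        group: list[Locus] = []
        reach = -1
        for l in items:
            if group and l.start - reach > gap_bp:
                out.append(_merge_group(group))
                group = []
            group.append(l)
            reach = max(reach, l.end)
        if group:
            out.append(_merge_group(group))
    return out


def extend_loci(loci: list[Locus], pad_bp: int = 250_000) -> list[Locus]:
    """Extend each locus by ``pad_bp`` on both sides (start floored at 1)
    and merge overlapping extended intervals of the same analysis, so the
    result counts independent loci."""
    padded = [
        Locus(chrom=l.chrom, start=max(1, l.start - pad_bp), end=l.end + pad_bp,
              index_variant=l.index_variant, members=list(l.members),
              min_p=l.min_p, source=l.source, member_pos=dict(l.member_pos))
        for l in loci
    ]
    # overlap (>= 1 bp) == within gap 0 after extension; group per source
    by_source: dict[str, list[Locus]] = {}
    for l in padded:
        by_source.setdefault(l.source, []).append(l)
    out: list[Locus] = []
    for src in sorted(by_source):
        out.extend(merge_clumps(by_source[src], gap_bp=0))
    return out


def overlap_known(loci: list[Locus], known: list[tuple[str, int, int]]) -> list[bool]:
    """Flag each locus as known (True) iff its interval intersects any known
    interval on the same chromosome (1-based inclusive coordinates)."""
    flags = []
    for l in loci:
        hit = any(
            chrom == l.chrom and not (end < l.start or start > l.end)
            for chrom, start, end in known
        )
        flags.append(hit)
    return flags


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> tuple[str, int]:
    """Nearest protein-coding gene to a position.

    Distance is 0 inside a gene span, else the smaller endpoint distance;
    exact ties go to the gene with smaller start, then lexicographically
    smaller symbol. Raises when no protein-coding gene shares the
    chromosome.
    """
    sub = genes.loc[(genes["biotype"] == "protein_coding")
                    & (genes["chrom"].astype(str) == str(chrom))]
    if sub.empty:
        raise ValueError(f"no protein-coding genes on chromosome {chrom}")
    start = sub["start"].to_numpy(dtype=int)
    end = sub["end"].to_numpy(dtype=int)
    inside = (pos >= start) & (pos <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    best = np.lexsort((sub["symbol"].to_numpy(), start, dist))[0]
    return str(sub["symbol"].iloc[best]), int(dist[best])
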