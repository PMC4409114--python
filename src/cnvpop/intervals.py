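"""Interval matching: reciprocal overlap, locus clustering, Jaccard, novelty.

Two calls *match* under the reciprocal rule when the overlap covers at
least a fraction ``threshold`` of EACH interval's length (the field's
standard 50% reciprocal-overlap criterion), or, in exact-breakpoint mode,
when both endpoints agree within ``breakpoint_tolerance`` bp. Loci are the
connected components of the match graph (single linkage), so chained
overlaps merge; a strict all-pairs mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import CNVCall, CNVLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapRule:
    """Matching rule for CNV intervals.

    mode: ``"reciprocal"`` (default) or ``"exact_breakpoint"``.
    threshold: reciprocal-overlap fraction in (0, 1], default 0.5.
    breakpoint_tolerance: bp slack for exact mode, default 0.
    """

    mode: str = "reciprocal"
    threshold: float = 0.5
    breakpoint_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("reciprocal", "exact_breakpoint"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.breakpoint_tolerance < 0:
            raise ValueError("breakpoint_tolerance must be >= 0")

    def matches(self, a: CNVCall, b: CNVCall) -> bool:
        if a.chrom != b.chrom:
            return False
        if self.mode == "exact_breakpoint":
            return (
                abs(a.start - b.start) <= self.breakpoint_tolerance
                and abs(a.end - b.end) <= self.breakpoint_tolerance
            )
        return reciprocal_overlap(a, b) >= self.threshold


def reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    """Reciprocal overlap fraction min(o/len(a), o/len(b)) in [0, 1].

    Overlap length on inclusive coordinates: ``min(end) - max(start) + 1``
    when positive. Intervals on different chromosomes return 0.
    """
    if a.chrom != b.chrom:
        return 0.0
    o = min(a.end, b.end) - max(a.start, b.start) + 1
    if o <= 0:
        return 0.0
    return min(o / a.length, o / b.length)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def dedup_same_sample(calls: list[CNVCall], rule: OverlapRule | None = None) -> list[CNVCall]:
    """Collapse a sample's redundant calls (e.g. merged algorithm outputs).

    Within each (sample, type, chromosome) group, calls matching under
    ``rule`` are merged; the longest member of each group is kept. Order of
    the kept calls follows first appearance.
    """
    rule = rule or OverlapRule()
    keyed: dict[tuple[str, str, str], list[int]] = {}
    for i, c in enumerate(calls):
        keyed.setdefault((c.sample_id, c.cnv_type, c.chrom), []).append(i)
    uf = _UnionFind(len(calls))
    for idxs in keyed.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                if rule.matches(calls[idxs[ai]], calls[idxs[bi]]):
                    uf.union(idxs[ai], idxs[bi])
    best: dict[int, int] = {}
    for i, c in enumerate(calls):
        r = uf.find(i)
        if r not in best or c.length > calls[best[r]].length:
            best[r] = i
    kept_idx = sorted(best.values())
    if len(kept_idx) < len(calls):
        logger.info("same-sample dedup removed %d of %d calls", len(calls) - len(kept_idx), len(calls))
    return [calls[i] for i in kept_idx]


def cluster_loci(
    calls: list[CNVCall],
    rule: OverlapRule | None = None,
    type_aware: bool = True,
    strict_all_pairs: bool = False,
) -> list[CNVLocus]:
    """Partition calls into loci (breakpoint regions) under ``rule``.

    Single-linkage by default: two calls link iff they match under the
    rule, and loci are the connected components, accelerated with an
    interval tree. When ``type_aware`` (default), DUP and DEL never link —
    losses and gains are analysed separately. ``strict_all_pairs`` instead
    grows a cluster only while every member pair matches (greedy by
    leftmost start, deterministic).

    Loci are returned sorted by (chrom, start, end) with ids ``L000001``…
    """
    rule = rule or OverlapRule()
    if not calls:
        return []
    groups: dict[tuple, list[int]] = {}
    for i, c in enumerate(calls):
        key = (c.chrom, c.cnv_type) if type_aware else (c.chrom,)
        groups.setdefault(key, []).append(i)

    clusters: list[list[int]] = []
    for idxs in groups.values():
        if strict_all_pairs:
            clusters.extend(_cluster_strict(calls, idxs, rule))
        else:
            clusters.extend(_cluster_single_linkage(calls, idxs, rule))

    loci = []
    for members in clusters:
        mc = tuple(sorted((calls[i] for i in members), key=lambda c: (c.start, c.end, c.sample_id)))
        loci.append(
            CNVLocus(
                locus_id="",
                chrom=mc[0].chrom,
                start=min(c.start for c in mc),
                end=max(c.end for c in mc),
                member_calls=mc,
            )
        )
    loci.sort(key=lambda l: (_chrom_key(l.chrom), l.start, l.end))
    return [
        CNVLocus(f"L{i + 1:06d}", l.chrom, l.start, l.end, l.member_calls)
        for i, l in enumerate(loci)
    ]


def _chrom_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):02d}") if chrom.isdigit() else (1, chrom)


def _cluster_single_linkage(calls, idxs, rule: OverlapRule) -> list[list[int]]:
    uf = _UnionFind(len(idxs))
    pos = {g: k for k, g in enumerate(idxs)}
    # half-open tree coordinates: end + 1
    tree = IntervalTree()
    for g in idxs:
        tree.addi(calls[g].start, calls[g].end + 1, g)
    for g in idxs:
        for hit in tree.overlap(calls[g].start, calls[g].end + 1):
            h = hit.data
            if h > g and rule.matches(calls[g], calls[h]):
                uf.union(pos[g], pos[h])
    comps: dict[int, list[int]] = {}
    for g in idxs:
        comps.setdefault(uf.find(pos[g]), []).append(g)
    return list(comps.values())


def _cluster_strict(calls, idxs, rule: OverlapRule) -> list[list[int]]:
    order = sorted(idxs, key=lambda i: (calls[i].start, calls[i].end, i))
    clusters: list[list[int]] = []
    for i in order:
        for cl in clusters:
            if all(rule.matches(calls[i], calls[j]) for j in cl):
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def _greedy_match(a: list[CNVCall], b: list[CNVCall], rule: OverlapRule) -> int:
    """Greedy 1-1 matching count, by descending overlap; deterministic ties."""
    pairs = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            if rule.mode == "exact_breakpoint":
                if rule.matches(ca, cb):
                    pairs.append((1.0, ca.start, ca.length, i, j))
            else:
                ov = reciprocal_overlap(ca, cb)
                if ov >= rule.threshold:
                    pairs.append((ov, ca.start, ca.length, i, j))
    # descending overlap; ties broken by leftmost start then smallest length
    pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _, _, _, i, j in pairs:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matched += 1
    return matched


def jaccard_calls(
    setA: list[CNVCall],
    setB: list[CNVCall],
    rule: OverlapRule | None = None,
    by_type: bool = True,
) -> float:
    """Jaccard concordance of two call sets under an overlap rule.

    Matched pairs are found by greedy 1-1 matching (descending overlap);
    J = matched / (|A| + |B| - matched). With ``by_type`` (default) losses
    and gains are matched separately, then pooled into one statistic. Two
    empty sets return 1.0 by convention.
    """
    rule = rule or OverlapRule()
    if not setA and not setB:
        return 1.0
    matched = 0
    if by_type:
        for t in ("DUP", "DEL"):
            matched += _greedy_match(
                [c for c in setA if c.cnv_type == t],
                [c for c in setB if c.cnv_type == t],
                rule,
            )
    else:
        matched = _greedy_match(setA, setB, rule)
    return matched / (len(setA) + len(setB) - matched)


@dataclass
class NoveltySummary:
    n_calls: int
    n_novel: int
    novel_fraction: float
    by_type: dict[str, float] = field(default_factory=dict)


def flag_novel(
    calls: list[CNVCall],
    reference: list[CNVCall],
    rule: OverlapRule | None = None,
) -> tuple[list[bool], NoveltySummary]:
    """Flag calls with no match in a reference CNV catalogue.

    A call is novel iff it matches no reference interval under ``rule``.
    Type is ignored for matching (a catalogued region of either type makes
    a call known). Returns per-call flags aligned with the input plus a
    summary split by DUP/DEL.
    """
    rule = rule or OverlapRule()
    if not reference:
        logger.warning("empty reference set: all %d calls flagged novel", len(calls))
    trees: dict[str, IntervalTree] = {}
    for r in reference:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    flags: list[bool] = []
    for c in calls:
        novel = True
        tree = trees.get(c.chrom)
        if tree is not None:
            for hit in tree.overlap(c.start, c.end + 1):
                if rule.matches(c, hit.data):
                    novel = False
                    break
        flags.append(novel)
    by_type = {}
    for t in ("DUP", "DEL"):
        sub = [f for f, c in zip(flags, calls) if c.cnv_type == t]
        by_type[t] = sum(sub) / len(sub) if sub else 0.0
    n_novel = sum(flags)
    summary = NoveltySummary(
        n_calls=len(calls),
        n_novel=n_novel,
        novel_fraction=n_novel / len(calls) if calls else 0.0,
        by_type=by_type,
    )
    return flags, summary
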