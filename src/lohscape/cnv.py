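"""Copy-number binning, gene-level annotation and segment-set comparison.

Total copy number is binned into five categories (0 = Deletion, 1 = Loss,
2-3 = Neutral, 4-5 = Gain, >=6 = Amplification).  A gene's copy number is
the minimum over the covered parts of its locus; a gene counts as deleted
when more than half of the locus is covered by Deletion-binned segments and
as amplified only when the entire locus is covered by Amplification-binned
segments.  Segment sets are compared with 50% reciprocal overlap
(shared/private calls) and a basepair Jaccard statistic (BEDtools
convention: intersection length over union length of the merged sets).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import CNCategory, GeneModel, SegmentProfile

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]  # (chrom, start, end), 1-based inclusive


def bin_copy_number(cn_total: int) -> CNCategory:
    """Map a total copy number to its category."""
    if cn_total < 0:
        raise ValueError(f"copy number must be >= 0, got {cn_total}")
    if cn_total == 0:
        return CNCategory.DELETION
    if cn_total == 1:
        return CNCategory.LOSS
    if cn_total <= 3:
        return CNCategory.NEUTRAL
    if cn_total <= 5:
        return CNCategory.GAIN
    return CNCategory.AMPLIFICATION


@dataclass
class GeneCNCall:
    gene: str
    sample_id: str
    min_cn: Optional[int]
    category: Optional[CNCategory]
    covered_fraction: float
    covered_fraction_by_category: dict[CNCategory, float] = field(default_factory=dict)

    @property
    def qualifies_deleted(self) -> bool:
        return self.covered_fraction_by_category.get(CNCategory.DELETION, 0.0) > 0.5

    @property
    def qualifies_amplified(self) -> bool:
        return self.covered_fraction_by_category.get(CNCategory.AMPLIFICATION, 0.0) >= 1.0


def annotate_gene_cn(gene: GeneModel, profile: SegmentProfile) -> GeneCNCall:
    """Gene-level copy-number call from the segments intersecting the locus.

    ``min_cn`` is computed over covered parts only; uncovered portions of the
    gene contribute to no category (the ``covered_fraction`` field lets
    callers filter poorly covered genes).  A gene on a chromosome absent from
    the profile yields a no-call with a warning.
    """
    segs = profile.by_chrom().get(gene.chrom)
    if segs is None:
        logger.warning("gene %s: chromosome %s absent from profile %s",
                       gene.gene, gene.chrom, profile.sample_id)
        return GeneCNCall(gene.gene, profile.sample_id, None, None, 0.0)
    min_cn: Optional[int] = None
    covered = 0
    by_cat: dict[CNCategory, int] = {}
    for seg in segs:
        ov = min(seg.end, gene.end) - max(seg.start, gene.start) + 1
        if ov <= 0:
            continue
        covered += ov
        cat = bin_copy_number(seg.cn_total)
        by_cat[cat] = by_cat.get(cat, 0) + ov
        min_cn = seg.cn_total if min_cn is None else min(min_cn, seg.cn_total)
    if min_cn is None:
        return GeneCNCall(gene.gene, profile.sample_id, None, None, 0.0)
    glen = gene.length
    return GeneCNCall(
        gene.gene, profile.sample_id, min_cn, bin_copy_number(min_cn),
        covered_fraction=covered / glen,
        covered_fraction_by_category={c: n / glen for c, n in by_cat.items()},
    )


# ---------------------------------------------------------------------------
# interval set comparison
# ---------------------------------------------------------------------------

def _overlap(a: Interval, b: Interval) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]) + 1)


def reciprocal_overlap(a: Interval, b: Interval, f: float = 0.5) -> bool:
    """True iff the intersection covers at least fraction ``f`` of each interval."""
    if not (0.0 < f <= 1.0):
        raise ValueError(f"reciprocal-overlap fraction must be in (0, 1], got {f}")
    ov = _overlap(a, b)
    return ov >= f * (a[2] - a[1] + 1) and ov >= f * (b[2] - b[1] + 1)


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2] + 1:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def _total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s + 1 for _, s, e in intervals)


def _intersect_merged(a: list[Interval], b: list[Interval]) -> int:
    total = 0
    for ia in a:
        for ib in b:
            total += _overlap(ia, ib)
    return total


def jaccard(set_a: Sequence[Interval], set_b: Sequence[Interval]) -> float:
    """Basepair Jaccard of two interval sets (on their merged footprints)."""
    ma, mb = _merge_intervals(set_a), _merge_intervals(set_b)
    inter = _intersect_merged(ma, mb)
    union = _total_length(ma) + _total_length(mb) - inter
    return inter / union if union else 0.0


@dataclass
class SegmentSetComparison:
    shared_a: list[Interval]
    shared_b: list[Interval]
    private_a: list[Interval]
    private_b: list[Interval]
    jaccard: float


def compare_segment_sets(set_a: Sequence[Interval], set_b: Sequence[Interval],
                         f: float = 0.5) -> SegmentSetComparison:
    """Classify each segment as shared or private at reciprocal overlap ``f``.

    Matching is greedy on overlap length (deterministic: ties broken by
    input order), one partner per segment.  The Jaccard statistic is
    computed on the full merged sets, independent of the matching.
    """
    candidates = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if reciprocal_overlap(a, b, f):
                candidates.append((-_overlap(a, b), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
    return SegmentSetComparison(
        shared_a=[a for i, a in enumerate(set_a) if i in used_a],
        shared_b=[b for j, b in enumerate(set_b) if j in used_b],
        private_a=[a for i, a in enumerate(set_a) if i not in used_a],
        private_b=[b for j, b in enumerate(set_b) if j not in used_b],
        jaccard=jaccard(set_a, set_b),
    )


def minimal_common_region(interval_lists: Sequence[Sequence[Interval]],
                          min_support: int = 1) -> tuple[Optional[Interval], int]:
    """Maximal-support intersection interval across per-sample interval lists.

    Support of a basepair is the number of lists with at least one interval
    covering it.  Returns the leftmost contiguous region of greatest support
    among those reaching ``min_support``, with that support count; ``(None,
    0)`` when no region reaches ``min_support``.
    """
    if not any(interval_lists):
        return None, 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for sample in interval_lists:
        for chrom, s, e in _merge_intervals(list(sample)):
            by_chrom.setdefault(chrom, []).append((s, e))
    # breakpoint sweep: elementary intervals between consecutive breakpoints
    elementary: list[tuple[Interval, int]] = []
    for chrom in sorted(by_chrom):
        deltas: dict[int, int] = {}
        for s, e in by_chrom[chrom]:
            deltas[s] = deltas.get(s, 0) + 1
            deltas[e + 1] = deltas.get(e + 1, 0) - 1
        positions = sorted(deltas)
        depth = 0
        for p, nxt in zip(positions, positions[1:]):
            depth += deltas[p]
            if depth > 0:
                elementary.append(((chrom, p, nxt - 1), depth))
    if not elementary:
        return None, 0
    best_support = max(d for _, d in elementary)
    if best_support < min_support:
        return None, 0
    top = [iv for iv, d in elementary if d == best_support]
    # merge contiguous top-support pieces; report the leftmost region
    merged = _merge_intervals(top)
    return merged[0], best_support


# ---------------------------------------------------------------------------
# cohort-level gene ranking
# ---------------------------------------------------------------------------

EVENT_CATEGORIES = {
    "gain_or_amp": {CNCategory.GAIN, CNCategory.AMPLIFICATION},
    "loss_or_del": {CNCategory.LOSS, CNCategory.DELETION},
}


def rank_genes_by_cn_event(gene_calls: pd.DataFrame, event: str, group: str,
                           ) -> list[tuple[str, int]]:
    """Rank genes by the number of distinct patients showing a CN event.

    ``gene_calls`` has columns gene, patient_id, group, category.  A gene
    counts at most once per patient within the group, regardless of how many
    of the patient's samples show the event.  Descending score, ties broken
    lexicographically by gene symbol.
    """
    if event not in EVENT_CATEGORIES:
        raise ValueError(f"unknown event {event!r}; expected one of {sorted(EVENT_CATEGORIES)}")
    if group not in set(gene_calls.get("group", pd.Series(dtype=str))) and len(gene_calls):
        raise ValueError(f"unknown group label {group!r}")
    wanted = {c.value for c in EVENT_CATEGORIES[event]}
    sub = gene_calls[(gene_calls["group"] == group)
                     & (gene_calls["category"].isin(wanted))]
    counts = sub.groupby("gene")["patient_id"].nunique()
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
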