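"""Independent brute-force reference scorers used as test oracles.

Deliberately simple, quadratic implementations written directly from the
score definitions, sharing no code with the package: maximal same-state
runs are found by repeated full rescans, smoothing removes one segment per
pass, and interval statistics are counted per basepair where feasible.
"""
from __future__ import annotations


def _to_runs(segments):
    """[(start, end, (major, minor))] per chromosome via repeated rescans."""
    by_chrom = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(
            [seg.start, seg.end, (seg.cn_major, seg.cn_minor)])
    for chrom, rows in by_chrom.items():
        rows.sort()
        changed = True
        while changed:
            changed = False
            for i in range(len(rows) - 1):
                a, b = rows[i], rows[i + 1]
                if a[2] == b[2] and b[0] == a[1] + 1:
                    rows[i] = [a[0], b[1], a[2]]
                    del rows[i + 1]
                    changed = True
                    break
    return by_chrom


def naive_hrd_loh(profile, annotation, min_len=15_000_000):
    count = 0
    for chrom, runs in _to_runs(profile.segments).items():
        for s, e, (major, minor) in runs:
            if minor == 0 and (e - s + 1) > min_len \
                    and (e - s + 1) < annotation.chrom_lengths[chrom]:
                count += 1
    return count


def naive_ntai(profile, annotation, min_len=1_000_000, tol=0):
    count = 0
    for chrom, runs in _to_runs(profile.segments).items():
        clen = annotation.chrom_lengths[chrom]
        cs, ce = annotation.centromeres[chrom]
        for s, e, (major, minor) in runs:
            if major == minor:
                continue
            if (e - s + 1) < min_len or (e - s + 1) >= clen:
                continue
            at_telomere = (s - 1) <= tol or (clen - e) <= tol
            overlaps_cen = not (e < cs or s > ce)
            if at_telomere and not overlaps_cen:
                count += 1
    return count


def naive_lst(profile, min_seg=10_000_000, smooth=3_000_000):
    total = 0
    for chrom, rows in _to_runs(profile.segments).items():
        rows = [list(r) for r in rows]
        # merge same-state neighbours across small gaps, then smooth,
        # one change per full pass
        changed = True
        while changed:
            changed = False
            for i in range(len(rows) - 1):
                a, b = rows[i], rows[i + 1]
                if a[2] == b[2] and (b[0] - a[1] - 1) < smooth:
                    rows[i] = [a[0], b[1], a[2]]
                    del rows[i + 1]
                    changed = True
                    break
            if changed:
                continue
            smalls = [(r[1] - r[0] + 1, i) for i, r in enumerate(rows)
                      if (r[1] - r[0] + 1) < smooth]
            if smalls:
                _, i = min(smalls)
                del rows[i]
                changed = True
        for i in range(len(rows) - 1):
            a, b = rows[i], rows[i + 1]
            if a[2] != b[2] and (a[1] - a[0] + 1) >= min_seg \
                    and (b[1] - b[0] + 1) >= min_seg and (b[0] - a[1] - 1) < smooth:
                total += 1
    return total


def naive_aneuploidy(profile, annotation):
    import math

    target = math.floor(profile.ploidy + 0.5)
    count = 0
    for chrom in annotation.chroms():
        for arm, arm_s, arm_e in annotation.arm_intervals(chrom):
            altered = 0
            for seg in profile.segments:
                if seg.chrom != chrom or seg.cn_total == target:
                    continue
                lo, hi = max(seg.start, arm_s), min(seg.end, arm_e)
                if lo <= hi:
                    altered += hi - lo + 1
            if altered >= 0.8 * (arm_e - arm_s + 1):
                count += 1
    return count


# --- per-basepair interval statistics (tiny coordinates only) --------------

def naive_jaccard(set_a, set_b):
    bp_a = {(c, p) for c, s, e in set_a for p in range(s, e + 1)}
    bp_b = {(c, p) for c, s, e in set_b for p in range(s, e + 1)}
    union = bp_a | bp_b
    return len(bp_a & bp_b) / len(union) if union else 0.0


def naive_mcr(interval_lists, min_support=1):
    """Per-basepair support count; returns (leftmost best interval, support)."""
    support: dict[tuple, int] = {}
    for sample in interval_lists:
        seen = set()
        for c, s, e in sample:
            for p in range(s, e + 1):
                seen.add((c, p))
        for key in seen:
            support[key] = support.get(key, 0) + 1
    if not support:
        return None, 0
    best = max(support.values())
    if best < min_support:
        return None, 0
    top = sorted(k for k, v in support.items() if v == best)
    # leftmost contiguous run on the first chromosome reaching best support
    chrom, start = top[0]
    end = start
    for c, p in top[1:]:
        if c == chrom and p == end + 1:
            end = p
        else:
            break
    return (chrom, start, end), best
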