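"""Half-open interval arithmetic on a single sequence.

All intervals are 0-based half-open ``(start, end)`` tuples with
``end > start``.  Functions return sorted, non-overlapping lists.
"""

from __future__ import annotations

Interval = tuple[int, int]


def _check(ivs) -> list[Interval]:
    out = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        out.append((int(s), int(e)))
    return out


def merge(ivs, gap: int = 0) -> list[Interval]:
    """Merge overlapping intervals; intervals separated by <= ``gap`` bases fuse."""
    ivs = sorted(_check(ivs))
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s - pe <= gap:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def union(a, b) -> list[Interval]:
    return merge(list(a) + list(b))


def intersect(a, b) -> list[Interval]:
    """Intersection of two interval sets."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets) -> list[Interval]:
    """Intersection over an iterable of interval sets (error on empty iterable)."""
    sets = list(sets)
    if not sets:
        raise ValueError("intersection over zero interval sets is undefined")
    acc = merge(sets[0])
    for s in sets[1:]:
        acc = intersect(acc, s)
        if not acc:
            break
    return acc


def union_many(sets) -> list[Interval]:
    out: list[Interval] = []
    for s in sets:
        out.extend(s)
    return merge(out)


def subtract(a, b) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs) -> int:
    return sum(e - s for s, e in merge(ivs))


def coverage_fraction(target: Interval, ivs) -> float:
    """Fraction of ``target`` covered by the interval set."""
    s, e = target
    cov = total_length(intersect([(s, e)], ivs))
    return cov / (e - s)
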