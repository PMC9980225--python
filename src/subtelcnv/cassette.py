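"""The gene-cassette locus model and its read-based validation.

The locus is modelled as ordered, oriented segments
[flank ST array | A | B1 | I | B2 | short ST array | B2' | I' | B1' | A' |
flank ST array]; the reverse half is the reverse complement of the forward
half and the strand flip inside the short subtelomere array is the
*inversion point*.  Junction support is counted from single alignment
records spanning a boundary with a minimum overhang on both sides; because
every named junction occurs twice per tandem unit while the inversion point
occurs once, its expected spanning count is half the others' -- the
half-coverage prediction tested by ``junction_ratio_test``.

``self_align`` is an exact k-mer dotplot (both strands, chained on
diagonals); ``infer_macrostructure`` reads tandem arrays and inverted
duplications off the chained segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .simulate import CassetteSpec, encode_seq

# --------------------------------------------------------------- model

@dataclass(frozen=True)
class Segment:
    name: str
    length: int
    strand: str = "+"
    inversion_offset: int = -1   # strand-flip offset inside an ST array

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"segment {self.name}: length must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"segment {self.name}: bad strand {self.strand!r}")

    @property
    def base_name(self) -> str:
        """Family name used in junction ids: B1/B2 -> B, ST_* -> ST."""
        m = re.match(r"[A-Za-z]+", self.name)
        return m.group(0) if m else self.name


class CassetteModel:
    """Ordered abutting segments with cumulative 0-based coordinates."""

    def __init__(self, segments: Sequence[Segment], label: str = "cassette"):
        if not segments:
            raise ValueError("model needs at least one segment")
        self.segments = list(segments)
        self.label = label
        self.starts = np.concatenate(
            [[0], np.cumsum([s.length for s in self.segments])])

    @property
    def total_length(self) -> int:
        return int(self.starts[-1])

    def segment_bounds(self, i: int) -> tuple[int, int]:
        return int(self.starts[i]), int(self.starts[i + 1])

    def reversed(self) -> "CassetteModel":
        flip = {"+": "-", "-": "+"}
        segs = []
        for s in reversed(self.segments):
            inv = (s.length - s.inversion_offset
                   if s.inversion_offset >= 0 else -1)
            segs.append(Segment(s.name, s.length, flip[s.strand], inv))
        return CassetteModel(segs, self.label + "_rc")

    def to_bed(self) -> list[tuple]:
        rows = []
        for i, s in enumerate(self.segments):
            b, e = self.segment_bounds(i)
            rows.append((self.label, b, e, s.name, s.inversion_offset, s.strand))
        return rows

    @classmethod
    def from_bed(cls, rows: Iterable[tuple]) -> "CassetteModel":
        rows = sorted(rows, key=lambda r: int(r[1]))
        label = rows[0][0]
        segs, expect = [], 0
        for chrom, start, end, name, inv, strand in rows:
            start, end = int(start), int(end)
            if start != expect:
                raise ValueError("BED segments do not abut")
            segs.append(Segment(str(name), end - start, str(strand), int(inv)))
            expect = end
        return cls(segs, label)


def build_cassette_model(cassette: CassetteSpec, unit_length: int = 452,
                         full: bool = True) -> CassetteModel:
    """One tandem unit of the locus (plus the closing flank array).

    ``full=False`` gives the forward half only: [ST, A, B1, I, B2, ST].
    """
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    flank_len = sum(cassette.flank_array) * unit_length
    short_len = sum(cassette.short_array) * unit_length
    inv_off = cassette.short_array[0] * unit_length
    fwd = [Segment("A", cassette.len_a), Segment("B1", cassette.len_b1),
           Segment("I", cassette.len_i), Segment("B2", cassette.len_b2)]
    segs = [Segment("ST_flank", flank_len)] + fwd
    segs.append(Segment("ST_short", short_len,
                        inversion_offset=inv_off if full else -1))
    if full:
        segs += [Segment(s.name, s.length, "-") for s in reversed(fwd)]
        segs.append(Segment("ST_flank", flank_len))
    return CassetteModel(segs)


# ------------------------------------------------------------ junctions

@dataclass(frozen=True)
class Junction:
    id: str
    position: int
    left: str
    right: str
    left_strand: str = "+"
    right_strand: str = "+"


def enumerate_junctions(model: CassetteModel) -> list[Junction]:
    """One junction per adjacent segment pair, ids canonicalised to the
    forward-cassette reading (a boundary flanked by a reverse-strand
    segment reports the mirrored id); the strand flip inside the short
    array is the ``inversion-point``."""
    out = []
    segs = model.segments
    for i in range(1, len(segs)):
        left, right = segs[i - 1], segs[i]
        pos = int(model.starts[i])
        bl, br = left.base_name, right.base_name
        # ST arrays are mixed-strand; orientation is read off the gene
        # segments so ids survive reverse-complementing the reference
        strands = [s.strand for s in (left, right) if s.base_name != "ST"] \
            or [left.strand, right.strand]
        if "-" in strands:
            bl, br = br, bl
        out.append(Junction(f"{bl}-{br}", pos, left.name, right.name,
                            left.strand, right.strand))
    if len(segs) > 1:
        for i, s in enumerate(segs):
            if s.inversion_offset >= 0:
                pos = int(model.starts[i]) + s.inversion_offset
                out.append(Junction("inversion-point", pos, s.name, s.name,
                                    "+", "-"))
    out.sort(key=lambda j: j.position)
    return out


@dataclass
class JunctionSupport:
    junction_id: str
    count: int
    read_ids: tuple[str, ...]
    min_overhang: int

    def __post_init__(self):
        if self.count != len(self.read_ids):
            raise ValueError("count must equal the number of supporting reads")


def _alignment_arrays(alignments):
    if hasattr(alignments, "tlen"):    # CassetteAlignments
        names = [alignments.read_names[int(i)] for i in alignments.read_idx]
        return (np.asarray(alignments.start), np.asarray(alignments.end),
                names, alignments.tlen)
    ts, te, names, tlen = [], [], [], 0
    for rec in alignments:
        ts.append(rec.tstart)
        te.append(rec.tend)
        names.append(rec.qname)
        tlen = max(tlen, rec.tlen)
    return (np.asarray(ts, dtype=np.int64), np.asarray(te, dtype=np.int64),
            names, tlen)


def count_spanning_reads(alignments, junctions: Sequence[Junction],
                         min_overhang: int = 100,
                         reference_length: Optional[int] = None
                         ) -> list[JunctionSupport]:
    """Spanning-read support per junction id.

    A read supports a junction iff a single alignment record covers
    [pos - min_overhang, pos + min_overhang); junction ids with several
    positions (one per cassette half) pool their support, each read counted
    once per id.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    ts, te, names, tlen = _alignment_arrays(alignments)
    if reference_length is not None:
        tlen = reference_length
    by_id: dict[str, list[int]] = {}
    for j in junctions:
        if tlen and not (0 < j.position < tlen):
            raise ValueError(f"junction {j.id} at {j.position} outside "
                             f"reference of length {tlen}")
        by_id.setdefault(j.id, []).append(j.position)
    out = []
    for jid, positions in by_id.items():
        support: set[str] = set()
        for pos in positions:
            hit = (ts <= pos - min_overhang) & (te >= pos + min_overhang)
            support.update(names[i] for i in np.flatnonzero(hit))
        out.append(JunctionSupport(jid, len(support),
                                   tuple(sorted(support)), min_overhang))
    return out


@dataclass(frozen=True)
class RatioTest:
    ratio: float
    se: float
    consistent_with_2: bool


def junction_ratio_test(supports: Sequence[JunctionSupport],
                        inversion_id: str = "inversion-point") -> RatioTest:
    """Mean non-inversion support over inversion support, with a
    counting-noise standard error; flags whether 2 falls within 3 SE."""
    inv = [s for s in supports if s.junction_id == inversion_id]
    non = [s.count for s in supports if s.junction_id != inversion_id]
    if not inv or inv[0].count == 0:
        raise ValueError("inversion junction absent or unsupported; "
                         "ratio undefined")
    if not non:
        raise ValueError("no non-inversion junctions to compare")
    inv_count = inv[0].count
    ratio = float(np.mean(non)) / inv_count
    se = ratio * np.sqrt(1.0 / sum(non) + 1.0 / inv_count)
    return RatioTest(ratio, float(se), bool(abs(2.0 - ratio) <= 3 * se))


# ------------------------------------------------------- variant copies

@dataclass(frozen=True)
class VariantCopyEstimate:
    fraction: float
    total_copies: int
    mutant_copies: int
    se_copies: float


def estimate_variant_copies(fraction: float, total_copies: int,
                            n_reads: int = 0) -> VariantCopyEstimate:
    """Mutant copy count from a marker read fraction: m = round(f * C),
    with binomial standard error sqrt(f(1-f)/n) * C."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    m = int(round(fraction * total_copies))
    se = (np.sqrt(fraction * (1 - fraction) / n_reads) * total_copies
          if n_reads > 0 else float("nan"))
    return VariantCopyEstimate(fraction, total_copies, m, float(se))


# --------------------------------------------------------- self-alignment

@dataclass(frozen=True)
class MatchSegment:
    """Chained exact match: [start1, start1+length) vs
    [start2, start2+length) (the latter reverse-complemented when
    strand == '-')."""

    start1: int
    start2: int
    length: int
    strand: str

    @property
    def end1(self) -> int:
        return self.start1 + self.length

    @property
    def end2(self) -> int:
        return self.start2 + self.length

    @property
    def lag(self) -> int:
        return self.start2 - self.start1


def _kmer_hashes(codes: np.ndarray, k: int):
    n = len(codes)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    pow_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pow_f
    rc = (3 - win) @ pow_f[::-1]
    return fwd, rc


def _group_pairs(values_a: np.ndarray, values_b: np.ndarray):
    """All (i, j) with values_a[i] == values_b[j]."""
    order_a = np.argsort(values_a, kind="stable")
    order_b = np.argsort(values_b, kind="stable")
    va, vb = values_a[order_a], values_b[order_b]
    uniq = np.intersect1d(va, vb)
    ii, jj = [], []
    a_left = np.searchsorted(va, uniq, side="left")
    a_right = np.searchsorted(va, uniq, side="right")
    b_left = np.searchsorted(vb, uniq, side="left")
    b_right = np.searchsorted(vb, uniq, side="right")
    for al, ar, bl, br in zip(a_left, a_right, b_left, b_right):
        pa, pb = order_a[al:ar], order_b[bl:br]
        g1, g2 = np.meshgrid(pa, pb, indexing="ij")
        ii.append(g1.ravel())
        jj.append(g2.ravel())
    if not ii:
        return (np.empty(0, dtype=np.int64),) * 2
    return np.concatenate(ii), np.concatenate(jj)


def _chain(i: np.ndarray, j: np.ndarray, diag: np.ndarray, k: int,
           max_gap: int, anti: bool):
    """Greedy chaining by (anti)diagonal then position."""
    if len(i) == 0:
        return []
    order = np.lexsort((i, diag))
    i, j, diag = i[order], j[order], diag[order]
    new = np.flatnonzero((np.diff(diag) != 0) | (np.diff(i) > max_gap))
    segs = []
    for run in np.split(np.arange(len(i)), new + 1):
        i0, i1 = int(i[run[0]]), int(i[run[-1]])
        length = i1 - i0 + k
        if anti:
            start2 = int(j[run[-1]])
        else:
            start2 = i0 + int(diag[run[0]])
        segs.append((i0, start2, length))
    return segs


def self_align(sequence, k: int = 15, max_chain_gap: int = 100,
               min_segment: int = 100) -> list[MatchSegment]:
    """Exact k-mer self-matches on both strands, chained when collinear;
    the trivial forward main diagonal is excluded.  Symmetric: every
    reported segment appears in both orientations of its coordinates."""
    codes = sequence if isinstance(sequence, np.ndarray) else encode_seq(str(sequence))
    if len(codes) < k:
        raise ValueError(f"sequence shorter than k={k}")
    fwd, rc = _kmer_hashes(codes, k)

    i, j = _group_pairs(fwd, fwd)
    keep = i < j     # one triangle; mirrored below
    i, j = i[keep], j[keep]
    out: list[MatchSegment] = []
    for s1, s2, ln in _chain(i, j, j - i, k, max_chain_gap, anti=False):
        if ln >= min_segment:
            out.append(MatchSegment(s1, s2, ln, "+"))
            out.append(MatchSegment(s2, s1, ln, "+"))

    i, j = _group_pairs(fwd, rc)
    keep = i <= j
    i, j = i[keep], j[keep]
    for s1, s2, ln in _chain(i, j, i + j, k, max_chain_gap, anti=True):
        if ln >= min_segment:
            out.append(MatchSegment(s1, s2, ln, "-"))
            if s2 != s1:
                out.append(MatchSegment(s2, s1, ln, "-"))
    out.sort(key=lambda m: (m.start1, m.start2))
    return out


# -------------------------------------------------------- macrostructure

@dataclass(frozen=True)
class TandemArray:
    start: int
    end: int
    unit_length: int
    copies: int
    strand: str
    is_minimum: bool    # truncated at a sequence boundary: copies is a floor


@dataclass(frozen=True)
class InvertedDuplication:
    interval1: tuple[int, int]
    interval2: tuple[int, int]
    midpoint: float
    arm_span: int
    coverage: float


@dataclass
class Macrostructure:
    tandem_arrays: list[TandemArray] = field(default_factory=list)
    inverted_duplications: list[InvertedDuplication] = field(default_factory=list)


def infer_macrostructure(segments: Sequence[MatchSegment],
                         sequence_length: int,
                         min_copies: int = 3,
                         min_arm_fraction: float = 0.05) -> Macrostructure:
    """Read repeat macrostructure off chained self-alignment segments.

    Tandem arrays come from self-overlapping forward segments (lag <=
    length): clustered by span, the smallest lag is the unit and
    span/unit the copy count.  Inverted duplications are reverse-strand
    segments with disjoint arms covering either >= 50% of the sequence or
    arms >= ``min_arm_fraction`` of it; arrays truncated at a sequence end
    carry a minimum-copies flag.  Deterministic given its input.
    """
    tandemish = [m for m in segments
                 if m.strand == "+" and 0 < m.lag <= m.length]
    clusters: list[list[MatchSegment]] = []
    for m in sorted(tandemish, key=lambda m: m.start1):
        if clusters:
            prev = clusters[-1]
            scale = min(m.lag, min(x.lag for x in prev))
            # genuine same-array segments overlap by at least half a unit;
            # chance matches at an array boundary touch by a few bases only
            if max(x.end2 for x in prev) - m.start1 >= 0.5 * scale:
                prev.append(m)
                continue
        clusters.append([m])

    arrays: list[TandemArray] = []
    for cl in clusters:
        lag0 = min(m.lag for m in cl)
        start = min(m.start1 for m in cl)
        end = max(m.end2 for m in cl)
        copies = int(round((end - start) / lag0))
        if copies < min_copies:
            continue
        at_edge = start <= lag0 or end >= sequence_length - lag0
        arrays.append(TandemArray(start, end, lag0, copies, "+", at_edge))

    invdups: list[InvertedDuplication] = []
    rev = [m for m in segments if m.strand == "-" and m.start1 < m.start2]
    for m in rev:
        # perfect palindromes chain to seed-width arm overlap at the centre
        if m.end1 - m.start2 > max(25, 0.02 * m.length):
            continue
        cov = 2 * m.length / sequence_length
        if cov >= 0.5 or m.length >= min_arm_fraction * sequence_length:
            mid = (m.end1 + m.start2) / 2
            invdups.append(InvertedDuplication(
                (m.start1, m.end1), (m.start2, m.end2), mid, m.length, cov))
    invdups.sort(key=lambda d: -d.arm_span)

    # strand assignment: a reverse-strand link between two tandem arrays
    # marks the later one as the inverted block
    def _linked(a, lo, hi):
        ov = min(a.end, hi) - max(a.start, lo)
        return ov >= 0.5 * min(a.end - a.start, hi - lo)

    out_arrays = list(arrays)
    for m in rev:
        src = [idx for idx, a in enumerate(out_arrays)
               if _linked(a, m.start1, m.end1)]
        dst = [idx for idx, a in enumerate(out_arrays)
               if _linked(a, m.start2, m.end2)]
        for idx in dst:
            if any(s != idx for s in src):
                a = out_arrays[idx]
                out_arrays[idx] = TandemArray(a.start, a.end, a.unit_length,
                                              a.copies, "-", a.is_minimum)
    return Macrostructure(out_arrays, invdups)
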