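"""Tandem repeat detection and subtelomere relatedness.

Covers the repeat-centric half of the analysis: terminal telomere-motif
arrays, strand-wise copy counts of the subtelomeric repeat unit, global
percent identity between subtelomere sequences (gaps count against
identity), and a neighbor-joining relatedness tree on 100 - identity
distances, written as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio import Align

from .simulate import encode_seq, revcomp


@dataclass(frozen=True)
class RepeatArray:
    seqname: str
    start: int
    end: int
    unit: str
    copies_forward: int
    copies_reverse: int
    terminal: bool

    @property
    def copies(self) -> int:
        return self.copies_forward + self.copies_reverse


# ------------------------------------------------------- telomere arrays

def _motif_positions(codes: np.ndarray, motif: np.ndarray, allowed: int) -> np.ndarray:
    if len(codes) < len(motif):
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, len(motif))
    mism = (win != motif).sum(axis=1)
    return np.flatnonzero(mism <= allowed)


def _partial_end_extension(codes, motif, start, end, allowed_frac):
    """Extend the array span over degenerate partial copies at sequence
    ends (span only; copy count untouched)."""
    m = len(motif)
    if 0 < start < m:
        part = codes[:start]
        if (part != motif[m - start:]).sum() <= int(allowed_frac * start):
            start = 0
    tail = len(codes) - end
    if 0 < tail < m:
        part = codes[end:]
        if (part != motif[:tail]).sum() <= int(allowed_frac * tail):
            end = len(codes)
    return start, end


def find_telomere_arrays(sequence: str, motif: str = "TTTAGGG",
                         min_copies: int = 10, max_offset: int = 1_000,
                         max_mismatch_frac: float = 0.1,
                         seqname: str = "seq") -> list[RepeatArray]:
    """Maximal tandem runs of the telomere motif on either strand.

    A run is consecutive motif-length steps each within the per-copy
    mismatch tolerance; ``terminal`` marks runs starting or ending within
    ``max_offset`` of a sequence end.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    codes = encode_seq(sequence)
    m = len(motif)
    allowed = int(max_mismatch_frac * m)
    out = []
    for strand, mseq in (("+", motif), ("-", revcomp(motif))):
        mcodes = encode_seq(mseq)
        pos = _motif_positions(codes, mcodes, allowed)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) != m)
        for run in np.split(pos, breaks + 1):
            # keep only phase-locked runs (consecutive step == motif length)
            copies = len(run)
            if copies < min_copies:
                continue
            start, end = int(run[0]), int(run[-1]) + m
            start, end = _partial_end_extension(codes, mcodes, start, end,
                                                max_mismatch_frac)
            terminal = start <= max_offset or len(codes) - end <= max_offset
            out.append(RepeatArray(
                seqname, start, end, motif,
                copies if strand == "+" else 0,
                copies if strand == "-" else 0, terminal))
    out.sort(key=lambda a: a.start)
    return out


# --------------------------------------------------- subtelomeric units

def _scan_units(seq: str, unit: str, max_edits: int, slack: int):
    """Greedy anchored scan: non-overlapping placements of ``unit`` in
    ``seq``, each within ``max_edits``; anchored at the best-scoring
    occurrence and stepped unit-by-unit, then repeated on the uncovered
    flanks.  Returns (count, [(start, end), ...])."""
    u = len(unit)
    n = len(seq)
    if u > n:
        return 0, []
    hits: list[tuple[int, int]] = []

    def scan_region(lo: int, hi: int) -> None:
        if hi - lo < u - max_edits:
            return
        region = seq[lo:hi]
        res = edlib.align(unit, region, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            return
        a_start, a_end = res["locations"][0]
        a_start, a_end = lo + a_start, lo + a_end + 1
        placements = [(a_start, a_end)]
        # walk right
        cur = a_end
        while cur + u - max_edits <= hi:
            w = seq[cur:min(cur + u + slack, hi)]
            r = edlib.align(unit, w, mode="HW", task="locations", k=max_edits)
            if r["editDistance"] < 0 or r["locations"][0][0] > slack:
                break
            s, e = r["locations"][0]
            placements.append((cur + s, cur + e + 1))
            cur = cur + e + 1
        # walk left
        cur = a_start
        while cur - (u - max_edits) >= lo:
            w0 = max(lo, cur - u - slack)
            w = seq[w0:cur]
            r = edlib.align(unit, w, mode="HW", task="locations", k=max_edits)
            if r["editDistance"] < 0 or len(w) - (r["locations"][0][1] + 1) > slack:
                break
            s, e = r["locations"][0]
            placements.append((w0 + s, w0 + e + 1))
            cur = w0 + s
        placements.sort()
        hits.extend(placements)
        scan_region(lo, placements[0][0])
        scan_region(placements[-1][1], hi)

    scan_region(0, n)
    hits.sort()
    return len(hits), hits


def count_subtelomeric_units(sequence: str, unit: str,
                             min_identity: float = 90.0
                             ) -> tuple[int, int, list[tuple[int, int, str]]]:
    """Strand-wise copy counts of the subtelomere unit.

    Placements are greedy, non-overlapping and phase-anchored at the best
    occurrence; a placement counts if its edit distance keeps identity at
    or above ``min_identity``.  Returns (copies_forward, copies_reverse,
    [(start, end, strand), ...]).
    """
    if len(unit) < 50:
        raise ValueError("unit must be >= 50 bp")
    if len(unit) > len(sequence):
        return 0, 0, []
    max_edits = int((1 - min_identity / 100.0) * len(unit))
    slack = max(5, len(unit) // 20)
    n_f, hits_f = _scan_units(sequence, unit, max_edits, slack)
    n_r, hits_r = _scan_units(sequence, revcomp(unit), max_edits, slack)
    ivs = [(s, e, "+") for s, e in hits_f] + [(s, e, "-") for s, e in hits_r]
    ivs.sort()
    return n_f, n_r, ivs


# ------------------------------------------------------ percent identity

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def pairwise_identity(seq_a: str, seq_b: str, try_reverse: bool = True) -> float:
    """Global-alignment percent identity (matches / alignment columns);
    with ``try_reverse`` the better of the forward and reverse-complement
    orientations of ``seq_b`` is scored."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    al = _aligner()
    cands = [seq_b]
    if try_reverse:
        cands.append(revcomp(seq_b))
    best, best_score = None, -np.inf
    for cand in cands:
        score = al.score(seq_a, cand)
        if score > best_score:
            best, best_score = cand, score
    aln = al.align(seq_a, best)[0]
    c = aln.counts()
    columns = c.gaps + c.identities + c.mismatches
    return 100.0 * c.identities / columns


@dataclass
class IdentityMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("diagonal must be exactly 100")
        if m.min() < 0 or m.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.matrix = m

    @classmethod
    def from_sequences(cls, sequences: dict[str, str],
                       try_reverse: bool = True) -> "IdentityMatrix":
        labels = list(sequences)
        n = len(labels)
        m = np.full((n, n), 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                pid = pairwise_identity(sequences[labels[i]],
                                        sequences[labels[j]], try_reverse)
                m[i, j] = m[j, i] = pid
        return cls(labels, m)

    def to_distances(self) -> np.ndarray:
        return 100.0 - self.matrix


# ------------------------------------------------------------------ tree

class TreeNode:
    def __init__(self, label: Optional[str] = None,
                 children: Optional[list[tuple["TreeNode", float]]] = None):
        self.label = label
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, precision: int = 6) -> str:
        return self._nwk(precision) + ";"

    def _nwk(self, p: int) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(f"{c._nwk(p)}:{bl:.{p}f}" for c, bl in self.children)
        return f"({inner})"

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (tests the additive-exactness of NJ)."""
        depths: dict[str, list[tuple[int, float]]] = {}

        def walk(node, path):
            if node.is_leaf:
                depths[node.label] = path
                return
            for c, bl in node.children:
                walk(c, path + [(id(c), bl)])

        walk(self, [])
        out = {}
        labels = sorted(depths)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                pa, pb = depths[a], depths[b]
                k = 0
                while k < len(pa) and k < len(pb) and pa[k][0] == pb[k][0]:
                    k += 1
                d = sum(x[1] for x in pa[k:]) + sum(x[1] for x in pb[k:])
                out[(a, b)] = out[(b, a)] = d
        return out


def build_tree(matrix: IdentityMatrix) -> TreeNode:
    """Neighbor joining on distances 100 - identity.

    Deterministic lowest-index tie-breaking, negative branch lengths
    clamped to zero; NJ reconstructs any additive distance matrix exactly.
    """
    labels = matrix.labels
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    D = matrix.to_distances().astype(float)
    nodes = [TreeNode(l) for l in labels]
    if len(labels) == 2:
        d = D[0, 1]
        return TreeNode(children=[(nodes[0], max(d / 2, 0.0)),
                                  (nodes[1], max(d / 2, 0.0))])
    active = list(range(len(labels)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # row-major: lowest index wins ties
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        new = TreeNode(children=[(nodes[active[i]], max(li, 0.0)),
                                 (nodes[active[j]], max(lj, 0.0))])
        dk = 0.5 * (sub[i, :] + sub[j, :] - dij)
        nodes.append(new)
        newD = np.zeros((D.shape[0] + 1, D.shape[1] + 1))
        newD[:-1, :-1] = D
        for k, ak in enumerate(active):
            newD[-1, ak] = newD[ak, -1] = dk[k]
        D = newD
        ni = D.shape[0] - 1
        active = [a for idx, a in enumerate(active) if idx not in (i, j)] + [ni]
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    return TreeNode(children=[(nodes[a], max(la, 0.0)),
                              (nodes[b], max(lb, 0.0)),
                              (nodes[c], max(lc, 0.0))])
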