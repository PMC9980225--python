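"""Synthetic genomes, long reads, cDNA reads and count matrices with planted truth.

The generator emulates the structural situation the pipeline is built to
detect: a diploid grass-like genome whose chromosomes end in telomeric
``(TTTAGGG)n`` arrays and tandem subtelomeric repeat units, and a resistant
haplotype carrying a subtelomeric gene cassette

    [flank ST array | A | B1 | I | B2 | short ST array (inverted) |
     B2' | I' | B1' | A']

amplified in tandem, where A and B1+B2 are copies of two single-copy native
regions and I is novel sequence.  Susceptible haplotypes carry only the
native single-copy regions.  Every planted feature is recorded, so depth
calling, junction counting and repeat analysis can be scored against truth.

Reads are placed uniformly on haplotypes; alignment is replaced by exact
truth projection onto the susceptible reference (``project_to_reference``)
or onto the one-unit cassette model (``project_to_cassette``).  Projection
drops subtelomere-array and Region-I bases in reference space, the way a
repeat-aware aligner discards multimapping reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import PafRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def encode_seq(s: str) -> np.ndarray:
    """DNA string -> uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(s: str) -> str:
    return decode_seq(revcomp_codes(encode_seq(s)))


# ------------------------------------------------------------------- specs

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the background genome.

    Each chromosome is [telomere | subtelomere array | background |
    subtelomere array (reverse) | telomere (reverse)].  The subtelomere
    unit is a random sequence of ``subtelomere_unit_length`` drawn from
    ``seed`` unless given explicitly.
    """

    chromosomes: tuple[tuple[str, int], ...]
    telomere_motif: str = "TTTAGGG"
    telomere_copies_per_end: int = 100
    subtelomere_unit: Optional[str] = None
    subtelomere_unit_length: int = 452
    subtelomere_copies_per_end: int = 25
    seed: int = 0

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
        if not self.telomere_motif or set(self.telomere_motif) - set("ACGT"):
            raise ValueError("telomere motif must be a non-empty ACGT string")
        if self.subtelomere_unit is not None:
            if not self.subtelomere_unit or set(self.subtelomere_unit) - set("ACGT"):
                raise ValueError("subtelomere unit must be a non-empty ACGT string")
        elif self.subtelomere_unit_length <= 0:
            raise ValueError("subtelomere unit length must be > 0")


@dataclass(frozen=True)
class CassetteSpec:
    """Cassette locus geometry.

    ``short_array``/``flank_array`` are (forward, reverse) copy counts of the
    subtelomere unit; the short array separates the forward and reverse
    cassette halves (its strand flip is the inversion point), the flank
    array precedes every tandem unit and closes the locus.
    ``insertion_site`` is (chromosome, offset from the 3' end).
    """

    len_a: int = 35_000
    len_b1: int = 5_000
    len_b2: int = 36_000
    len_i: int = 3_396
    short_array: tuple[int, int] = (12, 31)
    flank_array: tuple[int, int] = (43, 294)
    tandem_copies: int = 10
    insertion_site: tuple[str, int] = ("Chr3", 20_000)
    native_a: tuple[str, int] = ("Chr3", 1_666_750)
    native_b: tuple[str, int] = ("Chr3", 2_719_750)
    # (segment, offset, ref_base-or-None, alt_base, n_mutant_copies)
    marker_variants: tuple = ()

    def __post_init__(self):
        for nm, v in (("A", self.len_a), ("B1", self.len_b1),
                      ("B2", self.len_b2), ("I", self.len_i)):
            if v < 1:
                raise ValueError(f"segment {nm}: length must be >= 1")
        if self.tandem_copies < 0:
            raise ValueError("tandem_copies must be >= 0")
        for nm, arr in (("short_array", self.short_array),
                        ("flank_array", self.flank_array)):
            if min(arr) < 0 or max(arr) < 1:
                raise ValueError(f"{nm}: copy counts must be >= 0 with >= 1 total")

    @property
    def len_b(self) -> int:
        return self.len_b1 + self.len_b2


@dataclass(frozen=True)
class IndividualDesign:
    """Tandem copy count carried by each of the two haplotypes (0 = none)."""

    name: str
    hap_copies: tuple[int, int] = (0, 0)

    @property
    def group(self) -> str:
        return "susceptible" if max(self.hap_copies) == 0 else "resistant"

    @property
    def zygosity(self) -> str:
        a, b = self.hap_copies
        if a == 0 and b == 0:
            return "susceptible"
        return "hom" if a > 0 and b > 0 else "het"


def standard_cohort(tandem_copies: int = 10, n_resistant: int = 8,
                    n_susceptible: int = 8, het_index: Optional[int] = None,
                    het_copies: Optional[int] = None) -> list[IndividualDesign]:
    """The resequencing cohort layout: homozygous-amplified resistant
    individuals plus one heterozygote carrying a shorter array on a single
    haplotype (its depth sits near one third of the homozygotes', the
    signature by which the het is recognised), and susceptible individuals.
    """
    if het_index is None:
        het_index = n_resistant - 1 if n_resistant >= 3 else -1
    if het_copies is None:
        het_copies = max(1, round(0.6 * tandem_copies))
    out = []
    for i in range(n_resistant):
        if i == het_index:
            out.append(IndividualDesign(f"R{i + 1}", (het_copies, 0)))
        else:
            out.append(IndividualDesign(f"R{i + 1}", (tandem_copies, tandem_copies)))
    for i in range(n_susceptible):
        out.append(IndividualDesign(f"S{i + 1}", (0, 0)))
    return out


def desk_scale(seed: int = 0, tandem_copies: int = 10) -> tuple[GenomeSpec, CassetteSpec]:
    """Preset with segment lengths and flank-array copies shrunk 10x so the
    full pipeline runs in seconds; structure is otherwise identical."""
    spec = GenomeSpec(
        chromosomes=(("Chr1", 180_000), ("Chr2", 160_000), ("Chr3", 160_000)),
        seed=seed)
    cassette = CassetteSpec(
        len_a=3_500, len_b1=500, len_b2=3_600, len_i=340,
        short_array=(12, 31), flank_array=(4, 29),
        tandem_copies=tandem_copies,
        insertion_site=("Chr3", 20_000),
        native_a=("Chr3", 40_000), native_b=("Chr3", 55_000))
    return spec, cassette


def paper_scale(seed: int = 0, tandem_copies: int = 10) -> tuple[GenomeSpec, CassetteSpec]:
    """Full-size segment lengths and array copy counts; native regions sit at
    their published chromosome-3 coordinates."""
    spec = GenomeSpec(
        chromosomes=(("Chr1", 1_000_000), ("Chr2", 1_000_000), ("Chr3", 3_000_000)),
        seed=seed)
    cassette = CassetteSpec(tandem_copies=tandem_copies)
    return spec, cassette


# ----------------------------------------------------------------- genome

# piece kinds
_REF, _ST, _SEG_A, _SEG_B1, _SEG_B2, _SEG_I = range(6)
_SEG_NAMES = {_SEG_A: "A", _SEG_B1: "B1", _SEG_B2: "B2", _SEG_I: "I"}


@dataclass
class _Piece:
    kind: int
    length: int
    ref_chrom: str = ""
    ref_start: int = 0
    strand: str = "+"
    copy_index: int = -1
    st_fwd: int = 0
    st_rev: int = 0
    inversion_offset: int = -1   # within-piece offset of the strand flip, ST only

    @property
    def mapped(self) -> bool:
        return self.kind in (_REF, _SEG_A, _SEG_B1, _SEG_B2)


class GenomeTruth:
    """Synthetic diploid genomes plus complete planted-feature truth."""

    def __init__(self, spec: GenomeSpec, cassette: CassetteSpec,
                 cohort: Sequence[IndividualDesign]):
        self.spec = spec
        self.cassette = cassette
        self.cohort = list(cohort)
        names = [d.name for d in self.cohort]
        if len(set(names)) != len(names):
            raise ValueError("duplicate individual names in cohort")
        self._seq_cache: dict[tuple[str, str], np.ndarray] = {}
        self._build()

    # -- construction -------------------------------------------------

    def _build(self) -> None:
        spec, cas = self.spec, self.cassette
        rng = np.random.default_rng(spec.seed)
        self.telomere = encode_seq(spec.telomere_motif)
        if spec.subtelomere_unit is not None:
            self.unit = encode_seq(spec.subtelomere_unit)
        else:
            self.unit = rng.integers(0, 4, spec.subtelomere_unit_length,
                                     dtype=np.uint8)
        self.iseq = rng.integers(0, 4, cas.len_i, dtype=np.uint8)

        self.reference_names = [n for n, _ in spec.chromosomes]
        self.reference_lengths = {n: l for n, l in spec.chromosomes}

        tel_len = len(self.telomere) * spec.telomere_copies_per_end
        st_len = len(self.unit) * spec.subtelomere_copies_per_end
        self._end_block = tel_len + st_len  # telomere+subtelomere at each end
        self.base_sequences: dict[str, np.ndarray] = {}
        base_features = []
        for name, length in spec.chromosomes:
            if length < 2 * self._end_block + 1000:
                raise ValueError(
                    f"chromosome {name}: too short for telomere/subtelomere blocks")
            seq = np.empty(length, dtype=np.uint8)
            tel5 = np.tile(self.telomere, spec.telomere_copies_per_end)
            st5 = np.tile(self.unit, spec.subtelomere_copies_per_end)
            st3 = np.tile(revcomp_codes(self.unit), spec.subtelomere_copies_per_end)
            tel3 = np.tile(revcomp_codes(self.telomere), spec.telomere_copies_per_end)
            seq[:tel_len] = tel5
            seq[tel_len:tel_len + st_len] = st5
            bg_len = length - 2 * self._end_block
            seq[tel_len + st_len:tel_len + st_len + bg_len] = rng.integers(
                0, 4, bg_len, dtype=np.uint8)
            seq[length - self._end_block:length - tel_len] = st3
            seq[length - tel_len:] = tel3
            self.base_sequences[name] = seq
            if spec.telomere_copies_per_end:
                base_features.append((name, 0, tel_len, "telomere_array", "+",
                                      spec.telomere_copies_per_end, 0))
                base_features.append((name, length - tel_len, length,
                                      "telomere_array", "-", 0,
                                      spec.telomere_copies_per_end))
            if spec.subtelomere_copies_per_end:
                base_features.append((name, tel_len, tel_len + st_len,
                                      "subtelomere_array", "+",
                                      spec.subtelomere_copies_per_end, 0))
                base_features.append((name, length - self._end_block,
                                      length - tel_len, "subtelomere_array", "-",
                                      0, spec.subtelomere_copies_per_end))
        self._base_features = base_features

        # native regions must fit inside the background of their chromosomes
        for label, (chrom, start), seg_len in (
                ("native A", cas.native_a, cas.len_a),
                ("native B", cas.native_b, cas.len_b)):
            if chrom not in self.reference_lengths:
                raise ValueError(f"{label}: unknown chromosome {chrom!r}")
            length = self.reference_lengths[chrom]
            if start < self._end_block or start + seg_len > length - self._end_block:
                raise ValueError(
                    f"{label}: [{start}, {start + seg_len}) exceeds the background "
                    f"of {chrom} (segment lengths exceed chromosome bounds)")

        ins_chrom, ins_offset = cas.insertion_site
        if ins_chrom not in self.reference_lengths:
            raise ValueError(f"insertion site: unknown chromosome {ins_chrom!r}")
        ins_len = self.reference_lengths[ins_chrom]
        self.insertion_pos = ins_len - ins_offset
        if ins_offset < 0 or self.insertion_pos < 0:
            raise ValueError("insertion site outside chromosome bounds")
        if (self.insertion_pos < tel_len or self.insertion_pos > ins_len - tel_len):
            raise ValueError(
                "insertion site overlaps a telomere array; place the cassette "
                "inside the subtelomere or chromosome body")
        a_chrom, a_start = cas.native_a
        b_chrom, b_start = cas.native_b
        for label, chrom, s, e in (("native A", a_chrom, a_start, a_start + cas.len_a),
                                   ("native B", b_chrom, b_start, b_start + cas.len_b)):
            if chrom == ins_chrom and s < self.insertion_pos < e:
                raise ValueError(f"insertion site falls inside {label}")

        # distinct haplotypes required by the cohort
        self.haplotypes: dict[str, dict[str, list[_Piece]]] = {}
        self._hap_of: dict[str, tuple[str, str]] = {}
        for d in self.cohort:
            haps = tuple(self._hap_name(t) for t in d.hap_copies)
            self._hap_of[d.name] = haps
            for t, h in zip(d.hap_copies, haps):
                if h not in self.haplotypes:
                    self.haplotypes[h] = self._build_haplotype(t)

        self._features = self._collect_features()
        self.truth_cnv = self._collect_truth_cnv()
        self._piece_arrays_cache: dict[tuple[str, str], dict] = {}

    @staticmethod
    def _hap_name(tandem: int) -> str:
        return "S" if tandem == 0 else f"R{tandem}"

    def _st_piece(self, fwd: int, rev: int, inversion: bool = False) -> _Piece:
        u = len(self.unit)
        return _Piece(_ST, (fwd + rev) * u, st_fwd=fwd, st_rev=rev,
                      inversion_offset=fwd * u if inversion else -1)

    def _cassette_pieces(self, tandem: int) -> list[_Piece]:
        cas = self.cassette
        a_chrom, a_start = cas.native_a
        b_chrom, b_start = cas.native_b
        pieces: list[_Piece] = []
        for copy in range(tandem):
            pieces.append(self._st_piece(*cas.flank_array))
            fwd = [
                _Piece(_SEG_A, cas.len_a, a_chrom, a_start, "+", copy),
                _Piece(_SEG_B1, cas.len_b1, b_chrom, b_start, "+", copy),
                _Piece(_SEG_I, cas.len_i, strand="+", copy_index=copy),
                _Piece(_SEG_B2, cas.len_b2, b_chrom, b_start + cas.len_b1,
                       "+", copy),
            ]
            pieces.extend(fwd)
            pieces.append(self._st_piece(*cas.short_array, inversion=True))
            pieces.extend(
                _Piece(p.kind, p.length, p.ref_chrom, p.ref_start, "-", copy)
                for p in reversed(fwd))
        pieces.append(self._st_piece(*cas.flank_array))
        return pieces

    def _build_haplotype(self, tandem: int) -> dict[str, list[_Piece]]:
        chroms: dict[str, list[_Piece]] = {}
        ins_chrom = self.cassette.insertion_site[0]
        for name, length in self.spec.chromosomes:
            if tandem > 0 and name == ins_chrom:
                pieces = [_Piece(_REF, self.insertion_pos, name, 0)]
                pieces += self._cassette_pieces(tandem)
                pieces.append(_Piece(_REF, length - self.insertion_pos, name,
                                     self.insertion_pos))
            else:
                pieces = [_Piece(_REF, length, name, 0)]
            chroms[name] = pieces
        return chroms

    # -- truth tables --------------------------------------------------

    def _collect_features(self) -> pd.DataFrame:
        rows = []
        for hap, chroms in self.haplotypes.items():
            for chrom, pieces in chroms.items():
                pos = 0
                for p in pieces:
                    if p.kind == _REF:
                        for (c, s, e, typ, strand, cf, cr) in self._base_features:
                            if c == chrom and p.ref_start <= s and e <= p.ref_start + p.length:
                                off = pos - p.ref_start
                                rows.append((hap, chrom, s + off, e + off, typ,
                                             typ, strand, -1, cf, cr))
                    elif p.kind == _ST:
                        rows.append((hap, chrom, pos, pos + p.length,
                                     "subtelomere_array", "ST", "+", -1,
                                     p.st_fwd, p.st_rev))
                    else:
                        rows.append((hap, chrom, pos, pos + p.length,
                                     "cassette_segment", _SEG_NAMES[p.kind],
                                     p.strand, p.copy_index, 0, 0))
                    pos += p.length
        return pd.DataFrame(rows, columns=[
            "hap", "chrom", "start", "end", "type", "name", "strand",
            "copy_index", "copies_fwd", "copies_rev"])

    def _collect_truth_cnv(self) -> dict[str, list[dict]]:
        cas = self.cassette
        out: dict[str, list[dict]] = {}
        for d in self.cohort:
            total_tandem = sum(d.hap_copies)
            if total_tandem == 0:
                out[d.name] = []
                continue
            copies = 2 + 2 * total_tandem   # native pair + fwd/rev per unit
            out[d.name] = [
                {"region": "A", "chrom": cas.native_a[0],
                 "start": cas.native_a[1], "end": cas.native_a[1] + cas.len_a,
                 "copies": copies},
                {"region": "B", "chrom": cas.native_b[0],
                 "start": cas.native_b[1], "end": cas.native_b[1] + cas.len_b,
                 "copies": copies},
            ]
        return out

    @property
    def features(self) -> pd.DataFrame:
        return self._features

    # -- lookups -------------------------------------------------------

    def haplotypes_of(self, individual: str) -> tuple[str, str]:
        return self._hap_of[individual]

    def haplotype_lengths(self, hap: str) -> dict[str, int]:
        return {c: sum(p.length for p in ps)
                for c, ps in self.haplotypes[hap].items()}

    def locus_params(self, hap: str) -> Optional[dict]:
        """Cassette locus geometry on a haplotype: start, unit length, flank
        length and copy count, in haplotype coordinates."""
        cas = self.cassette
        chrom = cas.insertion_site[0]
        pieces = self.haplotypes[hap][chrom]
        if len(pieces) == 1:
            return None
        flank_len = (cas.flank_array[0] + cas.flank_array[1]) * len(self.unit)
        n_units = (len(pieces) - 3) // 10
        unit_len = flank_len + cas.len_a + cas.len_b1 + cas.len_i + cas.len_b2 \
            + (cas.short_array[0] + cas.short_array[1]) * len(self.unit) \
            + cas.len_b2 + cas.len_i + cas.len_b1 + cas.len_a
        return {"chrom": chrom, "start": self.insertion_pos,
                "unit_len": unit_len, "flank_len": flank_len,
                "n_units": n_units,
                "end": self.insertion_pos + n_units * unit_len + flank_len}

    # -- sequence ------------------------------------------------------

    def _piece_seq(self, p: _Piece) -> np.ndarray:
        if p.kind == _REF:
            return self.base_sequences[p.ref_chrom][p.ref_start:p.ref_start + p.length]
        if p.kind == _ST:
            seq = np.concatenate([np.tile(self.unit, p.st_fwd),
                                  np.tile(revcomp_codes(self.unit), p.st_rev)]) \
                if p.st_rev else np.tile(self.unit, p.st_fwd)
            return seq
        if p.kind == _SEG_I:
            base = self.iseq.copy()
        else:
            src = self.base_sequences[p.ref_chrom]
            base = src[p.ref_start:p.ref_start + p.length].copy()
        base = self._apply_markers(p, base)
        return revcomp_codes(base) if p.strand == "-" else base

    def _apply_markers(self, p: _Piece, seq: np.ndarray) -> np.ndarray:
        for seg, offset, ref_base, alt_base, n_mut in self.cassette.marker_variants:
            if _SEG_NAMES.get(p.kind) != seg or p.copy_index >= n_mut or p.copy_index < 0:
                continue
            if offset >= p.length:
                raise ValueError(f"marker offset {offset} outside segment {seg}")
            if ref_base is not None and seq[offset] != _CODE[ord(ref_base)]:
                raise ValueError(f"marker in {seg}: reference base mismatch")
            seq = seq.copy()
            seq[offset] = _CODE[ord(alt_base)]
        return seq

    def sequence(self, hap: str, chrom: str) -> np.ndarray:
        key = (hap, chrom)
        if key not in self._seq_cache:
            self._seq_cache[key] = np.concatenate(
                [self._piece_seq(p) for p in self.haplotypes[hap][chrom]])
        return self._seq_cache[key]

    def sequence_str(self, hap: str, chrom: str) -> str:
        return decode_seq(self.sequence(hap, chrom))

    def reference_sequences(self) -> dict[str, str]:
        return {n: decode_seq(s) for n, s in self.base_sequences.items()}

    def haplotype_sequences(self, hap: str) -> dict[str, str]:
        return {f"{hap}|{c}": self.sequence_str(hap, c)
                for c in self.haplotypes[hap]}

    # -- piece tables for projection ----------------------------------

    def piece_arrays(self, hap: str, chrom: str) -> dict:
        key = (hap, chrom)
        if key not in self._piece_arrays_cache:
            pieces = self.haplotypes[hap][chrom]
            bounds = np.zeros(len(pieces) + 1, dtype=np.int64)
            np.cumsum([p.length for p in pieces], out=bounds[1:])
            self._piece_arrays_cache[key] = {
                "bounds": bounds,
                "mapped": np.array([p.mapped for p in pieces]),
                "ref_chrom": np.array(
                    [self.reference_names.index(p.ref_chrom) if p.mapped else -1
                     for p in pieces], dtype=np.int64),
                "ref_start": np.array([p.ref_start for p in pieces], dtype=np.int64),
                "strand": np.array([p.strand == "-" for p in pieces]),
            }
        return self._piece_arrays_cache[key]


def build_genome(spec: GenomeSpec, cassette: CassetteSpec,
                 cohort: Sequence[IndividualDesign]) -> GenomeTruth:
    """Construct the cohort's diploid genomes with full planted truth."""
    return GenomeTruth(spec, cassette, cohort)


# ------------------------------------------------------------------- reads

@dataclass(frozen=True)
class ReadParams:
    """Long-read simulation parameters (HiFi-like defaults)."""

    depth: float = 30.0
    mean_length: float = 5_000.0
    length_sigma: float = 0.3        # log-scale spread of the log-normal
    sub_rate: float = 0.001
    ins_rate: float = 0.0005
    del_rate: float = 0.0005
    min_length: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for nm in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, nm)
            if not 0 <= v < 1:
                raise ValueError(f"{nm} must be in [0, 1)")
        if self.mean_length <= 0 or self.length_sigma < 0:
            raise ValueError("mean_length must be > 0 and length_sigma >= 0")


class ReadSet:
    """Simulated reads for one individual: truth placements in haplotype
    coordinates (0-based half-open); sequences materialised on demand."""

    def __init__(self, genome: GenomeTruth, individual: str, params: ReadParams,
                 hap_names, hap_idx, chrom_names, chrom_idx, start, end, strand):
        self.genome = genome
        self.individual = individual
        self.params = params
        self.hap_names = list(hap_names)
        self.chrom_names = list(chrom_names)
        self.hap_idx = hap_idx
        self.chrom_idx = chrom_idx
        self.start = start
        self.end = end
        self.strand = strand
        self.names = [f"{individual}/read{i}" for i in range(len(start))]

    def __len__(self) -> int:
        return len(self.start)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def total_bases(self) -> int:
        return int(self.lengths.sum())

    def placements_df(self) -> pd.DataFrame:
        return pd.DataFrame({
            "read": self.names,
            "hap": [self.hap_names[i] for i in self.hap_idx],
            "chrom": [self.chrom_names[i] for i in self.chrom_idx],
            "start": self.start, "end": self.end,
            "strand": np.where(self.strand, "-", "+")})

    def sequences(self) -> Iterable[tuple[str, str]]:
        """Yield (name, sequence) with the error model applied; deterministic
        for a fixed seed."""
        rng = np.random.default_rng((self.params.seed, 0xE44))
        p = self.params
        for i in range(len(self)):
            hap = self.hap_names[self.hap_idx[i]]
            chrom = self.chrom_names[self.chrom_idx[i]]
            codes = self.genome.sequence(hap, chrom)[self.start[i]:self.end[i]]
            if self.strand[i]:
                codes = revcomp_codes(codes)
            codes = _apply_errors(codes, p.sub_rate, p.ins_rate, p.del_rate, rng)
            yield self.names[i], decode_seq(codes)

    def to_fastq(self, path) -> None:
        from .io import write_fastq
        write_fastq(path, ((n, s, "I" * len(s)) for n, s in self.sequences()))

    def truth_paf_records(self) -> list[PafRecord]:
        lens = {h: self.genome.haplotype_lengths(h) for h in self.hap_names}
        out = []
        for i in range(len(self)):
            hap = self.hap_names[self.hap_idx[i]]
            chrom = self.chrom_names[self.chrom_idx[i]]
            span = int(self.end[i] - self.start[i])
            out.append(PafRecord(
                self.names[i], span, 0, span, "-" if self.strand[i] else "+",
                f"{hap}|{chrom}", lens[hap][chrom],
                int(self.start[i]), int(self.end[i]), span, span, 60))
        return out


def _apply_errors(codes: np.ndarray, sub: float, ins: float, dele: float,
                  rng: np.random.Generator) -> np.ndarray:
    if sub == 0 and ins == 0 and dele == 0:
        return codes
    n = len(codes)
    out = codes.copy()
    k = rng.binomial(n, sub)
    if k:
        pos = rng.choice(n, size=k, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
    if dele:
        keep = rng.random(n) >= dele
        out = out[keep]
    if ins:
        m = rng.binomial(len(out) + 1, ins)
        if m:
            at = np.sort(rng.integers(0, len(out) + 1, size=m))
            out = np.insert(out, at, rng.integers(0, 4, size=m).astype(np.uint8))
    return out


def simulate_long_reads(genome: GenomeTruth, individual: str,
                        params: ReadParams) -> ReadSet:
    """Uniformly placed long reads over both haplotypes of one individual.

    ``depth`` is total coverage over the individual's full (diploid)
    haplotype sequence; read lengths are log-normal with the configured
    mean, truncated to [min_length, chromosome length] and clipped at
    chromosome ends.
    """
    rng = np.random.default_rng((params.seed, hash(individual) & 0x7FFFFFFF))
    haps = genome.haplotypes_of(individual)
    hap_names = sorted(set(haps))
    units = []   # (hap_i, chrom_i, length)
    chrom_names = genome.reference_names
    for h in haps:   # both haplotypes, even when identical
        lens = genome.haplotype_lengths(h)
        hi = hap_names.index(h)
        for ci, c in enumerate(chrom_names):
            units.append((hi, ci, lens[c]))
    lengths = np.array([u[2] for u in units], dtype=np.int64)
    total = int(lengths.sum())
    n_reads = max(1, int(round(params.depth * total / params.mean_length)))
    alloc = rng.multinomial(n_reads, lengths / total)

    mu = np.log(params.mean_length) - 0.5 * params.length_sigma ** 2
    hap_idx, chrom_idx, starts, ends = [], [], [], []
    warned = False
    for (hi, ci, L), k in zip(units, alloc):
        if k == 0:
            continue
        if params.mean_length > L and not warned:
            warnings.warn("mean read length exceeds a chromosome length; "
                          "reads truncated at sequence ends")
            warned = True
        s = rng.integers(0, L, size=k)
        rl = np.exp(rng.normal(mu, params.length_sigma, size=k))
        rl = np.clip(rl, min(params.min_length, L), L).astype(np.int64)
        e = np.minimum(s + rl, L)
        hap_idx.append(np.full(k, hi)); chrom_idx.append(np.full(k, ci))
        starts.append(s); ends.append(e)
    hap_idx = np.concatenate(hap_idx); chrom_idx = np.concatenate(chrom_idx)
    starts = np.concatenate(starts); ends = np.concatenate(ends)
    strand = rng.random(len(starts)) < 0.5
    return ReadSet(genome, individual, params, hap_names, hap_idx,
                   chrom_names, chrom_idx, starts, ends, strand)


# -------------------------------------------------------------- projection

class RefAlignments:
    """Read pieces projected onto the susceptible reference (exact truth
    alignment); subtelomere-array and Region-I bases are unmapped."""

    def __init__(self, ref_names, ref_lengths, chrom_idx, start, end,
                 read_idx, read_names, strand):
        self.ref_names = list(ref_names)
        self.ref_lengths = ref_lengths
        self.chrom_idx = chrom_idx
        self.start = start
        self.end = end
        self.read_idx = read_idx
        self.read_names = read_names
        self.strand = strand

    def __len__(self):
        return len(self.start)

    def total_aligned_bases(self) -> int:
        return int((self.end - self.start).sum())

    def to_paf_records(self) -> list[PafRecord]:
        out = []
        qoff: dict[int, int] = {}
        for i in range(len(self)):
            ri = int(self.read_idx[i])
            span = int(self.end[i] - self.start[i])
            q0 = qoff.get(ri, 0)
            qoff[ri] = q0 + span
            tname = self.ref_names[self.chrom_idx[i]]
            out.append(PafRecord(
                self.read_names[ri], qoff[ri], q0, q0 + span,
                "-" if self.strand[i] else "+", tname,
                self.ref_lengths[tname], int(self.start[i]), int(self.end[i]),
                span, span, 60))
        return out


def project_to_reference(genome: GenomeTruth, reads: ReadSet) -> RefAlignments:
    chrom_idx_out, start_out, end_out, read_idx_out, strand_out = [], [], [], [], []
    for hi, hap in enumerate(reads.hap_names):
        for ci, chrom in enumerate(reads.chrom_names):
            sel = np.flatnonzero((reads.hap_idx == hi) & (reads.chrom_idx == ci))
            if sel.size == 0:
                continue
            pa = genome.piece_arrays(hap, chrom)
            bounds = pa["bounds"]
            s, e = reads.start[sel], reads.end[sel]
            i0 = np.searchsorted(bounds, s, side="right") - 1
            i1 = np.searchsorted(bounds, e - 1, side="right") - 1
            counts = i1 - i0 + 1
            offs = np.concatenate([[0], np.cumsum(counts)])
            tot = int(offs[-1])
            pidx = np.repeat(i0, counts) + (np.arange(tot) - np.repeat(offs[:-1], counts))
            rs = np.maximum(np.repeat(s, counts), bounds[pidx])
            re = np.minimum(np.repeat(e, counts), bounds[pidx + 1])
            ridx = np.repeat(sel, counts)
            ok = pa["mapped"][pidx] & (re > rs)
            pidx, rs, re, ridx = pidx[ok], rs[ok], re[ok], ridx[ok]
            rev = pa["strand"][pidx]
            off5 = rs - bounds[pidx]
            off3 = bounds[pidx + 1] - re
            ref_s = np.where(rev, pa["ref_start"][pidx] + off3,
                             pa["ref_start"][pidx] + off5)
            ref_e = ref_s + (re - rs)
            chrom_idx_out.append(pa["ref_chrom"][pidx])
            start_out.append(ref_s); end_out.append(ref_e)
            read_idx_out.append(ridx); strand_out.append(rev)
    cat = (lambda xs: np.concatenate(xs) if xs else np.empty(0, dtype=np.int64))
    return RefAlignments(genome.reference_names, genome.reference_lengths,
                         cat(chrom_idx_out), cat(start_out), cat(end_out),
                         cat(read_idx_out), reads.names,
                         cat(strand_out).astype(bool))


class CassetteAlignments:
    """One maximal alignment record per read against the one-unit cassette
    model (flank + unit + flank covers every junction context once)."""

    def __init__(self, tname, tlen, start, end, read_idx, read_names):
        self.tname = tname
        self.tlen = tlen
        self.start = start
        self.end = end
        self.read_idx = read_idx
        self.read_names = read_names

    def __len__(self):
        return len(self.start)

    def to_paf_records(self) -> list[PafRecord]:
        out = []
        for i in range(len(self)):
            span = int(self.end[i] - self.start[i])
            out.append(PafRecord(
                self.read_names[int(self.read_idx[i])], span, 0, span, "+",
                self.tname, self.tlen, int(self.start[i]), int(self.end[i]),
                span, span, 60))
        return out


def project_to_cassette(genome: GenomeTruth, reads: ReadSet,
                        tname: str = "cassette") -> CassetteAlignments:
    """Project reads overlapping the cassette locus onto the one-unit model.

    The model reference is [flank array | unit | flank array-at-end]; a read
    starting at phase t within tandem unit j aligns as a single record
    [t, min(t + len, unit + flank)), the maximal contiguous match an aligner
    could report.  Phases are uniform, so every junction context receives
    equal expected support and the inversion point (present once per unit
    versus twice for every other junction id) receives half.
    """
    starts, ends, ridx = [], [], []
    tlen = None
    for hi, hap in enumerate(reads.hap_names):
        lp = genome.locus_params(hap)
        if lp is None:
            continue
        tlen = lp["unit_len"] + lp["flank_len"]
        ci = reads.chrom_names.index(lp["chrom"])
        sel = np.flatnonzero((reads.hap_idx == hi) & (reads.chrom_idx == ci))
        if sel.size == 0:
            continue
        s = np.maximum(reads.start[sel], lp["start"])
        e = np.minimum(reads.end[sel], lp["end"])
        ok = e > s
        sel, s, e = sel[ok], s[ok], e[ok]
        t = (s - lp["start"]) % lp["unit_len"]
        # reads in the terminal flank (no following unit) keep their offset
        in_tail = s - lp["start"] >= lp["n_units"] * lp["unit_len"]
        t = np.where(in_tail, lp["unit_len"] + (s - lp["start"])
                     - lp["n_units"] * lp["unit_len"], t)
        span = np.minimum(e - s, tlen - t)
        starts.append(t); ends.append(t + span); ridx.append(sel)
    if tlen is None:
        raise ValueError("no haplotype in this read set carries the cassette")
    cat = (lambda xs: np.concatenate(xs) if xs else np.empty(0, dtype=np.int64))
    return CassetteAlignments(tname, int(tlen), cat(starts), cat(ends),
                              cat(ridx), reads.names)


# ------------------------------------------------------------- cDNA reads

@dataclass
class CdnaReads:
    """cDNA reads drawn uniformly from C gene copies, m of which carry a
    marker substitution."""

    total_copies: int
    mutant_copies: int
    copy_idx: np.ndarray
    is_mutant: np.ndarray
    sequences: Optional[list[str]] = None

    @property
    def mutant_read_count(self) -> int:
        return int(self.is_mutant.sum())

    @property
    def mutant_fraction(self) -> float:
        return self.mutant_read_count / len(self.copy_idx)


def simulate_cdna_reads(total_copies: int, mutant_copies: int, n_reads: int,
                        seed: int = 0, template: Optional[str] = None,
                        marker_offset: Optional[int] = None,
                        alt_base: str = "T") -> tuple[CdnaReads, int]:
    """Assign each of ``n_reads`` reads to one of ``total_copies`` gene
    copies uniformly; reads from the first ``mutant_copies`` copies carry
    the marker.  Returns the read set and the mutant read count."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not 0 <= mutant_copies <= total_copies:
        raise ValueError("need 0 <= mutant_copies <= total_copies")
    rng = np.random.default_rng(seed)
    copy_idx = rng.integers(0, total_copies, size=n_reads)
    is_mutant = copy_idx < mutant_copies
    seqs = None
    if template is not None:
        off = len(template) // 2 if marker_offset is None else marker_offset
        mut = template[:off] + alt_base + template[off + 1:]
        seqs = [mut if m else template for m in is_mutant]
    reads = CdnaReads(total_copies, mutant_copies, copy_idx, is_mutant, seqs)
    return reads, reads.mutant_read_count


# ----------------------------------------------------------- count matrix

def simulate_counts(n_genes: int, group_sizes: tuple[int, int] = (8, 8),
                    baseline_means=None, dispersion: float = 0.05,
                    dosage_map: Optional[dict[int, float]] = None,
                    seed: int = 0, group_names: tuple[str, str] = ("GS", "GR")):
    """Two-group negative-binomial count matrix; genes in ``dosage_map``
    (gene index -> copy ratio) have group-2 means scaled by the ratio.

    Counts are gamma-Poisson with Var = mu + dispersion * mu^2;
    dispersion = 0 gives the Poisson limit.
    """
    from .expression import CountMatrix

    if min(group_sizes) <= 0:
        raise ValueError("group sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if baseline_means is None:
        baseline_means = 10 ** rng.uniform(1, 3, size=n_genes)
    base = np.broadcast_to(np.asarray(baseline_means, dtype=float),
                           (n_genes,)).copy()
    if (base <= 0).any():
        raise ValueError("baseline means must be > 0")
    dosage = np.ones(n_genes)
    for gi, ratio in (dosage_map or {}).items():
        dosage[gi] = ratio
    n1, n2 = group_sizes
    mu = np.concatenate([np.tile(base[:, None], (1, n1)),
                         np.tile((base * dosage)[:, None], (1, n2))], axis=1)
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    samples = [f"{group_names[0]}{i + 1}" for i in range(n1)] + \
              [f"{group_names[1]}{i + 1}" for i in range(n2)]
    groups = [group_names[0]] * n1 + [group_names[1]] * n2
    genes = [f"gene{i}" for i in range(n_genes)]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(df, pd.Series(groups, index=samples))
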