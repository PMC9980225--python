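"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; PAF (12 mandatory columns) and BED are
small line formats written here so the column contracts are explicit.
All genomic coordinates are 0-based half-open on disk except the packaged
table fixtures, which keep their printed 1-based convention and are
converted by their parsers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    recs = (SeqRecord(Seq(s), id=n, description="") for n, s in items)
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {name}: sequence/quality length mismatch")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ----------------------------------------------------------------------- PAF

@dataclass(frozen=True)
class PafRecord:
    """One alignment line: the 12 mandatory PAF columns."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str   # '+' or '-'
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int

    def to_line(self) -> str:
        return "\t".join(str(v) for v in (
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.nmatch, self.alnlen, self.mapq))


def read_paf(path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: PAF needs 12 columns, got {len(f)}")
            if f[4] not in "+-":
                raise ValueError(f"{path}:{ln}: bad strand {f[4]!r}")
            out.append(PafRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                                 f[5], int(f[6]), int(f[7]), int(f[8]),
                                 int(f[9]), int(f[10]), int(f[11])))
    return out


def write_paf(path, records: Iterable[PafRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


# ----------------------------------------------------------------------- BED

def read_bed(path) -> list[tuple]:
    """BED3+ rows: (chrom, start, end, *extra-columns)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            out.append((f[0], start, end, *f[3:]))
    return out


def write_bed(path, rows: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ----------------------------------------------------------------------- TSV

def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_newick(path, newick: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


# ------------------------------------------------------------------ fixtures

_FIXTURE_FILES = {
    "cnv_table": "table1_cnv.tsv",
    "de_table": "table2_de.tsv",
}

# sha256 of the packaged transcriptions; guards accidental edits.
_FIXTURE_SHA256 = {}


def fixture_path(name: str) -> Path:
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_FIXTURE_FILES)}")
    return Path(str(resources.files("subtelcnv.data") / _FIXTURE_FILES[name]))


def load_fixture(name: str):
    """Load and schema-validate a packaged table fixture.

    ``cnv_table`` returns the CNV event rows (34), ``de_table`` the
    cassette-gene differential-expression rows (9).
    """
    path = fixture_path(name)
    payload = path.read_bytes()
    expect = _FIXTURE_SHA256.get(name)
    if expect is not None:
        got = hashlib.sha256(payload).hexdigest()
        if got != expect:
            raise ValueError(f"fixture {name}: checksum mismatch ({got})")
    if name == "cnv_table":
        from .depth import parse_cnv_table
        return parse_cnv_table(path)
    from .expression import parse_de_table
    return parse_de_table(path)


# ------------------------------------------------------------------ manifest

def write_manifest(path, *, command: str, params: dict, seed=None,
                   inputs: Iterable[str] = ()) -> None:
    """Run manifest: parameters, seed, input hashes, package version."""
    from . import __version__

    hashes = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    doc = {"tool": "subtelcnv", "version": __version__, "command": command,
           "seed": seed, "params": params, "input_sha256": hashes}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
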