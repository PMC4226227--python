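"""Sequence I/O, alphabet normalisation and strand operations.

A :class:`Genome` is an ordered collection of named contigs over the
five-letter alphabet ``{A, C, G, T, N}``.  Everything else in the package
counts over this object: k-mer multiplicities, maximal repeats, gap runs.
Both DNA strands matter for repeat counting, so the strand primitives
(:func:`reverse_complement`, :func:`canonical_kmer`) live here and are used
by every counting module.

Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Genome",
    "GenomicInterval",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "canonical_kmer",
]

# IUPAC nucleotide codes.  A/C/G/T stay; every other valid code (ambiguity
# codes, U, N, and gap characters '-' '.') folds to N, matching the view of
# the genome as "assembled (ACGT) versus not".
_IUPAC = set("ACGTUNRYSWKMBDHV-.")

_FOLD = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in _IUPAC}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class Contig:
    """One named sequence over {A,C,G,T,N} (uppercase)."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.name!r} contains non-ACGTN residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class Genome:
    """Ordered collection of contigs with unique names."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("contig names are not unique")

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "Genome":
        """Build a genome from ``{name: sequence}``, folding the alphabet."""
        return cls([Contig(n, _fold_residues(n, s)) for n, s in seqs.items()])


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig, optionally stranded."""

    contig: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment on forward coordinates, strand-agnostic."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def _fold_residues(name: str, raw: str) -> str:
    s = raw.upper()
    bad = set(s) - _IUPAC
    if bad:
        raise FastaFormatError(
            f"record {name!r}: non-IUPAC characters {sorted(bad)}"
        )
    return s.translate(_FOLD)


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly gzip-compressed) FASTA file into a :class:`Genome`.

    Lowercase folds to uppercase and IUPAC ambiguity codes other than
    A/C/G/T fold to N.  Malformed input (leading non-header text, an empty
    record) raises :class:`FastaFormatError` naming the offending line.
    """
    with _open_maybe_gzip(path) as fh:
        text = fh.read()
    # SeqIO silently drops leading junk and tolerates empty records; the
    # contract here is stricter, so pre-validate line structure.
    lines = text.splitlines()
    first_content = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if first_content is None:
        raise FastaFormatError(f"{path}: empty file")
    if not lines[first_content].startswith(">"):
        raise FastaFormatError(
            f"{path}: line {first_content + 1}: expected FASTA header, "
            f"got {lines[first_content][:30]!r}"
        )
    prev_header: int | None = None
    has_seq = False
    for i, ln in enumerate(lines):
        if ln.startswith(">"):
            if prev_header is not None and not has_seq:
                raise FastaFormatError(
                    f"{path}: line {prev_header + 1}: empty record "
                    f"{lines[prev_header][1:].split()[0] if len(lines[prev_header]) > 1 else ''!r}"
                )
            prev_header, has_seq = i, False
        elif ln.strip():
            has_seq = True
    if prev_header is not None and not has_seq:
        raise FastaFormatError(f"{path}: line {prev_header + 1}: empty record")

    contigs = [
        Contig(rec.id, _fold_residues(rec.id, str(rec.seq)))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path) -> None:
    """Write a genome as FASTA, 60 characters per sequence line."""
    records = [
        SeqRecord(Seq(c.residues), id=c.name, description="") for c in genome
    ]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def reverse_complement(s: str) -> str:
    """Reverse complement over {A,C,G,T,N}; case preserved, N maps to N."""
    bad = set(s.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def canonical_kmer(s: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    Collapses the two strand readings of a k-mer onto one representative so
    that multiplicity counting treats ``aaagg`` and ``ccttt`` as the same
    repeat type.  N is rejected: windows containing unassembled bases are
    excluded from counting upstream.
    """
    if "N" in s.upper():
        raise ValueError("k-mer contains N; filter such windows before canonicalizing")
    rc = reverse_complement(s)
    return s if s <= rc else rc
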