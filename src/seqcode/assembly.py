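"""Genome assemblies and the integrity statistics tested during type validation.

An assembly is an ordered collection of contigs read from a (possibly
gzip-compressed) FASTA file.  :func:`compute_stats` derives the statistics
that the registry's recommended genome-integrity thresholds are evaluated
against: total length, contig count, largest contig, N50/L50, G+C content
and the number of ambiguous (non-ACGT IUPAC) bases.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "AssemblyRecord",
    "AssemblyStats",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "compute_stats",
]

# IUPAC nucleotide one-letter codes; U accepted and normalized to T on read.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
_AMBIGUOUS = frozenset("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input: duplicate identifiers, empty or
    non-IUPAC sequences."""


@dataclass(frozen=True)
class AssemblyRecord:
    """An ordered set of uniquely named contig sequences.

    Sequences are stored uppercase over the IUPAC nucleotide alphabet.
    """

    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, seq in self.contigs:
            if name in seen:
                raise FastaFormatError(f"duplicate contig identifier {name!r}")
            seen.add(name)
            if not seq:
                raise FastaFormatError(f"contig {name!r} has an empty sequence")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.contigs)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(seq) for _, seq in self.contigs)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def sequence(self, contig_id: str) -> str:
        for name, seq in self.contigs:
            if name == contig_id:
                return seq
        raise KeyError(contig_id)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssemblyRecord":
        """Build a record from (identifier, sequence) pairs, validating the
        alphabet and normalizing case."""
        contigs = []
        for name, seq in pairs:
            contigs.append((name, _validate_sequence(name, seq)))
        return cls(tuple(contigs))


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise FastaFormatError(f"contig {name!r} has an empty sequence")
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise FastaFormatError(
            f"contig {name!r} contains non-IUPAC character {seq[pos]!r} "
            f"at position {pos + 1}"
        )
    return seq


@dataclass(frozen=True)
class AssemblyStats:
    """Integrity statistics of one assembly.

    ``gc_percent`` is 100·(G+C)/(A+C+G+T), i.e. ambiguous bases are excluded
    from the denominator and counted in ``ambiguous_bases`` instead.  The
    unrounded value is stored; :attr:`gc_percent_rounded` gives the
    nearest-integer presentation used in protologues.
    """

    total_length: int
    n_contigs: int
    largest_contig: int
    n50: int
    l50: int
    gc_percent: float
    ambiguous_bases: int

    @property
    def gc_percent_rounded(self) -> int:
        return int(round(self.gc_percent))

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "n_contigs": self.n_contigs,
            "largest_contig": self.largest_contig,
            "n50": self.n50,
            "l50": self.l50,
            "gc_percent": self.gc_percent,
            "gc_percent_rounded": self.gc_percent_rounded,
            "ambiguous_bases": self.ambiguous_bases,
        }


def _open_text(path: Union[str, Path]) -> io.TextIOBase:
    path = Path(path)
    raw = path.open("rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def read_fasta(path: Union[str, Path]) -> AssemblyRecord:
    """Read an assembly from a FASTA file (plain or gzip).

    Records are returned in file order with sequences uppercased.  Duplicate
    identifiers, empty sequences and characters outside the IUPAC nucleotide
    alphabet raise :class:`FastaFormatError` naming the offending contig.
    """
    with _open_text(path) as handle:
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not pairs:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return AssemblyRecord.from_pairs(pairs)


def write_fasta(assembly: AssemblyRecord, path: Union[str, Path], width: int = 70) -> None:
    """Write an assembly as uncompressed FASTA with fixed line width."""
    with Path(path).open("w") as out:
        for name, seq in assembly.contigs:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def compute_stats(assembly: AssemblyRecord) -> AssemblyStats:
    """Compute :class:`AssemblyStats` for a non-empty assembly.

    N50 is the smallest contig length L such that contigs of length >= L sum
    to at least half of the total length (ties resolved to the larger
    qualifying length by construction of the cumulative scan); L50 is the
    number of such contigs.
    """
    if not assembly.contigs:
        raise ValueError("cannot compute statistics of an empty assembly")

    lengths = np.sort(np.array(assembly.lengths, dtype=np.int64))[::-1]
    total = int(lengths.sum())
    cumulative = np.cumsum(lengths)
    # first index where the running sum reaches half the assembly
    idx = int(np.searchsorted(cumulative, (total + 1) // 2))
    n50 = int(lengths[idx])
    l50 = idx + 1

    gc = at = ambiguous = 0
    for _, seq in assembly.contigs:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        ambiguous += sum(seq.count(c) for c in _AMBIGUOUS)
    unambiguous = gc + at
    gc_percent = 100.0 * gc / unambiguous if unambiguous else 0.0

    return AssemblyStats(
        total_length=total,
        n_contigs=len(assembly.contigs),
        largest_contig=int(lengths[0]),
        n50=n50,
        l50=l50,
        gc_percent=gc_percent,
        ambiguous_bases=ambiguous,
    )
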