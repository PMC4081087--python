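"""Nucleic-acid primitives and FASTA/TSV input-output.

All sequences are carried as :class:`NucleicSequence` objects with an
explicit RNA or DNA alphabet.  Inputs may mix U and T freely; residues are
canonicalised to the declared alphabet (U for RNA, T for DNA) and to upper
case on construction.  IUPAC ambiguity codes are rejected rather than
expanded, since every quantity downstream (seed matching, cut-site
placement) counts exact residues.

Coordinates are 1-based inclusive in every user-facing report and 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alphabet",
    "NucleicSequence",
    "SiRNADuplex",
    "reverse_complement",
    "complement",
    "extract_seed",
    "gc_fraction",
    "read_fasta",
    "write_fasta",
    "read_duplex_tsv",
    "write_duplex_tsv",
]


class Alphabet(str, Enum):
    RNA = "RNA"
    DNA = "DNA"


_RNA_RESIDUES = frozenset("ACGU")
_DNA_RESIDUES = frozenset("ACGT")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonicalize(residues: str, alphabet: Alphabet) -> str:
    s = residues.upper()
    s = s.replace("T", "U") if alphabet is Alphabet.RNA else s.replace("U", "T")
    allowed = _RNA_RESIDUES if alphabet is Alphabet.RNA else _DNA_RESIDUES
    for pos, ch in enumerate(s, start=1):
        if ch not in allowed:
            raise ValueError(
                f"unknown residue {ch!r} at position {pos} "
                f"for alphabet {alphabet.value}"
            )
    return s


@dataclass(frozen=True)
class NucleicSequence:
    """An identified RNA or DNA sequence in canonical upper-case form."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.RNA

    def __post_init__(self) -> None:
        alphabet = Alphabet(self.alphabet)
        object.__setattr__(self, "alphabet", alphabet)
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", _canonicalize(self.residues, alphabet))

    def __len__(self) -> int:
        return len(self.residues)

    def with_id(self, new_id: str) -> "NucleicSequence":
        return NucleicSequence(new_id, self.residues, self.alphabet)

    def as_alphabet(self, alphabet: Alphabet) -> "NucleicSequence":
        """Transliterate to the other alphabet (U<->T); identity otherwise."""
        alphabet = Alphabet(alphabet)
        if alphabet is self.alphabet:
            return self
        return NucleicSequence(self.id, self.residues, alphabet)


def complement(seq: NucleicSequence) -> NucleicSequence:
    table = _RNA_COMPLEMENT if seq.alphabet is Alphabet.RNA else _DNA_COMPLEMENT
    return NucleicSequence(seq.id, seq.residues.translate(table), seq.alphabet)


def reverse_complement(seq: NucleicSequence) -> NucleicSequence:
    """Antiparallel complement in the same alphabet.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    table = _RNA_COMPLEMENT if seq.alphabet is Alphabet.RNA else _DNA_COMPLEMENT
    return NucleicSequence(seq.id, seq.residues.translate(table)[::-1], seq.alphabet)


def revcomp_str(residues: str, alphabet: Alphabet = Alphabet.RNA) -> str:
    """Reverse complement of a bare residue string (internal convenience)."""
    table = _RNA_COMPLEMENT if Alphabet(alphabet) is Alphabet.RNA else _DNA_COMPLEMENT
    return residues.translate(table)[::-1]


def extract_seed(
    guide: NucleicSequence, first: int = 2, last: int = 8
) -> NucleicSequence:
    """Seed region of a guide strand, 1-based inclusive positions 5'->3'.

    Guide nucleotides 2-8 form the 7-nt seed that drives miRNA-like
    off-target repression.
    """
    if not 1 <= first <= last:
        raise ValueError(f"invalid seed positions {first}..{last}")
    if len(guide) < last:
        raise ValueError(
            f"guide {guide.id!r} has {len(guide)} nt, "
            f"too short for seed positions {first}..{last}"
        )
    return NucleicSequence(
        f"{guide.id}_seed", guide.residues[first - 1 : last], guide.alphabet
    )


def gc_fraction(residues: str) -> float:
    return (residues.count("G") + residues.count("C")) / len(residues)


@dataclass(frozen=True)
class SiRNADuplex:
    """A guide/passenger siRNA duplex with a paired core and 3' overhangs.

    Both strands have length ``core_length + overhang_length`` (21 nt by
    default: 19-bp core plus 2-nt 3' overhang).  The first ``core_length``
    nucleotides of the guide are the antiparallel complement of the first
    ``core_length`` nucleotides of the passenger; the trailing overhang
    nucleotides of each strand are unpaired 3' tails.
    """

    name: str
    guide: NucleicSequence
    passenger: NucleicSequence
    core_length: int = 19
    overhang_length: int = 2

    def __post_init__(self) -> None:
        if self.guide.alphabet is not Alphabet.RNA:
            raise ValueError(f"duplex {self.name!r}: guide must be RNA")
        if self.passenger.alphabet is not Alphabet.RNA:
            raise ValueError(f"duplex {self.name!r}: passenger must be RNA")
        expected = self.core_length + self.overhang_length
        if len(self.guide) != expected or len(self.passenger) != expected:
            raise ValueError(
                f"duplex {self.name!r}: strands must be "
                f"{expected} nt (core {self.core_length} + overhang "
                f"{self.overhang_length}); got guide {len(self.guide)}, "
                f"passenger {len(self.passenger)}"
            )
        gcore = self.guide.residues[: self.core_length]
        pcore = self.passenger.residues[: self.core_length]
        if gcore != revcomp_str(pcore):
            raise ValueError(
                f"duplex {self.name!r}: guide core is not the antiparallel "
                f"complement of the passenger core"
            )

    @property
    def guide_core(self) -> str:
        return self.guide.residues[: self.core_length]

    @property
    def passenger_core(self) -> str:
        return self.passenger.residues[: self.core_length]

    @property
    def guide_overhang(self) -> str:
        return self.guide.residues[self.core_length :]

    @property
    def passenger_overhang(self) -> str:
        return self.passenger.residues[self.core_length :]


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.RNA) -> list[NucleicSequence]:
    """Read a multi-record FASTA into canonical sequences.

    Duplicate IDs and empty records are rejected.  T and U are both accepted
    and canonicalised to the declared alphabet.
    """
    records: list[NucleicSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if not residues:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(NucleicSequence(rec.id, residues, alphabet))
    duplicates = sorted(i for i, c in seen.items() if c > 1)
    if duplicates:
        raise ValueError(f"duplicate record IDs in {path}: {', '.join(duplicates)}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[NucleicSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_duplex_tsv(
    path: str | Path, core_length: int = 19, overhang_length: int = 2
) -> list[SiRNADuplex]:
    """Read a duplex table with header columns: name, guide, passenger."""
    import csv

    duplexes: list[SiRNADuplex] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "guide", "passenger"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"duplex TSV {path} must have header columns "
                f"name, guide, passenger"
            )
        for row in reader:
            name = row["name"].strip()
            duplexes.append(
                SiRNADuplex(
                    name=name,
                    guide=NucleicSequence(f"{name}_guide", row["guide"].strip()),
                    passenger=NucleicSequence(
                        f"{name}_passenger", row["passenger"].strip()
                    ),
                    core_length=core_length,
                    overhang_length=overhang_length,
                )
            )
    return duplexes


def write_duplex_tsv(duplexes: Sequence[SiRNADuplex], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tguide\tpassenger\n")
        for d in duplexes:
            fh.write(f"{d.name}\t{d.guide.residues}\t{d.passenger.residues}\n")
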