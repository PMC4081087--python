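"""Annealing and single-strand-specific RNase T1 digestion, in silico.

Two in-vitro-transcribed strands are annealed by exact antiparallel
complementarity: all maximal complementary stretches of at least
``min_duplex_len`` base pairs are enumerated and accepted greedily in order
of decreasing length (ties: leftmost on the sense strand), skipping any
stretch that conflicts with already-accepted pairs.  No thermodynamics and
no G.U wobble pairs are modelled: siPool constructs are designed for exact
registers, and wobble protection is deliberately out of scope.

RNase T1 cleaves 3' of guanosine in single-stranded RNA; a guanosine is
protected if and only if it is itself base-paired.  Digestion is complete:
every eligible site is cut, matching the observed complete disappearance of
the annealed precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .seqcore import Alphabet, NucleicSequence, revcomp_str

__all__ = [
    "PairingMap",
    "Fragment",
    "ProductKind",
    "Provenance",
    "DigestionProduct",
    "YieldReport",
    "find_complementary_stretches",
    "anneal",
    "digest",
    "pair_products",
    "classify_products",
]

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->U, C<->G


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_ENCODE[c] for c in residues), dtype=np.int8, count=len(residues))


@dataclass(frozen=True)
class Stretch:
    """A maximal antiparallel exact-complementary run.

    ``a_start`` indexes strand A 5'->3'; position ``a_start + k`` pairs with
    ``b_end - 1 - k`` on strand B, for ``k in range(length)``.
    """

    a_start: int
    b_end: int  # half-open: the pair for a_start is b_end - 1
    length: int

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_start(self) -> int:
        return self.b_end - self.length

    def pairs(self) -> list[tuple[int, int]]:
        return [(self.a_start + k, self.b_end - 1 - k) for k in range(self.length)]


def find_complementary_stretches(
    a: str, b: str, min_len: int
) -> list[Stretch]:
    """All maximal antiparallel exact-complementary stretches >= min_len.

    Implemented as common-substring runs between strand A and the reverse
    complement of strand B, scanned per diagonal with numpy.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ea = _encode(a)
    eb_rc = _COMP_CODE[_encode(b)][::-1]  # reverse complement of b, encoded
    n, m = len(ea), len(eb_rc)
    match = ea[:, None] == eb_rc[None, :]
    stretches: list[Stretch] = []
    for off in range(-(n - 1), m):
        diag = np.diagonal(match, offset=off)
        if diag.size < min_len or not diag.any():
            continue
        # run-length encode the boolean diagonal
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            length = run_end - run_start
            if length < min_len:
                continue
            # np.diagonal(offset=off): element k is match[k, k+off] if off>=0
            # else match[k-off, k]
            if off >= 0:
                a_start, j_start = run_start, run_start + off
            else:
                a_start, j_start = run_start - off, run_start
            # j indexes the reversed-complement of b; map back to b
            b_hi = m - j_start  # pair of a_start is b position b_hi - 1
            stretches.append(Stretch(a_start=a_start, b_end=b_hi, length=length))
    return stretches


@dataclass
class PairingMap:
    """Per-position pairing of two annealed strands (A = sense, B = antisense)."""

    strand_a: NucleicSequence
    strand_b: NucleicSequence
    stretches: list[Stretch] = field(default_factory=list)

    def __post_init__(self) -> None:
        pa = np.zeros(len(self.strand_a), dtype=bool)
        pb = np.zeros(len(self.strand_b), dtype=bool)
        for s in self.stretches:
            pa[s.a_start : s.a_end] = True
            pb[s.b_start : s.b_end] = True
        self._paired_a = pa
        self._paired_b = pb
        self._partner_a = np.full(len(self.strand_a), -1, dtype=np.int64)
        self._partner_b = np.full(len(self.strand_b), -1, dtype=np.int64)
        for s in self.stretches:
            for i, j in s.pairs():
                self._partner_a[i] = j
                self._partner_b[j] = i

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {(i, j) for s in self.stretches for i, j in s.pairs()}

    def paired(self, strand: str) -> np.ndarray:
        """Boolean paired-state array for strand 'a' or 'b'."""
        return self._paired_a if strand == "a" else self._paired_b

    def partner(self, strand: str) -> np.ndarray:
        return self._partner_a if strand == "a" else self._partner_b


def anneal(
    sense: NucleicSequence, antisense: NucleicSequence, min_duplex_len: int = 8
) -> PairingMap:
    """Greedy maximal-stretch annealing of two RNA strands.

    Stretches are accepted in order of decreasing length (ties broken by the
    leftmost position on the sense strand, then on the antisense strand); a
    stretch overlapping any already-paired position is skipped whole.
    Returning zero pairs is a valid outcome.
    """
    if sense.alphabet is not Alphabet.RNA or antisense.alphabet is not Alphabet.RNA:
        raise ValueError("anneal expects two RNA strands")
    candidates = find_complementary_stretches(
        sense.residues, antisense.residues, min_duplex_len
    )
    candidates.sort(key=lambda s: (-s.length, s.a_start, s.b_start))
    used_a = np.zeros(len(sense), dtype=bool)
    used_b = np.zeros(len(antisense), dtype=bool)
    accepted: list[Stretch] = []
    for s in candidates:
        if used_a[s.a_start : s.a_end].any() or used_b[s.b_start : s.b_end].any():
            continue
        used_a[s.a_start : s.a_end] = True
        used_b[s.b_start : s.b_end] = True
        accepted.append(s)
    return PairingMap(sense, antisense, accepted)


@dataclass(frozen=True)
class Fragment:
    """A maximal uncut interval of one strand after complete T1 digestion."""

    strand: str  # 'a' (sense) or 'b' (antisense)
    start: int  # 0-based half-open interval on the source transcript
    end: int
    residues: str

    def __len__(self) -> int:
        return self.end - self.start


def digest(pairing: PairingMap) -> dict[str, list[Fragment]]:
    """Complete RNase T1 digestion of both annealed strands.

    A cut is placed immediately 3' of every G whose position is unpaired;
    fragments are the maximal uncut intervals.  Fragment concatenation
    5'->3' reproduces each strand exactly.
    """
    out: dict[str, list[Fragment]] = {}
    for key, seq in (("a", pairing.strand_a), ("b", pairing.strand_b)):
        paired = pairing.paired(key)
        residues = seq.residues
        cuts = [
            pos + 1
            for pos, ch in enumerate(residues)
            if ch == "G" and not paired[pos]
        ]
        bounds = [0] + cuts + ([len(residues)] if (not cuts or cuts[-1] != len(residues)) else [])
        frags = [
            Fragment(key, lo, hi, residues[lo:hi])
            for lo, hi in zip(bounds[:-1], bounds[1:])
            if hi > lo
        ]
        out[key] = frags
    return out


class ProductKind(str, Enum):
    DUPLEX = "duplex"
    SINGLE_STRAND = "single_strand"
    COMPLEX = "complex"


class Provenance(str, Enum):
    INTENDED = "intended"
    UNINTENDED_DUPLEX = "unintended_duplex"
    DEBRIS = "debris"


@dataclass
class DigestionProduct:
    kind: ProductKind
    strands: list[Fragment]
    core_paired_length: int = 0
    overhang_3p_lengths: tuple[int, int] | None = None
    provenance: Provenance | None = None

    @property
    def strand_lengths(self) -> tuple[int, ...]:
        return tuple(len(f) for f in self.strands)


def _overhang_3p(frag: Fragment, paired: np.ndarray) -> int:
    """Unpaired 3' tail length of a fragment."""
    n = 0
    for pos in range(frag.end - 1, frag.start - 1, -1):
        if paired[pos]:
            break
        n += 1
    return n


def pair_products(
    pairing: PairingMap, fragments: dict[str, list[Fragment]]
) -> list[DigestionProduct]:
    """Group digestion fragments into duplex and single-stranded products.

    Two fragments sharing at least one base pair form a duplex;
    ``core_paired_length`` counts the shared pairs and the 3' overhangs are
    the unpaired 3' tails of each fragment.  A fragment paired with more
    than one partner yields a 'complex' product listing all partners — a
    designer failure signal, never silently dropped.
    """
    frags_a = fragments["a"]
    frags_b = fragments["b"]
    # map positions to fragment indices
    pos2frag_a = np.full(len(pairing.strand_a), -1, dtype=np.int64)
    for idx, f in enumerate(frags_a):
        pos2frag_a[f.start : f.end] = idx
    pos2frag_b = np.full(len(pairing.strand_b), -1, dtype=np.int64)
    for idx, f in enumerate(frags_b):
        pos2frag_b[f.start : f.end] = idx

    # shared-pair counts between fragment pairs
    shared: dict[tuple[int, int], int] = {}
    for i, j in pairing.pairs:
        key = (int(pos2frag_a[i]), int(pos2frag_b[j]))
        shared[key] = shared.get(key, 0) + 1

    partners_a: dict[int, set[int]] = {}
    partners_b: dict[int, set[int]] = {}
    for fa, fb in shared:
        partners_a.setdefault(fa, set()).add(fb)
        partners_b.setdefault(fb, set()).add(fa)

    products: list[DigestionProduct] = []
    consumed_a: set[int] = set()
    consumed_b: set[int] = set()

    # connected components over the fragment-pairing graph
    for fa in sorted(partners_a):
        if fa in consumed_a:
            continue
        comp_a, comp_b = {fa}, set()
        frontier_a = {fa}
        while frontier_a:
            next_b = set().union(*(partners_a[x] for x in frontier_a)) - comp_b
            comp_b |= next_b
            frontier_a = set().union(*(partners_b[y] for y in next_b)) - comp_a
            comp_a |= frontier_a
        consumed_a |= comp_a
        consumed_b |= comp_b
        members = [frags_a[x] for x in sorted(comp_a)] + [
            frags_b[y] for y in sorted(comp_b)
        ]
        if len(comp_a) == 1 and len(comp_b) == 1:
            fa_, fb_ = next(iter(comp_a)), next(iter(comp_b))
            products.append(
                DigestionProduct(
                    kind=ProductKind.DUPLEX,
                    strands=[frags_a[fa_], frags_b[fb_]],
                    core_paired_length=shared[(fa_, fb_)],
                    overhang_3p_lengths=(
                        _overhang_3p(frags_a[fa_], pairing.paired("a")),
                        _overhang_3p(frags_b[fb_], pairing.paired("b")),
                    ),
                )
            )
        else:
            products.append(
                DigestionProduct(kind=ProductKind.COMPLEX, strands=members)
            )

    for idx, f in enumerate(frags_a):
        if idx not in consumed_a:
            products.append(DigestionProduct(kind=ProductKind.SINGLE_STRAND, strands=[f]))
    for idx, f in enumerate(frags_b):
        if idx not in consumed_b:
            products.append(DigestionProduct(kind=ProductKind.SINGLE_STRAND, strands=[f]))
    return products


@dataclass
class YieldReport:
    """Per-class product counts and per-block recovery for one digestion."""

    intended: int
    unintended_duplex: int
    debris: int
    complex_products: int
    block_recovery: dict[str, int]  # duplex name -> 0/1

    @property
    def all_blocks_recovered(self) -> bool:
        return all(v == 1 for v in self.block_recovery.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.block_recovery.items()),
            columns=["duplex_name", "recovered"],
        )


def classify_products(
    products: Sequence[DigestionProduct], blocks: Sequence
) -> YieldReport:
    """Label each product against the design manifest.

    A duplex is 'intended' when its two fragments coincide exactly — interval
    and residues — with a manifest block's core+overhang span on each
    transcript.  Other duplexes are 'unintended_duplex'; single-stranded
    fragments are spacer/leader/trailer debris.
    """
    # expected (sense interval, antisense interval) per block
    expected: dict[tuple[int, int, int, int], str] = {}
    for blk in blocks:
        s0, s1 = blk.sense_core_interval[0], blk.sense_overhang_interval[1]
        a0, a1 = blk.antisense_core_interval[0], blk.antisense_overhang_interval[1]
        expected[(s0, s1, a0, a1)] = blk.duplex_name

    recovery = {blk.duplex_name: 0 for blk in blocks}
    intended = unintended = debris = complex_n = 0
    for prod in products:
        if prod.kind is ProductKind.DUPLEX:
            fa, fb = prod.strands
            key = (fa.start, fa.end, fb.start, fb.end)
            name = expected.get(key)
            if name is not None:
                prod.provenance = Provenance.INTENDED
                recovery[name] = 1
                intended += 1
            else:
                prod.provenance = Provenance.UNINTENDED_DUPLEX
                unintended += 1
        elif prod.kind is ProductKind.SINGLE_STRAND:
            prod.provenance = Provenance.DEBRIS
            debris += 1
        else:
            complex_n += 1
    return YieldReport(
        intended=intended,
        unintended_duplex=unintended,
        debris=debris,
        complex_products=complex_n,
        block_recovery=recovery,
    )
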