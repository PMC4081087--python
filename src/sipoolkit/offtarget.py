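"""Seed-match scanning of 3'-UTR sets and the random-seed enrichment test.

An siRNA guide represses unintended transcripts miRNA-style when the
reverse complement of its seed (guide nucleotides 2-8, a 7-mer) occurs in a
transcript's 3'-UTR.  Given a set of repressed transcript IDs, enrichment
of seed-match carriers among them is assessed against a null distribution
built from random seeds: ``n_draw`` distinct random 7-mers are scanned
against the same UTRs, and the ``n_keep`` whose transcriptome-wide
match counts are closest to the observed seed's are retained, so the null
statistic is computed over seeds of comparable background frequency.

Two p-values are reported: a +1-corrected empirical tail (conservative; its
floor is 1/(n_keep+1), never zero) and an upper-tail probability under a
Gaussian fit to the null values, which is what a far-out observation needs
to be quantified beyond the empirical floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .seqcore import (
    Alphabet,
    NucleicSequence,
    SiRNADuplex,
    extract_seed,
    reverse_complement,
)

__all__ = [
    "UtrIndex",
    "SeedMatchIndex",
    "EnrichmentResult",
    "scan_utrs",
    "draw_null_seeds",
    "seed_match_enrichment",
    "pool_offtarget_profile",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_BASES_RNA = "ACGU"

_CODE_TABLE = np.zeros(256, dtype=np.int64)
for _ch, _v in _CODE.items():
    _CODE_TABLE[ord(_ch)] = _v


def _encode_residues(s: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | _CODE[ch]
    return code


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES_RNA[code & 3])
        code >>= 2
    return "".join(reversed(out))


class UtrIndex:
    """K-mer occurrence index over a fixed UTR set.

    Built once per transcriptome; every motif query is then O(1) for the
    transcriptome-wide match count and O(matches) for the matched IDs, which
    makes drawing thousands of random null seeds cheap.
    """

    def __init__(self, utrs: Sequence[NucleicSequence], k: int = 7):
        if not utrs:
            raise ValueError("UTR set is empty")
        ids = [u.id for u in utrs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript IDs in UTR set")
        self.k = k
        self.ids = ids
        self.n_transcripts = len(utrs)

        codes_parts: list[np.ndarray] = []
        tids_parts: list[np.ndarray] = []
        mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for tid, u in enumerate(utrs):
            s = u.residues
            if len(s) < k:
                continue
            enc = _encode_residues(s)
            # rolling k-mer codes via strided windows
            win = np.lib.stride_tricks.sliding_window_view(enc, k)
            codes_parts.append(win @ mult)
            tids_parts.append(np.full(len(s) - k + 1, tid, dtype=np.int64))
        if codes_parts:
            codes = np.concatenate(codes_parts)
            tids = np.concatenate(tids_parts)
        else:
            codes = np.empty(0, dtype=np.int64)
            tids = np.empty(0, dtype=np.int64)

        # unique (code, transcript) pairs with occurrence counts
        key = codes * self.n_transcripts + tids
        ukey, counts = np.unique(key, return_counts=True)
        self._pair_code = ukey // self.n_transcripts
        self._pair_tid = ukey % self.n_transcripts
        self._pair_count = counts
        # transcripts-with-at-least-one-occurrence per k-mer code
        self._match_count = np.bincount(
            self._pair_code, minlength=4**k
        ).astype(np.int64)

    def match_count(self, motif: str) -> int:
        return int(self._match_count[_encode_kmer(motif)])

    def matches(self, motif: str) -> tuple[list[str], dict[str, int]]:
        """Matched transcript IDs and per-transcript occurrence counts."""
        code = _encode_kmer(motif)
        lo = np.searchsorted(self._pair_code, code, side="left")
        hi = np.searchsorted(self._pair_code, code, side="right")
        tids = self._pair_tid[lo:hi]
        counts = self._pair_count[lo:hi]
        ids = [self.ids[t] for t in tids]
        return ids, dict(zip(ids, (int(c) for c in counts)))

    def match_counts_for_codes(self, codes: np.ndarray) -> np.ndarray:
        return self._match_count[codes]


@dataclass
class SeedMatchIndex:
    """Result of scanning one seed's reverse-complement motif over a UTR set."""

    seed: NucleicSequence
    motif: NucleicSequence
    matched_ids: frozenset[str]
    match_count: int
    occurrence_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.motif) != len(self.seed):
            raise ValueError("motif and seed lengths differ")
        if self.match_count != len(self.matched_ids):
            raise ValueError("match_count inconsistent with matched_ids")


def scan_utrs(
    seed: NucleicSequence,
    utrs: Sequence[NucleicSequence] | None = None,
    index: UtrIndex | None = None,
) -> SeedMatchIndex:
    """Scan the reverse complement of a seed over a 3'-UTR set.

    The motif is searched on the sense strand of each UTR (miRNA-like
    targeting geometry); overlapping occurrences are counted.  Either the
    UTR list or a prebuilt :class:`UtrIndex` over it must be given.
    """
    if index is None:
        if not utrs:
            raise ValueError("UTR set is empty")
        index = UtrIndex(utrs, k=len(seed))
    if len(seed) != index.k:
        raise ValueError(
            f"seed length {len(seed)} does not match index k={index.k}"
        )
    motif = reverse_complement(seed.as_alphabet(Alphabet.RNA)).with_id(
        f"{seed.id}_motif"
    )
    ids, occ = index.matches(motif.residues)
    return SeedMatchIndex(
        seed=seed,
        motif=motif,
        matched_ids=frozenset(ids),
        match_count=len(ids),
        occurrence_counts=occ,
    )


def draw_null_seeds(
    observed_index: SeedMatchIndex,
    utrs: Sequence[NucleicSequence] | None = None,
    n_draw: int = 7500,
    n_keep: int = 2000,
    rng_seed: int | None = None,
    index: UtrIndex | None = None,
    band_mode: str = "closest",
    rel_tol: float = 0.26,
) -> list[SeedMatchIndex]:
    """Draw random seeds and retain those with comparable match counts.

    ``n_draw`` distinct random seeds (uniform over k-mers, excluding the
    observed seed, drawn without replacement) are scanned against the same
    UTR set.  Retention modes:

    * ``"closest"`` (default): the ``n_keep`` seeds with match count closest
      to the observed count (ties: smaller absolute difference first, then
      lexicographic seed) — deterministic retained-set size.
    * ``"relative"``: all drawn seeds whose match count lies within
      ``rel_tol`` of the observed count, truncated to ``n_keep`` in draw
      order; errors if fewer than ``n_keep`` fall inside the band.
    """
    if index is None:
        if not utrs:
            raise ValueError("UTR set is empty")
        index = UtrIndex(utrs, k=len(observed_index.seed))
    k = index.k
    space = 4**k
    if n_draw > space - 1:
        raise ValueError(
            f"n_draw={n_draw} exceeds the {space - 1} distinct {k}-mers "
            f"available once the observed seed is excluded"
        )
    if n_keep > n_draw:
        raise ValueError("n_keep must be <= n_draw")

    rng = np.random.default_rng(rng_seed)
    obs_code = _encode_kmer(observed_index.seed.residues)
    draws = rng.choice(space - 1, size=n_draw, replace=False)
    draws = np.where(draws >= obs_code, draws + 1, draws)  # skip observed seed

    # band on the count of each seed's scanning motif (its reverse
    # complement), the same quantity the statistic uses
    seeds_str = [_decode_kmer(int(c), k) for c in draws]
    from .seqcore import revcomp_str

    counts = np.array(
        [index.match_count(revcomp_str(s)) for s in seeds_str], dtype=np.int64
    )
    obs_count = observed_index.match_count
    if band_mode == "closest":
        order = sorted(
            range(n_draw),
            key=lambda i: (abs(int(counts[i]) - obs_count), seeds_str[i]),
        )
        kept = order[:n_keep]
    elif band_mode == "relative":
        lo, hi = obs_count * (1 - rel_tol), obs_count * (1 + rel_tol)
        kept = [i for i in range(n_draw) if lo <= counts[i] <= hi]
        if len(kept) < n_keep:
            raise ValueError(
                f"only {len(kept)} of {n_draw} drawn seeds fall within "
                f"+/-{rel_tol:.0%} of the observed match count {obs_count}"
            )
        kept = kept[:n_keep]
    else:
        raise ValueError(f"unknown band_mode {band_mode!r}")

    out = []
    for i in kept:
        seed_str = _decode_kmer(int(draws[i]), k)
        seed = NucleicSequence(f"null_{seed_str}", seed_str)
        out.append(scan_utrs(seed, index=index))
    return out


@dataclass
class EnrichmentResult:
    """Seed-match enrichment among repressed transcripts vs random seeds."""

    seed: str
    observed: int
    null_values: list[int]
    n_drawn: int
    n_kept: int
    band: tuple[int, int]  # achieved (min, max) match count of retained seeds
    p_empirical: float
    p_gaussian: float
    rng_seed: int | None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "observed": self.observed,
            "n_drawn": self.n_drawn,
            "n_kept": self.n_kept,
            "band": list(self.band),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_empirical": self.p_empirical,
            "p_gaussian": self.p_gaussian,
            "rng_seed": self.rng_seed,
            "null_values": list(map(int, self.null_values)),
        }


def seed_match_enrichment(
    seed: NucleicSequence,
    utrs: Sequence[NucleicSequence] | None,
    repressed_ids: Iterable[str],
    n_draw: int = 7500,
    n_keep: int = 2000,
    rng_seed: int | None = None,
    index: UtrIndex | None = None,
    band_mode: str = "closest",
    rel_tol: float = 0.26,
) -> EnrichmentResult:
    """Test whether repressed transcripts are enriched for a seed match.

    The statistic is the number of repressed transcripts whose 3'-UTR
    carries the seed's reverse-complement motif; the null distribution is
    the same statistic over match-count-banded random seeds.

    ``p_empirical = (1 + #{null >= observed}) / (1 + n_keep)`` — the
    +1-corrected permutation tail, never zero.  ``p_gaussian`` is the
    normal-approximation upper tail from the null mean and SD.
    """
    repressed = set(repressed_ids)
    if not repressed:
        raise ValueError("repressed set is empty; the statistic is degenerate")
    if index is None:
        if not utrs:
            raise ValueError("UTR set is empty")
        index = UtrIndex(utrs, k=len(seed))
    known = set(index.ids)
    unknown = repressed - known
    if unknown:
        raise ValueError(
            f"{len(unknown)} repressed IDs are not in the UTR set "
            f"(e.g. {sorted(unknown)[:3]})"
        )

    obs_index = scan_utrs(seed, index=index)
    observed = len(repressed & obs_index.matched_ids)
    nulls = draw_null_seeds(
        obs_index,
        n_draw=n_draw,
        n_keep=n_keep,
        rng_seed=rng_seed,
        index=index,
        band_mode=band_mode,
        rel_tol=rel_tol,
    )
    null_values = [len(repressed & nl.matched_ids) for nl in nulls]
    band = (
        min(nl.match_count for nl in nulls),
        max(nl.match_count for nl in nulls),
    )
    arr = np.asarray(null_values, dtype=float)
    p_emp = (1.0 + int(np.sum(arr >= observed))) / (1.0 + len(null_values))
    mu, sd = float(arr.mean()), float(arr.std(ddof=1))
    if sd > 0:
        p_gauss = float(stats.norm.sf(observed, loc=mu, scale=sd))
    else:  # degenerate null: all retained seeds hit the same count
        p_gauss = 1.0 if observed <= mu else 0.0
    return EnrichmentResult(
        seed=seed.residues,
        observed=observed,
        null_values=null_values,
        n_drawn=n_draw,
        n_kept=len(null_values),
        band=band,
        p_empirical=p_emp,
        p_gaussian=p_gauss,
        rng_seed=rng_seed,
    )


def pool_offtarget_profile(
    pool: Sequence[SiRNADuplex],
    utrs: Sequence[NucleicSequence] | None = None,
    index: UtrIndex | None = None,
    seed_first: int = 2,
    seed_last: int = 8,
):
    """Per-transcript seed-match burden of a whole siRNA pool.

    For each transcript: the number of pool guides whose seed motif occurs
    in its 3'-UTR, and the dilution-weighted burden (that number divided by
    the pool size).  In a complex pool each guide contributes only 1/pool
    of the dose, so the burden is the equimolar-dilution picture of the
    pool's off-target pressure.  Sorted by burden descending.
    """
    import pandas as pd

    if not pool:
        raise ValueError("pool is empty")
    if index is None:
        if not utrs:
            raise ValueError("UTR set is empty")
        index = UtrIndex(utrs, k=seed_last - seed_first + 1)
    hits: dict[str, int] = {tid: 0 for tid in index.ids}
    for duplex in pool:
        seed = extract_seed(duplex.guide, seed_first, seed_last)
        smi = scan_utrs(seed, index=index)
        for tid in smi.matched_ids:
            hits[tid] += 1
    n = len(pool)
    frame = pd.DataFrame(
        {
            "transcript_id": list(hits.keys()),
            "matching_guides": list(hits.values()),
        }
    )
    frame["burden"] = frame["matching_guides"] / n
    return frame.sort_values(
        ["burden", "transcript_id"], ascending=[False, True]
    ).reset_index(drop=True)
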