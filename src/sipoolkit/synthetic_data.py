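"""Synthetic transcriptomes, repressed sets and reference sequences.

Everything the other modules consume can be generated here, so the whole
package is testable without any download.  The background model for UTRs is
i.i.d. per-residue at a target GC content (G = C and A = U split evenly)
with log-normal lengths; this is sufficient to calibrate an exact-match
7-mer statistic, though it lacks the dinucleotide structure and repeat
content of real 3'-UTRs (see the methods note for what that implies).

Motifs are planted by splice-in (inserting the motif, preserving flanks)
rather than substitution, so the planted carrier count is exact and the
length distribution stays interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqcore import Alphabet, NucleicSequence

__all__ = [
    "SyntheticTranscriptomeSpec",
    "RepressionModelSpec",
    "generate_transcriptome",
    "generate_repressed_set",
    "generate_target_mrna",
    "reference_sequences",
    "ReferenceSequence",
]


@dataclass(frozen=True)
class SyntheticTranscriptomeSpec:
    """Parameters of a synthetic 3'-UTR set.

    Lengths are log-normal with the given median (in nt) and dispersion
    (sigma of log length); defaults approximate a human 3'-UTR length
    distribution at a desk-scale transcript count.
    """

    n_transcripts: int = 1000
    utr_length_median: int = 1000
    utr_length_sigma: float = 0.5
    gc_content: float = 0.45
    planted_motif: NucleicSequence | None = None
    planted_fraction: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.planted_motif is not None and self.utr_length_median < len(
            self.planted_motif
        ):
            raise ValueError("median UTR length shorter than the planted motif")


@dataclass(frozen=True)
class RepressionModelSpec:
    """Weighted sampling model for a repressed transcript set.

    Transcripts carrying the motif get selection weight ``1 + effect_beta``;
    all others weight 1.  ``effect_beta = 0`` is the null model: repression
    independent of the motif.
    """

    repressed_set_size: int = 200
    effect_beta: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.effect_beta < 0:
            raise ValueError("effect_beta must be >= 0")
        if self.repressed_set_size < 1:
            raise ValueError("repressed_set_size must be >= 1")


_BASES = np.array(list("ACGU"))


def _random_residues(
    rng: np.random.Generator, length: int, gc: float
) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(rng.choice(_BASES, size=length, p=p))


def generate_transcriptome(
    spec: SyntheticTranscriptomeSpec,
) -> list[NucleicSequence]:
    """Generate a synthetic 3'-UTR set, optionally with a planted motif.

    If ``planted_motif`` is set, the motif is spliced into a simple random
    sample of ``ceil(planted_fraction * n)`` transcripts at a uniform random
    position, so the carrier count is exact.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mu = math.log(spec.utr_length_median)
    min_len = max(len(spec.planted_motif) if spec.planted_motif else 1, 10)

    lengths = []
    for _ in range(spec.n_transcripts):
        for _attempt in range(100):
            ln = int(round(rng.lognormal(mu, spec.utr_length_sigma)))
            if ln >= min_len:
                lengths.append(ln)
                break
        else:
            raise ValueError(
                "could not draw a UTR length of at least "
                f"{min_len} nt after 100 attempts"
            )

    width = len(str(spec.n_transcripts))
    utrs = [
        NucleicSequence(
            f"tx_{i + 1:0{width}d}", _random_residues(rng, lengths[i], spec.gc_content)
        )
        for i in range(spec.n_transcripts)
    ]

    if spec.planted_motif is not None and spec.planted_fraction > 0:
        motif = spec.planted_motif.as_alphabet(Alphabet.RNA).residues
        n_plant = math.ceil(spec.planted_fraction * spec.n_transcripts)
        chosen = rng.choice(spec.n_transcripts, size=n_plant, replace=False)
        for i in sorted(chosen):
            u = utrs[i]
            pos = int(rng.integers(0, len(u) + 1))
            utrs[i] = NucleicSequence(
                u.id, u.residues[:pos] + motif + u.residues[pos:]
            )
    return utrs


def generate_repressed_set(
    transcriptome: Sequence[NucleicSequence],
    motif: NucleicSequence | None,
    model: RepressionModelSpec,
) -> set[str]:
    """Sample a repressed transcript set, optionally motif-biased.

    Weighted sampling without replacement (Efraimidis-Spirakis exponential
    keys): motif carriers get weight ``1 + effect_beta``.  ``effect_beta=0``
    reduces exactly to simple random sampling.
    """
    n = len(transcriptome)
    if model.repressed_set_size > n:
        raise ValueError("repressed_set_size exceeds the transcriptome size")
    rng = np.random.default_rng(model.rng_seed)
    weights = np.ones(n)
    if motif is not None and model.effect_beta > 0:
        m = motif.as_alphabet(Alphabet.RNA).residues
        carriers = np.array([m in t.residues for t in transcriptome])
        weights[carriers] = 1.0 + model.effect_beta
    keys = rng.exponential(scale=1.0, size=n) / weights
    order = np.argsort(keys)
    return {transcriptome[i].id for i in order[: model.repressed_set_size]}


def generate_target_mrna(
    length: int = 1500, gc: float = 0.45, rng_seed: int | None = None
) -> NucleicSequence:
    """A random target mRNA for design tests; deterministic per seed."""
    if length < 200:
        raise ValueError("target length must be >= 200 nt")
    rng = np.random.default_rng(rng_seed)
    return NucleicSequence(f"target_{length}nt", _random_residues(rng, length, gc))


@dataclass(frozen=True)
class ReferenceSequence:
    """A built-in reference sequence with its role and completeness tag.

    ``form`` distinguishes 19-mers printed as cores only ("core_only") from
    full 21-nt strands ("full_strand"), long dsRNA precursor regions
    ("region") and DNA hybridisation probes ("probe").
    """

    seq: NucleicSequence
    role: str
    form: str


def reference_sequences() -> dict[str, ReferenceSequence]:
    """Built-in reference sequences from the siPool validation experiments.

    Antisense (guide) strands of the characterised off-target siRNAs against
    PolG and Scyl1 (each with a known MAD2 off-target), a Mad2 siRNA, a
    negative-control siRNA, the low-complexity-pool siRNAs against PolG
    (19-mers, core only) and Scyl1 (full 21-nt strands), the two esiRNA
    precursor regions (DNA) and the northern-blot probe oligos (DNA).
    """

    def rna(name: str, s: str) -> NucleicSequence:
        return NucleicSequence(name, s, Alphabet.RNA)

    def dna(name: str, s: str) -> NucleicSequence:
        return NucleicSequence(name, s, Alphabet.DNA)

    entries: list[tuple[NucleicSequence, str, str]] = [
        (rna("PolG_offT_antisense", "AAUAUCCAGCGCUUCACCC"), "guide", "core_only"),
        (rna("Scyl1_offT_antisense", "ACAUUGUUGUGGAUGAGGC"), "guide", "core_only"),
        (rna("Mad2_antisense", "CCAAUCUUUCAGUUGUUCC"), "guide", "core_only"),
        (rna("negctrl_antisense", "UUGUCUUGCAUUCGACUAA"), "guide", "core_only"),
        (rna("PolG_si1_antisense", "UCAUCCGACAGCCGAUACC"), "guide", "core_only"),
        (rna("PolG_si2_antisense", "AAUUCUUGCAGGUCCCACU"), "guide", "core_only"),
        (rna("PolG_si3_antisense", "GCUAUUACCAUCCUUGUGA"), "guide", "core_only"),
        (rna("PolG_si4_antisense", "UUAAACUGCAUUAGUAAGC"), "guide", "core_only"),
        (rna("Scyl1_si1_antisense", "UUUCUCAGGAUCUACAGUGAG"), "guide", "full_strand"),
        (rna("Scyl1_si2_antisense", "UUGAGGUAUAUUCCCAACGGG"), "guide", "full_strand"),
        (rna("Scyl1_si3_antisense", "UUGGUUUCUACAAAGCGGUUG"), "guide", "full_strand"),
        (rna("Scyl1_si4_antisense", "UUGUACAAUAAAUACAUCUGU"), "guide", "full_strand"),
        (
            dna(
                "PolG_esiRNA_region",
                "GGAAGAAGTGGGAGGTGGTTGCTGAACGGGCATGGAAGGGGGGCACAGAGTCAGAAATG"
                "TTCAATAAGCTTGAGAGCATTGCTACGTCTGACATACCACGTACCCCGGTGCTGGGCTG"
                "CTGCATCAGCCGAGCCCTGGAGCCCTCGGCTGTCCAGGAAGAGTTTATGACCAGCCGTG"
                "TGAATTGGGTGGTACAGAGCTCTGCTGTTGACTACTTACACCTCATGCTTGTGGCCATG"
                "AAGTGGCTGTTTGAAGAGT",
            ),
            "dsRNA_precursor",
            "region",
        ),
        (
            dna(
                "Scyl1_esiRNA_region",
                "CAGCCGAGAAGCAAAAATTCTTCCAGGAGCTGAGCAAGAGCCTGGACGCATTCCCTGAG"
                "GATTTCTGTCGGCACAAGGTGCTGCCCCAGCTGCTGACCGCCTTCGAGTTCGGCAATGC"
                "TGGGGCCGTTGTCCTCACGCCCCTCTTCAAGGTGGGCAAGTTCCTGAGCGCTGAGGAGT"
                "ATCAGCAGAAGATCATCCCTGTGGTGGTCAAGATGTTCTCATCCACTGACCGGGCCATG"
                "CGCATCCGCCTCCTGCAGCAGATGGAGCAGTTCATCCAGTACCTTGACGAGCCAACAGT"
                "CAACACCCAGATCTTCCCCCACGTCGTACATGGCTTCCTGGACACCAACCCTGCCATCC"
                "GGGAGCAGACGGTCAAGTCCATGCTGCTCCTGGCCCCAAAGCTGAACGAGGCCAACCTC"
                "AATGTGGAGCTGA",
            ),
            "dsRNA_precursor",
            "region",
        ),
        (dna("PolG_offT_guide_probe", "GGGTGAAGCGCTGGATATT"), "probe", "probe"),
        (dna("PolG_offT_passenger_probe", "AATATCCAGCGCTTCACCC"), "probe", "probe"),
        (dna("Scyl1_offT_guide_probe", "GCCTCATCCACAACAATGT"), "probe", "probe"),
        (dna("Scyl1_offT_passenger_probe", "ACATTGTTGTGGATGAGGC"), "probe", "probe"),
    ]
    return {e[0].id: ReferenceSequence(seq=e[0], role=e[1], form=e[2]) for e in entries}
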