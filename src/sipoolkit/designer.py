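"""siPool construct design.

A siPool is produced from two in-vitro-transcribed RNA strands that carry
the passenger (sense transcript) and guide (antisense transcript) sequences
of many siRNAs in tandem, separated by non-complementary single-stranded
spacers.  After annealing, only the siRNA cores are double-stranded; RNase
T1 then cuts 3' of every unpaired G, releasing each siRNA as a defined
duplex with 2-nt 3' overhangs.

Release geometry
----------------
Each released strand is ``core_length + overhang_length`` nucleotides
(21 by default).  Its 3' end is defined by the terminal overhang G (the T1
cut site); its 5' end by a single-stranded spacer G placed immediately
upstream of the core.  Three local rules make the release exact:

* the overhang's last nucleotide is G and no other overhang position is G
  (an internal overhang G would shorten the product);
* the overhang's first nucleotide is neither G (1-nt-overhang product) nor
  C (it would base-pair with the cut-site G facing it across the junction
  and protect that G from cleavage);
* every spacer ends in G, the upstream cut site of the next block.

Spacers are sampled from {A, U, C} with the single mandatory terminal G and
screened so that no antiparallel complementary stretch of
``min_duplex_len`` or more exists anywhere between the two transcripts
outside the intended cores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    Alphabet,
    NucleicSequence,
    SiRNADuplex,
    gc_fraction,
    revcomp_str,
)
from .digestion import find_complementary_stretches, Stretch

__all__ = [
    "SelectionRules",
    "AssemblyConfig",
    "BlockRecord",
    "SiPoolTemplate",
    "ValidationReport",
    "T7_PROMOTER",
    "select_sirnas",
    "design_spacer",
    "assemble_templates",
    "validate_design",
    "pool_concentration_report",
]

#: Canonical 18-nt bacteriophage T7 promoter; transcription initiates at its
#: final G, which is therefore also the first nucleotide of the transcript.
T7_PROMOTER = "TAATACGACTCACTATAG"

_COMP_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SelectionRules:
    """Filter rules for siRNA candidate selection on a target mRNA.

    The published consensus rules used here are deliberately minimal and
    each one is independently re-checkable: GC content of the 19-nt core
    between 30% and 60%, no homopolymer run longer than ``max_homopolymer``,
    thermodynamic asymmetry proxied by AU counts at the guide ends, and a
    minimum spacing between chosen sites on the target.
    """

    core_length: int = 19
    gc_min: float = 0.30
    gc_max: float = 0.60
    max_homopolymer: int = 3
    asymmetry_required: bool = True
    min_spacing_on_target: int = 5
    immunostimulatory_filter: bool = False
    #: no two selected duplexes may share a pairing k-mer this long: a shared
    #: k-mer lets one transcript's passenger block anneal out of register
    #: with another block's guide region, breaking clean T1 release
    cross_pairing_kmer: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.core_length < 15:
            raise ValueError("core_length must be >= 15")


# motifs reported to trigger sequence-dependent innate-immune activation
_IMMUNOSTIMULATORY_MOTIFS = ("UGUGU", "GUCCUUCAA")


def _max_homopolymer_run(s: str) -> int:
    best = run = 1
    for prev, cur in zip(s, s[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def _au_count(s: str) -> int:
    return sum(1 for c in s if c in "AU")


def _check_rules(core: str, rules: SelectionRules) -> str | None:
    """Return the name of the first failing rule, or None if all pass."""
    gc = gc_fraction(core)
    if not rules.gc_min <= gc <= rules.gc_max:
        return "gc_content"
    if _max_homopolymer_run(core) > rules.max_homopolymer:
        return "homopolymer"
    if rules.asymmetry_required:
        guide_core = revcomp_str(core)
        au5 = _au_count(guide_core[:4])
        au3 = _au_count(guide_core[-4:])
        if au5 < au3:
            return "asymmetry"
    if rules.immunostimulatory_filter:
        guide_core = revcomp_str(core)
        for motif in _IMMUNOSTIMULATORY_MOTIFS:
            if motif in core or motif in guide_core:
                return "immunostimulatory"
    return None


def _candidate_score(core: str, rules: SelectionRules) -> float:
    """Documented ranking score: asymmetry margin plus GC centrality.

    Asymmetry margin is the AU-count excess at the guide 5' end over the
    guide 3' end (range -4..4); GC centrality rewards cores near the middle
    of the allowed GC window (range 0..1).
    """
    guide_core = revcomp_str(core)
    margin = _au_count(guide_core[:4]) - _au_count(guide_core[-4:])
    mid = (rules.gc_min + rules.gc_max) / 2.0
    half = (rules.gc_max - rules.gc_min) / 2.0
    centrality = 1.0 - abs(gc_fraction(core) - mid) / half
    return margin + centrality


def select_sirnas(
    target: NucleicSequence,
    n: int,
    rules: SelectionRules | None = None,
    rng_seed: int | None = None,
    overhang: str = "UG",
) -> list[SiRNADuplex]:
    """Select ``n`` mutually non-overlapping siRNA duplexes against a target.

    Passenger cores are exact substrings of the target (transliterated to
    RNA); candidates passing all enabled rules are ranked by
    :func:`_candidate_score` (ties broken by 5'-most target position) and
    accepted greedily subject to ``min_spacing_on_target``.  The procedure
    is deterministic for fixed inputs; ``rng_seed`` is accepted for
    interface uniformity with the stochastic design stages.

    Raises
    ------
    ValueError
        If the target is too short, or fewer than ``n`` candidates pass the
        rules (the message reports the count found and a histogram of first
        failing rules).
    """
    rules = rules or SelectionRules()
    _validate_overhang(overhang)
    k = rules.core_length
    rna = target.as_alphabet(Alphabet.RNA)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    if len(rna) < n * (k + rules.min_spacing_on_target):
        raise ValueError(
            f"target {target.id!r} ({len(rna)} nt) too short for {n} "
            f"siRNAs of core {k} nt with spacing {rules.min_spacing_on_target}"
        )

    seq = rna.residues
    fail_hist: dict[str, int] = {}
    passing: list[tuple[float, int, str]] = []  # (-score, start, core)
    for start in range(len(seq) - k + 1):
        core = seq[start : start + k]
        failed = _check_rules(core, rules)
        if failed is None:
            passing.append((-_candidate_score(core, rules), start, core))
        else:
            fail_hist[failed] = fail_hist.get(failed, 0) + 1
    passing.sort()

    chosen: list[tuple[int, str]] = []
    occupied: list[tuple[int, int]] = []
    gap = rules.min_spacing_on_target
    kx = rules.cross_pairing_kmer
    # k-mers of the context each accepted block places on the transcripts:
    # upstream cut-site G + passenger core + overhang on the sense strand,
    # and the reverse complement of G + guide + overhang on the antisense
    # (what a sense window must avoid matching).  The G is included because
    # it is a fixed junction residue no spacer choice can change.
    sense_kmers: set[str] = set()
    rc_guide_kmers: set[str] = set()
    cross_rejected = 0
    for _, start, core in passing:
        lo, hi = start - gap, start + k + gap
        if any(not (hi <= s or e <= lo) for s, e in occupied):
            continue
        p_strand = "G" + core + overhang
        rcg_strand = revcomp_str("G" + revcomp_str(core) + overhang)
        if not _self_consistent(p_strand, rcg_strand, kx):
            cross_rejected += 1
            continue
        p_k = _kmer_set([p_strand], kx)
        rcg_k = _kmer_set([rcg_strand], kx)
        if p_k & rc_guide_kmers or rcg_k & sense_kmers:
            cross_rejected += 1
            continue
        chosen.append((start, core))
        occupied.append((start, start + k))
        sense_kmers |= p_k
        rc_guide_kmers |= rcg_k
        if len(chosen) == n:
            break
    if len(chosen) < n:
        hist = ", ".join(f"{k_}={v}" for k_, v in sorted(fail_hist.items())) or "none"
        raise ValueError(
            f"only {len(chosen)} of {n} requested siRNAs satisfiable on "
            f"target {target.id!r} (first-failing-rule histogram: {hist}; "
            f"{cross_rejected} candidates rejected for cross-pairing)"
        )

    chosen.sort()  # report duplexes 5'->3' along the target
    duplexes = []
    for idx, (start, core) in enumerate(chosen, start=1):
        name = f"{target.id}_si{idx:02d}_pos{start + 1}"
        passenger = NucleicSequence(f"{name}_passenger", core + overhang)
        guide = NucleicSequence(f"{name}_guide", revcomp_str(core) + overhang)
        duplexes.append(
            SiRNADuplex(
                name=name,
                guide=guide,
                passenger=passenger,
                core_length=k,
                overhang_length=len(overhang),
            )
        )
    return duplexes


def _validate_overhang(overhang: str, _len_hint: int | None = None) -> None:
    if len(overhang) < 1:
        raise ValueError("overhang must be non-empty")
    if overhang[-1] != "G":
        raise ValueError(
            f"overhang {overhang!r}: last nucleotide must be G (the T1 cut "
            f"site defining the released strand's 3' end)"
        )
    if "G" in overhang[:-1]:
        raise ValueError(
            f"overhang {overhang!r}: internal G would create a premature "
            f"cut and a shortened overhang"
        )
    if overhang[0] == "C":
        raise ValueError(
            f"overhang {overhang!r}: first nucleotide C would base-pair "
            f"with the facing cut-site G and protect it from cleavage"
        )


def _self_consistent(p_strand: str, rcg_strand: str, k: int) -> bool:
    """Reject cores whose block could anneal to its own partner block in a
    shifted register.

    ``p_strand`` is the sense-side block context and ``rcg_strand`` the
    reverse complement of the antisense-side context; the intended pairing
    aligns offset ``x`` on the former with offset ``x + 1`` on the latter
    (the contexts differ by the leading cut-site G vs the trailing one).
    Any shared k-mer at a different offset pair is a shifted self-pairing
    (an internal repeat) that would survive spacer re-sampling.
    """
    pos_rcg: dict[str, list[int]] = {}
    for y in range(len(rcg_strand) - k + 1):
        pos_rcg.setdefault(rcg_strand[y : y + k], []).append(y)
    for x in range(len(p_strand) - k + 1):
        for y in pos_rcg.get(p_strand[x : x + k], ()):
            if y != x + 1:
                return False
    return True


def _kmer_set(strings: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for s in strings:
        for i in range(len(s) - k + 1):
            kmers.add(s[i : i + k])
    return kmers


def _cross_complementary(candidate: str, opposite_kmers: set[str], k: int) -> bool:
    """True if candidate shares an antiparallel complementary run >= k with
    any opposite-transcript sequence (k-mer screen on its reverse
    complement)."""
    rc = revcomp_str(candidate)
    return any(rc[i : i + k] in opposite_kmers for i in range(len(rc) - k + 1))


def design_spacer(
    flanking_overhangs: Sequence[str] = (),
    length: int = 10,
    rng: np.random.Generator | int | None = None,
    *,
    opposite_kmers: set[str] | frozenset[str] = frozenset(),
    min_duplex_len: int = 8,
    max_attempts: int = 1000,
    context_5p: str = "",
    context_3p: str = "",
) -> NucleicSequence:
    """Sample a single-stranded spacer ending in the next block's cut-site G.

    The spacer body is drawn from {A, U, C}; the mandatory terminal G is the
    upstream T1 cut site of the following block.  A candidate is rejected if
    it — together with up to ``min_duplex_len - 1`` nucleotides of flanking
    context on each side, so boundary-spanning windows are screened too —
    shares an antiparallel complementary stretch of ``min_duplex_len`` or
    more with any opposite-transcript sequence, or if its terminal two
    nucleotides are antiparallel-complementary to the overhang dinucleotide
    facing them across the junction.
    """
    if length < 4:
        raise ValueError("spacer length must be >= 4")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    body_alphabet = np.array(list("AUC"))
    ctx = context_5p[-(min_duplex_len - 1) :] if min_duplex_len > 1 else ""
    ctx3 = context_3p[: min_duplex_len - 1] if min_duplex_len > 1 else ""
    for attempt in range(1, max_attempts + 1):
        body = "".join(rng.choice(body_alphabet, size=length - 1))
        spacer = body + "G"
        # junction rule: terminal two spacer nucleotides vs facing overhang
        bad = False
        for ovh in flanking_overhangs:
            if len(ovh) >= 1 and ovh[0] == _COMP_RNA[spacer[-1]]:
                bad = True
            if (
                len(ovh) >= 2
                and ovh[0] == _COMP_RNA[spacer[-1]]
                and ovh[1] == _COMP_RNA[spacer[-2]]
            ):
                bad = True
        if bad:
            continue
        if opposite_kmers and _cross_complementary(
            ctx + spacer + ctx3, opposite_kmers, min_duplex_len
        ):
            continue
        return NucleicSequence("spacer", spacer)
    raise ValueError(
        f"no admissible spacer of length {length} found after "
        f"{max_attempts} attempts"
    )


@dataclass(frozen=True)
class BlockRecord:
    """Coordinates of one siRNA block on the two transcripts.

    All intervals are 0-based half-open internally; the JSON manifest
    serialises them 1-based inclusive.
    """

    duplex_name: str
    sense_core_interval: tuple[int, int]
    sense_overhang_interval: tuple[int, int]
    antisense_core_interval: tuple[int, int]
    antisense_overhang_interval: tuple[int, int]
    upstream_cut_G_positions: tuple[int, int]  # (on sense, on antisense)
    guide: str = ""
    passenger: str = ""

    def to_manifest_dict(self) -> dict:
        def iv(t: tuple[int, int]) -> dict:
            return {"start": t[0] + 1, "end": t[1]}  # 1-based inclusive

        return {
            "duplex_name": self.duplex_name,
            "sense_core": iv(self.sense_core_interval),
            "sense_overhang": iv(self.sense_overhang_interval),
            "antisense_core": iv(self.antisense_core_interval),
            "antisense_overhang": iv(self.antisense_overhang_interval),
            "upstream_cut_G": [
                self.upstream_cut_G_positions[0] + 1,
                self.upstream_cut_G_positions[1] + 1,
            ],
            "guide": self.guide,
            "passenger": self.passenger,
        }

    @classmethod
    def from_manifest_dict(cls, d: dict) -> "BlockRecord":
        def iv(v: dict) -> tuple[int, int]:
            return (v["start"] - 1, v["end"])

        return cls(
            duplex_name=d["duplex_name"],
            sense_core_interval=iv(d["sense_core"]),
            sense_overhang_interval=iv(d["sense_overhang"]),
            antisense_core_interval=iv(d["antisense_core"]),
            antisense_overhang_interval=iv(d["antisense_overhang"]),
            upstream_cut_G_positions=(
                d["upstream_cut_G"][0] - 1,
                d["upstream_cut_G"][1] - 1,
            ),
            guide=d.get("guide", ""),
            passenger=d.get("passenger", ""),
        )


@dataclass
class SiPoolTemplate:
    """A designed siPool: two transcripts, their DNA templates and manifest."""

    sense_transcript: NucleicSequence
    antisense_transcript: NucleicSequence
    sense_dna_template: NucleicSequence
    antisense_dna_template: NucleicSequence
    blocks: list[BlockRecord]
    # ordered (kind, name, start, end) segments covering each transcript
    sense_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    antisense_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    core_length: int = 19
    overhang_length: int = 2

    def to_manifest(self) -> dict:
        return {
            "core_length": self.core_length,
            "overhang_length": self.overhang_length,
            "sense_length": len(self.sense_transcript),
            "antisense_length": len(self.antisense_transcript),
            "blocks": [b.to_manifest_dict() for b in self.blocks],
            "sense_segments": [
                {"kind": k, "name": nm, "start": s + 1, "end": e}
                for k, nm, s, e in self.sense_segments
            ],
            "antisense_segments": [
                {"kind": k, "name": nm, "start": s + 1, "end": e}
                for k, nm, s, e in self.antisense_segments
            ],
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)
            fh.write("\n")

    @staticmethod
    def blocks_from_manifest(manifest: dict) -> list[BlockRecord]:
        return [BlockRecord.from_manifest_dict(d) for d in manifest["blocks"]]


@dataclass(frozen=True)
class AssemblyConfig:
    """Tunable geometry of the tandem construct."""

    spacer_length: int = 10
    leader_length: int = 10
    trailer_length: int = 10
    min_duplex_len: int = 8
    rng_seed: int | None = 0
    max_spacer_attempts: int = 1000
    max_assembly_attempts: int = 20

    def __post_init__(self) -> None:
        if self.spacer_length < 4 or self.leader_length < 4:
            raise ValueError("spacer and leader lengths must be >= 4")


def _dna_template(transcript: NucleicSequence, name: str) -> NucleicSequence:
    # the promoter's final G is the transcript's first nucleotide, so the
    # full 18-nt promoter is a prefix of promoter-minus-G + transcript DNA
    dna = T7_PROMOTER[:-1] + transcript.residues.replace("U", "T")
    return NucleicSequence(name, dna, Alphabet.DNA)


def _build_strand(
    label: str,
    block_strands: list[tuple[str, str]],  # (duplex_name, core+overhang residues)
    cfg: AssemblyConfig,
    rng: np.random.Generator,
    opposite_kmers: set[str],
    overhangs_by_block: list[str],
    core_length: int,
) -> tuple[str, list[tuple[str, str, int, int]], list[dict]]:
    """Assemble one transcript: leader + blocks/spacers + trailer.

    Returns the residue string, the segment list and per-block coordinate
    dicts (core interval, overhang interval, upstream cut G position).
    """
    segments: list[tuple[str, str, int, int]] = []
    coords: list[dict] = []
    parts: list[str] = []
    pos = 0

    def emit(kind: str, name: str, residues: str) -> int:
        nonlocal pos
        parts.append(residues)
        segments.append((kind, name, pos, pos + len(residues)))
        start = pos
        pos += len(residues)
        return start

    # leader: T7 initiation GGG, single-stranded body, terminal cut-site G
    k1 = cfg.min_duplex_len - 1
    first_block = block_strands[0][1][:k1]
    for attempt in range(cfg.max_spacer_attempts):
        body = "".join(rng.choice(np.array(list("AUC")), size=cfg.leader_length - 4))
        leader = "GGG" + body + "G"
        if not _cross_complementary(
            leader + first_block, opposite_kmers, cfg.min_duplex_len
        ):
            break
    else:
        raise ValueError(f"{label}: no admissible leader found")
    emit("leader", "leader", leader)

    running = leader
    for i, (name, strand) in enumerate(block_strands):
        cut5 = pos - 1  # the G just emitted (leader/spacer terminal)
        start = emit("block", name, strand)
        coords.append(
            {
                "name": name,
                "core": (start, start + core_length),
                "overhang": (start + core_length, start + len(strand)),
                "cut5": cut5,
            }
        )
        running += strand
        if i + 1 < len(block_strands):
            nxt_ovh = overhangs_by_block[i + 1]
            sp = design_spacer(
                flanking_overhangs=(overhangs_by_block[i], nxt_ovh),
                length=cfg.spacer_length,
                rng=rng,
                opposite_kmers=opposite_kmers,
                min_duplex_len=cfg.min_duplex_len,
                max_attempts=cfg.max_spacer_attempts,
                context_5p=running,
                context_3p=block_strands[i + 1][1],
            )
            emit("spacer", f"spacer_{i + 1}", sp.residues)
            running += sp.residues
    # trailer: unconstrained debris downstream of the last cut-site G
    for attempt in range(cfg.max_spacer_attempts):
        trailer = "".join(rng.choice(np.array(list("AUC")), size=cfg.trailer_length))
        tail_ctx = running[-(cfg.min_duplex_len - 1) :]
        if not _cross_complementary(tail_ctx + trailer, opposite_kmers, cfg.min_duplex_len):
            break
    else:
        raise ValueError(f"{label}: no admissible trailer found")
    emit("trailer", "trailer", trailer)
    return "".join(parts), segments, coords


def assemble_templates(
    duplexes: Sequence[SiRNADuplex],
    config: AssemblyConfig | None = None,
) -> SiPoolTemplate:
    """Assemble the two tandem transcripts releasing the given duplex pool.

    The sense transcript carries the passenger strands in input order; the
    antisense transcript carries the guide strands in reverse order, so that
    antiparallel annealing brings each guide/passenger pair into register.
    The result is validated with :func:`validate_design`; spacers are
    re-sampled (bounded attempts) until the design is clean.
    """
    cfg = config or AssemblyConfig()
    if not duplexes:
        raise ValueError("need at least one duplex")
    names = [d.name for d in duplexes]
    if len(set(names)) != len(names):
        raise ValueError("duplex names must be unique")
    guides = [d.guide.residues for d in duplexes]
    if len(set(guides)) != len(guides):
        dup = sorted({g for g in guides if guides.count(g) > 1})
        raise ValueError(f"duplicate duplex (identical guide strand): {dup[0]}")
    core_len = duplexes[0].core_length
    ovh_len = duplexes[0].overhang_length
    for d in duplexes:
        if d.core_length != core_len or d.overhang_length != ovh_len:
            raise ValueError("all duplexes must share core/overhang geometry")
        _validate_overhang(d.passenger_overhang)
        _validate_overhang(d.guide_overhang)

    sense_blocks = [(d.name, d.passenger.residues) for d in duplexes]
    anti_blocks = [(d.name, d.guide.residues) for d in reversed(duplexes)]
    sense_ovhs = [d.passenger_overhang for d in duplexes]
    anti_ovhs = [d.guide_overhang for d in reversed(duplexes)]

    rng = np.random.default_rng(cfg.rng_seed)
    last_report = None
    for attempt in range(cfg.max_assembly_attempts):
        # antisense fixed content, including each block's immutable upstream
        # cut-site G, so sense spacers also avoid the junction windows
        anti_fixed_kmers = _kmer_set(
            ["G" + s for _, s in anti_blocks], cfg.min_duplex_len
        )
        sense_res, sense_seg, sense_coords = _build_strand(
            "sense", sense_blocks, cfg, rng, anti_fixed_kmers, sense_ovhs, core_len
        )
        sense_kmers = _kmer_set([sense_res], cfg.min_duplex_len)
        anti_res, anti_seg, anti_coords = _build_strand(
            "antisense", anti_blocks, cfg, rng, sense_kmers, anti_ovhs, core_len
        )

        anti_by_name = {c["name"]: c for c in anti_coords}
        blocks = []
        for c, d in zip(sense_coords, duplexes):
            a = anti_by_name[d.name]
            blocks.append(
                BlockRecord(
                    duplex_name=d.name,
                    sense_core_interval=c["core"],
                    sense_overhang_interval=c["overhang"],
                    antisense_core_interval=a["core"],
                    antisense_overhang_interval=a["overhang"],
                    upstream_cut_G_positions=(c["cut5"], a["cut5"]),
                    guide=d.guide.residues,
                    passenger=d.passenger.residues,
                )
            )
        template = SiPoolTemplate(
            sense_transcript=NucleicSequence("sense_transcript", sense_res),
            antisense_transcript=NucleicSequence("antisense_transcript", anti_res),
            sense_dna_template=_dna_template(
                NucleicSequence("s", sense_res), "sense_dna_template"
            ),
            antisense_dna_template=_dna_template(
                NucleicSequence("a", anti_res), "antisense_dna_template"
            ),
            blocks=blocks,
            sense_segments=sense_seg,
            antisense_segments=anti_seg,
            core_length=core_len,
            overhang_length=ovh_len,
        )
        report = validate_design(template, cfg.min_duplex_len)
        if report.ok:
            return template
        last_report = report
    raise ValueError(
        f"no valid assembly after {cfg.max_assembly_attempts} attempts; "
        f"last report: {last_report.summary() if last_report else 'n/a'}"
    )


@dataclass
class ValidationReport:
    """Independent scan of a template against the release-geometry rules."""

    unintended_stretches: list[tuple[int, int, int]] = field(default_factory=list)
    overhang_violations: list[str] = field(default_factory=list)
    junction_violations: list[str] = field(default_factory=list)
    cut_site_violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.unintended_stretches
            or self.overhang_violations
            or self.junction_violations
            or self.cut_site_violations
        )

    def summary(self) -> str:
        return (
            f"unintended_stretches={len(self.unintended_stretches)}, "
            f"overhang={len(self.overhang_violations)}, "
            f"junction={len(self.junction_violations)}, "
            f"cut_site={len(self.cut_site_violations)}"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, b, l in self.unintended_stretches:
            rows.append(
                (
                    "unintended_stretch",
                    f"sense {s + 1}..{s + l} / antisense {b - l + 1}..{b} "
                    f"({l} bp)",
                )
            )
        for msg in self.overhang_violations:
            rows.append(("overhang", msg))
        for msg in self.junction_violations:
            rows.append(("junction", msg))
        for msg in self.cut_site_violations:
            rows.append(("cut_site", msg))
        return pd.DataFrame(rows, columns=["violation", "detail"])


def validate_design(
    template: SiPoolTemplate, min_duplex_len: int = 8
) -> ValidationReport:
    """Scan a template for any deviation from the release geometry.

    Reports (i) every maximal antiparallel complementary stretch of
    ``min_duplex_len`` bp or more between the transcripts that is not
    exactly an intended core, (ii) overhang intervals with a non-terminal G
    or a missing terminal G, (iii) junction pairings that would protect a
    cut-site G, and (iv) missing upstream cut-site Gs.  An empty report
    means the design is valid.
    """
    rep = ValidationReport()
    sense = template.sense_transcript.residues
    anti = template.antisense_transcript.residues

    intended = {
        (b.sense_core_interval[0], b.antisense_core_interval[1],
         b.sense_core_interval[1] - b.sense_core_interval[0])
        for b in template.blocks
    }
    for s in find_complementary_stretches(sense, anti, min_duplex_len):
        if (s.a_start, s.b_end, s.length) not in intended:
            rep.unintended_stretches.append((s.a_start, s.b_end, s.length))

    for b in template.blocks:
        for label, strand, core_iv, ovh_iv, cut5 in (
            ("sense", sense, b.sense_core_interval, b.sense_overhang_interval,
             b.upstream_cut_G_positions[0]),
            ("antisense", anti, b.antisense_core_interval,
             b.antisense_overhang_interval, b.upstream_cut_G_positions[1]),
        ):
            ovh = strand[ovh_iv[0] : ovh_iv[1]]
            if not ovh or ovh[-1] != "G":
                rep.overhang_violations.append(
                    f"{b.duplex_name}/{label}: overhang {ovh!r} does not end in G"
                )
            if "G" in ovh[:-1]:
                rep.overhang_violations.append(
                    f"{b.duplex_name}/{label}: internal G in overhang {ovh!r}"
                )
            if strand[cut5] != "G":
                rep.cut_site_violations.append(
                    f"{b.duplex_name}/{label}: residue at upstream cut position "
                    f"{cut5 + 1} is {strand[cut5]!r}, expected G"
                )
        # junction rule: each overhang vs the facing residue on the opposite
        # transcript (the partner block's upstream cut-site G and the residue
        # 5' of it)
        s_ovh = sense[b.sense_overhang_interval[0] : b.sense_overhang_interval[1]]
        a_core_start = b.antisense_core_interval[0]
        facing = anti[a_core_start - 1] if a_core_start >= 1 else ""
        if facing and s_ovh and s_ovh[0] == _COMP_RNA[facing]:
            rep.junction_violations.append(
                f"{b.duplex_name}: sense overhang base-pairs with the facing "
                f"antisense cut-site G"
            )
        a_ovh = anti[
            b.antisense_overhang_interval[0] : b.antisense_overhang_interval[1]
        ]
        s_core_start = b.sense_core_interval[0]
        facing = sense[s_core_start - 1] if s_core_start >= 1 else ""
        if facing and a_ovh and a_ovh[0] == _COMP_RNA[facing]:
            rep.junction_violations.append(
                f"{b.duplex_name}: antisense overhang base-pairs with the "
                f"facing sense cut-site G"
            )
    return rep


def pool_concentration_report(
    n_sirnas: int, total_concentration: float, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Equimolar per-siRNA concentrations for a pool at a total concentration.

    The dilution argument behind complex pools: each siRNA is present at
    ``total / n`` (e.g. 60 siRNAs at 3 nM total -> 0.05 nM each), pushing
    each individual sequence's off-target footprint below detection.
    """
    if n_sirnas < 1:
        raise ValueError("n_sirnas must be >= 1")
    if total_concentration <= 0:
        raise ValueError("total_concentration must be > 0")
    if names is not None and len(names) != n_sirnas:
        raise ValueError("names length must equal n_sirnas")
    each = total_concentration / n_sirnas
    idx = list(names) if names is not None else [
        f"siRNA_{i + 1:02d}" for i in range(n_sirnas)
    ]
    return pd.DataFrame(
        {"sirna": idx, "concentration_nM": [each] * n_sirnas}
    )
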