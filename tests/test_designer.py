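import numpy as np
import pytest

from sipoolkit.seqcore import NucleicSequence, gc_fraction, revcomp_str
from sipoolkit.designer import (
    AssemblyConfig,
    SelectionRules,
    T7_PROMOTER,
    assemble_templates,
    design_spacer,
    pool_concentration_report,
    select_sirnas,
    validate_design,
    _au_count,
    _max_homopolymer_run,
)
from sipoolkit.synthetic_data import generate_target_mrna


class TestSelectSirnas:
    def test_rules_hold_on_every_selected_duplex(self, target_1500, duplexes_15):
        """Re-apply each selection rule independently to the 15 winners."""
        rules = SelectionRules()
        target = target_1500.residues
        occupied = []
        for d in duplexes_15:
            core = d.passenger_core
            assert core in target, "passenger core must be a target substring"
            assert rules.gc_min <= gc_fraction(core) <= rules.gc_max
            assert _max_homopolymer_run(core) <= rules.max_homopolymer
            g = d.guide_core
            assert _au_count(g[:4]) >= _au_count(g[-4:]), "asymmetry rule"
            start = target.index(core)
            for s, e in occupied:
                assert start + len(core) + rules.min_spacing_on_target <= s or \
                    e + rules.min_spacing_on_target <= start
            occupied.append((start, start + len(core)))
        assert len({d.guide.residues for d in duplexes_15}) == 15

    def test_n_zero_gives_empty_list(self, target_1500):
        assert select_sirnas(target_1500, 0) == []

    def test_pure_a_target_unsatisfiable(self):
        target = NucleicSequence("polyA", "A" * 400)
        with pytest.raises(ValueError, match="gc_content"):
            select_sirnas(target, 1)

    def test_too_short_target(self):
        target = generate_target_mrna(200, 0.45, rng_seed=0)
        with pytest.raises(ValueError, match="too short"):
            select_sirnas(target, 40)

    def test_deterministic(self, target_1500):
        a = select_sirnas(target_1500, 5, rng_seed=3)
        b = select_sirnas(target_1500, 5, rng_seed=3)
        assert [d.passenger.residues for d in a] == [d.passenger.residues for d in b]

    def test_four_disjoint_pools_of_15(self, target_1500):
        """Four mutually non-overlapping 15-siRNA sets against one target
        give 60 distinct duplexes (the pool-of-pools construction)."""
        all60 = select_sirnas(generate_target_mrna(4000, 0.45, rng_seed=9), 60)
        pools = [all60[i * 15 : (i + 1) * 15] for i in range(4)]
        union = {d.guide.residues for p in pools for d in p}
        assert len(union) == 60


class TestDesignSpacer:
    def test_basic_contract(self):
        sp = design_spacer((), length=8, rng=0)
        assert len(sp) == 8 and sp.residues.endswith("G")
        assert "G" not in sp.residues[:-1]

    def test_too_short(self):
        with pytest.raises(ValueError, match=">= 4"):
            design_spacer((), length=3, rng=0)

    def test_deterministic(self):
        a = [design_spacer((), 10, rng) for rng in range(50)]
        b = [design_spacer((), 10, rng) for rng in range(50)]
        assert [x.residues for x in a] == [x.residues for x in b]

    def test_screen_rejects_complementary_spacer(self):
        # opposite content complementary to almost any AUC-spacer: make the
        # screen unsatisfiable by covering the full candidate k-mer space
        from itertools import product

        opposite = {"".join(p) for p in product("AUCG", repeat=4)}
        with pytest.raises(ValueError, match="attempts"):
            design_spacer(
                (), length=8, rng=0, opposite_kmers=opposite,
                min_duplex_len=4, max_attempts=50,
            )

    def test_screen_pass_is_rechecked(self):
        rng = np.random.default_rng(5)
        opposite = {"AAAAAAAA"}  # complement of a UUUUUUUU spacer window
        for _ in range(20):
            sp = design_spacer(
                (), 12, rng, opposite_kmers=opposite, min_duplex_len=8
            )
            assert "AAAAAAAA" not in revcomp_str(sp.residues)


class TestAssembleTemplates:
    def test_manifest_invariants(self, template_15):
        tpl = template_15
        sense = tpl.sense_transcript.residues
        anti = tpl.antisense_transcript.residues
        assert len(tpl.blocks) == 15
        for b in tpl.blocks:
            s0, s1 = b.sense_core_interval
            a0, a1 = b.antisense_core_interval
            assert revcomp_str(sense[s0:s1]) == anti[a0:a1]
            for strand, ovh_iv, cut in (
                (sense, b.sense_overhang_interval, b.upstream_cut_G_positions[0]),
                (anti, b.antisense_overhang_interval, b.upstream_cut_G_positions[1]),
            ):
                ovh = strand[ovh_iv[0] : ovh_iv[1]]
                assert len(ovh) == tpl.overhang_length
                assert ovh[-1] == "G" and "G" not in ovh[:-1]
                assert strand[cut] == "G"

    def test_block_order_reversed_on_antisense(self, template_15, duplexes_15):
        names_sense = [
            nm for k, nm, *_ in template_15.sense_segments if k == "block"
        ]
        names_anti = [
            nm for k, nm, *_ in template_15.antisense_segments if k == "block"
        ]
        assert names_sense == [d.name for d in duplexes_15]
        assert names_anti == names_sense[::-1]

    def test_segments_reconstruct_transcripts(self, template_15):
        for seq, segs in (
            (template_15.sense_transcript, template_15.sense_segments),
            (template_15.antisense_transcript, template_15.antisense_segments),
        ):
            rebuilt = "".join(seq.residues[s:e] for _, _, s, e in segs)
            assert rebuilt == seq.residues

    def test_transcripts_start_with_g_and_templates_carry_promoter(self, template_15):
        assert template_15.sense_transcript.residues.startswith("GGG")
        assert template_15.antisense_transcript.residues.startswith("GGG")
        for dna in (template_15.sense_dna_template, template_15.antisense_dna_template):
            assert dna.residues.startswith(T7_PROMOTER)
        # template minus promoter is the DNA transliteration of the transcript
        body = template_15.sense_dna_template.residues[len(T7_PROMOTER) - 1 :]
        assert body == template_15.sense_transcript.residues.replace("U", "T")

    def test_duplicate_guide_rejected(self, duplexes_15):
        twice = list(duplexes_15) + [
            duplexes_15[0].__class__(
                name="clone",
                guide=duplexes_15[0].guide,
                passenger=duplexes_15[0].passenger,
            )
        ]
        with pytest.raises(ValueError, match="duplicate duplex"):
            assemble_templates(twice)

    def test_byte_identical_for_fixed_seed(self, duplexes_15):
        a = assemble_templates(duplexes_15, AssemblyConfig(rng_seed=3))
        b = assemble_templates(duplexes_15, AssemblyConfig(rng_seed=3))
        assert a.sense_transcript.residues == b.sense_transcript.residues
        assert a.antisense_transcript.residues == b.antisense_transcript.residues
        assert a.to_manifest() == b.to_manifest()

    def test_manifest_round_trip(self, template_15):
        manifest = template_15.to_manifest()
        blocks = template_15.blocks_from_manifest(manifest)
        assert blocks == template_15.blocks


class TestValidateDesign:
    def test_fresh_template_is_clean(self, template_15):
        assert validate_design(template_15).ok

    def test_planted_cross_complement_reported(self, template_15, duplexes_15):
        """Replace a sense spacer with the complement of another block's
        guide core: exactly that stretch must be reported."""
        tpl = template_15
        spacer_seg = next(
            (k, nm, s, e) for k, nm, s, e in tpl.sense_segments if k == "spacer"
        )
        _, _, s, e = spacer_seg
        # complement of the last block's antisense core, so it pairs with it
        a0, a1 = tpl.blocks[-1].antisense_core_interval
        planted = revcomp_str(tpl.antisense_transcript.residues[a0 : a0 + (e - s)])
        sense = tpl.sense_transcript.residues
        mutated = tpl.__class__(
            sense_transcript=NucleicSequence("sense", sense[:s] + planted + sense[e:]),
            antisense_transcript=tpl.antisense_transcript,
            sense_dna_template=tpl.sense_dna_template,
            antisense_dna_template=tpl.antisense_dna_template,
            blocks=tpl.blocks,
            sense_segments=tpl.sense_segments,
            antisense_segments=tpl.antisense_segments,
        )
        report = validate_design(mutated)
        assert not report.ok
        assert any(l >= e - s for _, _, l in report.unintended_stretches)

    def test_overhang_gg_violation_reported(self, template_15):
        tpl = template_15
        b = tpl.blocks[0]
        s = list(tpl.sense_transcript.residues)
        s[b.sense_overhang_interval[0]] = "G"  # overhang becomes GG
        mutated = tpl.__class__(
            sense_transcript=NucleicSequence("sense", "".join(s)),
            antisense_transcript=tpl.antisense_transcript,
            sense_dna_template=tpl.sense_dna_template,
            antisense_dna_template=tpl.antisense_dna_template,
            blocks=tpl.blocks,
            sense_segments=tpl.sense_segments,
            antisense_segments=tpl.antisense_segments,
        )
        report = validate_design(mutated)
        assert any("internal G" in v for v in report.overhang_violations)


class TestConcentrationReport:
    @pytest.mark.parametrize(
        "n,total,each", [(60, 3.0, 0.05), (1, 3.0, 3.0), (15, 3.0, 0.2)]
    )
    def test_equimolar_split(self, n, total, each):
        table = pool_concentration_report(n, total)
        assert len(table) == n
        assert np.allclose(table["concentration_nM"], each)
        assert np.isclose(table["concentration_nM"].sum(), total)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pool_concentration_report(0, 3.0)
        with pytest.raises(ValueError):
            pool_concentration_report(5, 0.0)
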