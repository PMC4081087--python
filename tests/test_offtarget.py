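import numpy as np
import pytest

from sipoolkit.seqcore import NucleicSequence, reverse_complement
from sipoolkit.offtarget import (
    UtrIndex,
    draw_null_seeds,
    pool_offtarget_profile,
    scan_utrs,
    seed_match_enrichment,
)
from sipoolkit.synthetic_data import (
    SyntheticTranscriptomeSpec,
    generate_transcriptome,
)

from conftest import random_rna
from _oracles import brute_scan


@pytest.fixture(scope="module")
def utrs_1000():
    spec = SyntheticTranscriptomeSpec(
        n_transcripts=1000, utr_length_median=300, rng_seed=77
    )
    return generate_transcriptome(spec)


@pytest.fixture(scope="module")
def index_1000(utrs_1000):
    return UtrIndex(utrs_1000, 7)


SCYL1_SEED = "CAUUGUU"  # positions 2-8 of the Scyl1 off-target guide


class TestScanUtrs:
    def test_planted_motif_found(self):
        rng = np.random.default_rng(4)
        motif = reverse_complement(NucleicSequence("s", SCYL1_SEED)).residues
        assert motif == "AACAAUG"
        utrs = [
            NucleicSequence("bg1", random_rna(rng, 50).replace("A", "C")),
            NucleicSequence("hit", "CCCC" + motif + "CCCC"),
            NucleicSequence("bg2", "U" * 60),
        ]
        smi = scan_utrs(NucleicSequence("s", SCYL1_SEED), utrs)
        assert smi.matched_ids == frozenset({"hit"})
        assert smi.match_count == 1

    def test_no_match(self):
        # the scan looks for the seed's reverse complement (UUUUUUU here),
        # which an all-A transcript cannot contain
        utrs = [NucleicSequence("u1", "AAAAAAAA")]
        smi = scan_utrs(NucleicSequence("s", "AAAAAAA"), utrs)
        assert smi.match_count == 0 and smi.matched_ids == frozenset()

    def test_overlapping_occurrences_counted(self):
        # motif AACAAUG cannot overlap itself, use a homopolymer seed
        utrs = [NucleicSequence("u1", "A" * 10)]  # 4 overlapping UUUUUUU RC hits
        smi = scan_utrs(NucleicSequence("s", "UUUUUUU"), utrs)
        assert smi.occurrence_counts == {"u1": 4}

    def test_agrees_with_naive_scan_on_random_utrs(self, utrs_1000, index_1000):
        rng = np.random.default_rng(123)
        for _ in range(5):
            seed = NucleicSequence("s", random_rna(rng, 7))
            smi = scan_utrs(seed, index=index_1000)
            naive = brute_scan(smi.motif.residues, utrs_1000)
            assert smi.occurrence_counts == naive
            assert smi.matched_ids == frozenset(naive)

    def test_empty_utr_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_utrs(NucleicSequence("s", SCYL1_SEED), [])


class TestDrawNullSeeds:
    def test_retained_are_closest_by_match_count(self, utrs_1000, index_1000):
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        nulls = draw_null_seeds(obs, n_draw=20, n_keep=5, rng_seed=1, index=index_1000)
        assert len(nulls) == 5
        # exhaustive check: re-draw the same 20 and verify the 5 kept have
        # the smallest |delta match count|
        all20 = draw_null_seeds(obs, n_draw=20, n_keep=20, rng_seed=1, index=index_1000)
        deltas = sorted(abs(nl.match_count - obs.match_count) for nl in all20)
        kept_deltas = sorted(abs(nl.match_count - obs.match_count) for nl in nulls)
        assert kept_deltas == deltas[:5]

    def test_keep_all_is_identity_on_draws(self, index_1000):
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        a = draw_null_seeds(obs, n_draw=30, n_keep=30, rng_seed=2, index=index_1000)
        assert len(a) == 30
        assert len({nl.seed.residues for nl in a}) == 30

    def test_observed_seed_excluded_and_deterministic(self, index_1000):
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        a = draw_null_seeds(obs, n_draw=200, n_keep=50, rng_seed=9, index=index_1000)
        b = draw_null_seeds(obs, n_draw=200, n_keep=50, rng_seed=9, index=index_1000)
        assert [x.seed.residues for x in a] == [x.seed.residues for x in b]
        assert SCYL1_SEED not in {x.seed.residues for x in a}

    def test_draw_space_exhaustion(self, index_1000):
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        with pytest.raises(ValueError, match="exceeds"):
            draw_null_seeds(obs, n_draw=4**7, n_keep=10, rng_seed=0, index=index_1000)


class TestSeedMatchEnrichment:
    def test_extreme_observation_hits_the_floor(self, utrs_1000, index_1000):
        """Plant the motif into every repressed transcript so the observed
        statistic exceeds all null values: p hits (1)/(n_keep+1)."""
        motif = reverse_complement(NucleicSequence("s", SCYL1_SEED)).residues
        utrs = [
            NucleicSequence(u.id, motif + u.residues) if i < 150 else u
            for i, u in enumerate(utrs_1000)
        ]
        repressed = {u.id for u in utrs[:150]}
        res = seed_match_enrichment(
            NucleicSequence("s", SCYL1_SEED), utrs, repressed,
            n_draw=400, n_keep=100, rng_seed=3,
        )
        assert res.observed == 150
        assert res.p_empirical == pytest.approx(1 / 101)
        assert res.p_gaussian < 1e-10

    def test_empty_repressed_set_rejected(self, utrs_1000):
        with pytest.raises(ValueError, match="degenerate"):
            seed_match_enrichment(
                NucleicSequence("s", SCYL1_SEED), utrs_1000, set(),
                n_draw=10, n_keep=5, rng_seed=0,
            )

    def test_unknown_repressed_ids_rejected(self, utrs_1000):
        with pytest.raises(ValueError, match="not in the UTR set"):
            seed_match_enrichment(
                NucleicSequence("s", SCYL1_SEED), utrs_1000, {"nope"},
                n_draw=10, n_keep=5, rng_seed=0,
            )

    def test_band_brackets_observed_when_possible(self, utrs_1000, index_1000):
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        repressed = {u.id for u in utrs_1000[:100]}
        res = seed_match_enrichment(
            NucleicSequence("s", SCYL1_SEED), None, repressed,
            n_draw=750, n_keep=200, rng_seed=4, index=index_1000,
        )
        lo, hi = res.band
        assert lo <= obs.match_count <= hi
        assert res.n_kept == 200 and len(res.null_values) == 200

    def test_relative_band_mode(self, utrs_1000, index_1000):
        repressed = {u.id for u in utrs_1000[:100]}
        res = seed_match_enrichment(
            NucleicSequence("s", SCYL1_SEED), None, repressed,
            n_draw=750, n_keep=50, rng_seed=4, index=index_1000,
            band_mode="relative", rel_tol=0.5,
        )
        obs = scan_utrs(NucleicSequence("s", SCYL1_SEED), index=index_1000)
        assert res.band[0] >= obs.match_count * 0.5 - 1e-9
        assert res.band[1] <= obs.match_count * 1.5 + 1e-9


class TestPoolOfftargetProfile:
    def test_single_guide_burden_binary(self, duplexes_15, utrs_1000):
        table = pool_offtarget_profile(duplexes_15[:1], utrs_1000)
        assert set(table["burden"].unique()) <= {0.0, 1.0}

    def test_dilution_arithmetic(self, utrs_1000, duplexes_15):
        t1 = pool_offtarget_profile(duplexes_15[:1], utrs_1000).set_index(
            "transcript_id"
        ).sort_index()
        t15 = pool_offtarget_profile(duplexes_15, utrs_1000).set_index(
            "transcript_id"
        ).sort_index()
        # the single guide's hits contribute exactly 1/15 burden in the pool
        hit_ids = t1.index[t1["matching_guides"] == 1]
        assert (t15.loc[hit_ids, "matching_guides"] >= 1).all()
        only = t15["matching_guides"] == t1["matching_guides"]
        assert np.allclose(
            t15.loc[only & (t1["matching_guides"] > 0), "burden"],
            t1.loc[only & (t1["matching_guides"] > 0), "matching_guides"] / 15,
        )

    def test_doubling_pool_with_nonmatching_guides_halves_burden(self):
        from sipoolkit.seqcore import SiRNADuplex, revcomp_str

        def duplex(name, seed):
            core = "C" + seed + "C" * 11  # guide positions 2-8 carry the seed
            return SiRNADuplex(
                name,
                guide=NucleicSequence("g", core + "UG"),
                passenger=NucleicSequence("p", revcomp_str(core) + "UG"),
            )

        matching = duplex("match", SCYL1_SEED)  # motif AACAAUG
        nonmatching = duplex("miss", "UCUCUCU")  # motif AGAGAGA, absent below
        utrs = [
            NucleicSequence("carrier1", "C" * 20 + "AACAAUG" + "C" * 20),
            NucleicSequence("carrier2", "AACAAUG" + "C" * 40),
            NucleicSequence("clean", "C" * 50),
        ]
        t1 = pool_offtarget_profile([matching], utrs).set_index("transcript_id")
        t2 = pool_offtarget_profile([matching, nonmatching], utrs).set_index(
            "transcript_id"
        )
        assert t1.loc["carrier1", "burden"] == 1.0
        assert np.allclose(t2["burden"], t1["burden"] / 2)

    def test_empty_pool_rejected(self, utrs_1000):
        with pytest.raises(ValueError, match="empty"):
            pool_offtarget_profile([], utrs_1000)
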