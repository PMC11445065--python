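"""Start model training, candidate enumeration/scoring, fractional resolution."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from altstart.homology import FlankedRegion
from altstart.simulate import (
    PlantedGeneSpec,
    SimulationConfig,
    generate_cohort,
    revcomp,
)
from altstart.startcall import (
    NoStopError,
    StartCandidate,
    StartModel,
    TrainingError,
    call_genome,
    enumerate_candidates,
    resolve_starts,
    score_candidates,
    train_start_model,
    truncate2,
)


def region_from(seq: str, hit_offset: int, hit_length: int, **kw) -> FlankedRegion:
    return FlankedRegion(
        sequence=seq,
        window_start=0,
        window_end=len(seq),
        hit_offset=hit_offset,
        hit_length=hit_length,
        left_flank=hit_offset,
        right_flank=len(seq) - hit_offset - hit_length,
        **kw,
    )


def cand(pos=0, codon="ATG", total=0.0, orf=300, rbs=True):
    c = StartCandidate(
        pos=pos, codon=codon, frame_anchor=0, stop_pos=pos + orf - 3, orf_length=orf
    )
    c.total_score = total
    c.rbs_present = rbs
    return c


class TestTraining:
    def test_dominant_codon_ranks_highest(self, trained_model):
        w = trained_model.start_weights
        assert w["ATG"] > w["GTG"] > w["TTG"]

    def test_hand_computed_smoothed_frequencies(self):
        """60 genes with counted codons 40/15/5 -> add-one smoothed log-odds
        against uniform 1/3: log(41/63*3), log(16/63*3), log(6/63*3)."""
        genes = []
        for i, codon in enumerate(["ATG"] * 40 + ["GTG"] * 15 + ["TTG"] * 5):
            genes.append(
                PlantedGeneSpec(f"t{i:02d}", orf_length=90, start_codon=codon,
                                sd_spacer=7)
            )
        cfg = SimulationConfig(seed=21, n_genomes=1,
                               contig_length=60 * 300 + 2000, genes=genes)
        cohort = generate_cohort(cfg)
        model = train_start_model(cohort.genomes["g000"], cohort.annotations["g000"])
        assert math.isclose(model.start_weights["ATG"], math.log(41 / 63 * 3))
        assert math.isclose(model.start_weights["GTG"], math.log(16 / 63 * 3))
        assert math.isclose(model.start_weights["TTG"], math.log(6 / 63 * 3))

    def test_planted_sd_motif_dominates_rbs_table(self):
        """All training genes carry AGGAGG at spacer 7 -> the (AGGAGG-
        containing k-mer, bin [7,9)) cell is the maximum of the table."""
        genes = [
            PlantedGeneSpec(f"t{i:02d}", orf_length=90, start_codon="ATG", sd_spacer=7)
            for i in range(60)
        ]
        cfg = SimulationConfig(seed=22, n_genomes=1,
                               contig_length=60 * 300 + 2000, genes=genes)
        cohort = generate_cohort(cfg)
        model = train_start_model(cohort.genomes["g000"], cohort.annotations["g000"])
        (kmer, bin_idx), _ = max(model.rbs_table.items(), key=lambda kv: kv[1])
        assert "AGGAGG" in kmer or kmer in "AGGAGG" * 2
        assert model.spacer_bins[bin_idx] == (7, 9)

    def test_too_few_genes_is_an_error(self):
        genes = [
            PlantedGeneSpec(f"t{i}", orf_length=90, start_codon="ATG")
            for i in range(10)
        ]
        cfg = SimulationConfig(seed=1, n_genomes=1, contig_length=6000, genes=genes)
        cohort = generate_cohort(cfg)
        with pytest.raises(TrainingError, match="larger training set"):
            train_start_model(cohort.genomes["g000"], cohort.annotations["g000"])

    def test_model_json_round_trip(self, trained_model):
        clone = StartModel.from_json(trained_model.to_json())
        assert clone.start_weights == trained_model.start_weights
        assert clone.rbs_table == trained_model.rbs_table
        assert clone.spacer_bins == trained_model.spacer_bins


class TestEnumerate:
    def test_single_start_single_candidate(self):
        seq = "CCCCCC" + "ATG" + "AAACCC" + "TAA" + "CCCCCC"
        region = region_from(seq, hit_offset=6, hit_length=12)
        cands = enumerate_candidates(region)
        assert [(c.pos, c.codon) for c in cands] == [(6, "ATG")]
        assert cands[0].orf_length == 12
        assert cands[0].stop_pos == 15

    def test_planted_secondary_start_six_apart_shares_stop(self):
        spec = PlantedGeneSpec(
            "lacI", orf_length=300, start_codon="GTG", secondary_start=("GTG", 6)
        )
        cfg = SimulationConfig(seed=13, n_genomes=1, contig_length=4000, genes=[spec])
        cohort = generate_cohort(cfg)
        row = cohort.manifest.iloc[0]
        contig = cohort.genomes[row.genome_id][row.contig_id]
        window = contig[row.start_pos - 75 : row.start_pos + 300 + 75]
        region = region_from(window, hit_offset=75, hit_length=300)
        cands = enumerate_candidates(region)
        near = [c for c in cands if abs(c.pos - 75) <= 9]
        assert [(c.pos, c.codon) for c in near] == [(75, "GTG"), (81, "GTG")]
        assert near[0].stop_pos == near[1].stop_pos

    def test_atgtg_overlap_exposes_only_the_in_frame_gtg(self):
        """The ATG of an ATGTG arrangement lies out of the hit frame and
        must not be proposed; its frame terminates immediately anyway."""
        spec = PlantedGeneSpec(
            "lacI", orf_length=300, start_codon="GTG", sd_spacer=6,
            atgtg_overlap=True,
        )
        cfg = SimulationConfig(seed=14, n_genomes=1, contig_length=4000, genes=[spec])
        cohort = generate_cohort(cfg)
        row = cohort.manifest.iloc[0]
        contig = cohort.genomes[row.genome_id][row.contig_id]
        assert contig[row.start_pos - 2 : row.start_pos + 3] == "ATGTG"
        window = contig[row.start_pos - 75 : row.start_pos + 300 + 75]
        region = region_from(window, hit_offset=75, hit_length=300)
        positions = {c.pos for c in enumerate_candidates(region)}
        assert 75 in positions and 73 not in positions

    def test_region_without_stop_is_an_error(self):
        region = region_from("CCC" * 30, hit_offset=3, hit_length=60)
        with pytest.raises(NoStopError):
            enumerate_candidates(region)


class TestScoring:
    def _two_regions_differing_in_codon(self):
        up = "CCCCCCCCCCCCAGGAGGCCCCCCC"  # AGGAGG at spacer 7
        tail = "AAACCC" + "TAA"
        return (
            region_from(up + "ATG" + tail, len(up), 12),
            region_from(up + "GTG" + tail, len(up), 12),
        )

    def test_score_difference_is_start_weight_difference(self, trained_model):
        ra, rg = self._two_regions_differing_in_codon()
        ca = score_candidates(enumerate_candidates(ra), trained_model, ra)
        cg = score_candidates(enumerate_candidates(rg), trained_model, rg)
        atg = [c for c in ca if c.pos == ra.hit_offset][0]
        gtg = [c for c in cg if c.pos == rg.hit_offset][0]
        assert math.isclose(
            atg.total_score - gtg.total_score,
            trained_model.start_weights["ATG"] - trained_model.start_weights["GTG"],
        )

    def test_planted_sd_beats_scrambled_upstream(self, trained_model):
        tail = "AAACCC" + "TAA"
        planted = "CCCCCCCCCCCCAGGAGGCCCCCCC" + "ATG" + tail
        scrambled = "CCCCCCCCCCCCAGAGGGCCCCCCC" + "ATG" + tail
        rp = region_from(planted, 25, 12)
        rs = region_from(scrambled, 25, 12)
        cp = score_candidates(enumerate_candidates(rp), trained_model, rp)[0]
        cs = score_candidates(enumerate_candidates(rs), trained_model, rs)[0]
        assert cp.rbs_score > cs.rbs_score

    def test_no_sd_like_kmer_means_no_rbs(self, trained_model):
        # upstream of C/T only: no vocabulary k-mer can occur
        seq = "CT" * 13 + "ATG" + "AAACCC" + "TAA"
        region = region_from(seq, 26, 12)
        c = score_candidates(enumerate_candidates(region), trained_model, region)[0]
        assert c.rbs_score == trained_model.no_motif_score
        assert not c.rbs_present

    def test_short_upstream_context_is_flagged(self, trained_model):
        seq = "CCC" + "ATG" + "AAACCC" + "TAA"
        region = region_from(seq, 3, 12)
        c = score_candidates(enumerate_candidates(region), trained_model, region)[0]
        assert c.truncated_context


class TestResolve:
    def test_fractional_counting_matches_worked_example(self):
        """Three retained equal candidates {ATG, GTG, GTG} -> 2/3 GTG and
        1/3 ATG, displayed truncated as 0.66 / 0.33."""
        cands = [
            cand(pos=0, codon="ATG", total=5.0),
            cand(pos=6, codon="GTG", total=5.0),
            cand(pos=9, codon="GTG", total=5.0),
        ]
        call = resolve_starts(cands, hit_length=300)
        assert call.weights["GTG"] == Fraction(2, 3)
        assert call.weights["ATG"] == Fraction(1, 3)
        assert call.display_weights()["GTG"] == 0.66
        assert call.display_weights()["ATG"] == 0.33

    def test_single_retained_candidate_gets_full_weight(self):
        call = resolve_starts([cand(codon="ATG", total=3.0)], hit_length=300)
        assert call.weights["ATG"] == 1

    def test_eighty_percent_score_threshold(self):
        """Scores 10.0 vs 7.9 with positive scores: 7.9 < 0.8*10 = 8.0, so
        only the top candidate survives."""
        cands = [
            cand(pos=0, codon="GTG", total=10.0, rbs=False),
            cand(pos=6, codon="ATG", total=7.9, rbs=False),
        ]
        call = resolve_starts(cands, hit_length=300)
        assert [c.total_score for c in call.retained] == [10.0]

    def test_score_ratio_well_defined_for_negative_scores(self):
        # both negative and nearly tied: shifted-ratio rule keeps both
        cands = [
            cand(pos=0, codon="GTG", total=-1.0),
            cand(pos=6, codon="ATG", total=-1.0),
        ]
        call = resolve_starts(cands, hit_length=300)
        assert len(call.retained) == 2

    def test_short_orf_candidates_dropped(self):
        cands = [
            cand(pos=0, codon="GTG", total=5.0, orf=300),
            cand(pos=60, codon="ATG", total=5.0, orf=240),  # 240 < 0.9*300
        ]
        call = resolve_starts(cands, hit_length=300)
        assert [c.codon for c in call.retained] == ["GTG"]
        assert "fragmented" in call.flags

    def test_rbs_consistency_rule(self):
        """Top candidate has an RBS -> RBS-less alternatives are dropped."""
        cands = [
            cand(pos=0, codon="GTG", total=5.0, rbs=True),
            cand(pos=6, codon="ATG", total=4.9, rbs=False),
        ]
        call = resolve_starts(cands, hit_length=300)
        assert [c.codon for c in call.retained] == ["GTG"]
        assert "rbs_filtered" in call.flags
        # without an RBS on top, both survive
        cands = [
            cand(pos=0, codon="GTG", total=5.0, rbs=False),
            cand(pos=6, codon="ATG", total=4.9, rbs=False),
        ]
        assert len(resolve_starts(cands, hit_length=300).retained) == 2

    def test_no_survivor_flags_no_candidate(self):
        call = resolve_starts([cand(codon="ATG", orf=100)], hit_length=300)
        assert call.flags[-1] == "no_candidate"
        assert all(w == 0 for w in call.weights.values())

    def test_resolution_soundness(self):
        """Every retained candidate satisfies all three rules; every dropped
        length-valid candidate violates at least one."""
        cands = [
            cand(pos=0, codon="GTG", total=10.0, rbs=True, orf=300),
            cand(pos=3, codon="ATG", total=9.5, rbs=False, orf=297),
            cand(pos=6, codon="TTG", total=5.0, rbs=True, orf=294),
            cand(pos=90, codon="ATG", total=10.0, rbs=True, orf=210),
        ]
        call = resolve_starts(cands, hit_length=300)
        retained = set(id(c) for c in call.retained)
        smax = max(c.total_score for c in cands if c.orf_length >= 270)
        for c in cands:
            ok_len = c.orf_length >= 0.9 * 300
            ok_score = c.total_score + 1e-9 >= 0.8 * (smax + 1e-9)
            ok_rbs = c.rbs_present
            if id(c) in retained:
                assert ok_len and ok_score and ok_rbs
            else:
                assert not (ok_len and ok_score and ok_rbs)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["ATG", "GTG", "TTG"]),
                st.floats(-5, 10, allow_nan=False),
                st.integers(200, 300),
                st.booleans(),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_weights_always_sum_to_one_or_flag(self, raw):
        cands = [
            cand(pos=3 * i, codon=c, total=s, orf=o, rbs=r)
            for i, (c, s, o, r) in enumerate(raw)
        ]
        call = resolve_starts(cands, hit_length=300)
        total = sum(call.weights.values())
        if call.retained:
            assert total == 1  # exact rational arithmetic
        else:
            assert total == 0 and "no_candidate" in call.flags


class TestTruncation:
    @pytest.mark.parametrize(
        "frac,shown",
        [(Fraction(2, 3), 0.66), (Fraction(1, 3), 0.33), (Fraction(1, 2), 0.5),
         (Fraction(1), 1.0), (Fraction(999, 1000), 0.99)],
    )
    def test_two_decimal_truncation_not_rounding(self, frac, shown):
        assert truncate2(frac) == shown


class TestCallGenome:
    def test_unambiguous_recovery_on_cohort(self, small_cohort, trained_model):
        refs = small_cohort.reference_sequences()
        for gid in sorted(small_cohort.genomes):
            calls = call_genome(
                small_cohort.genomes[gid], refs, trained_model, genome_id=gid
            )
            assert len(calls) == 1
            assert calls[0].weights["GTG"] == 1

    def test_missing_gene_flagged_absent_not_error(self, trained_model):
        import numpy as np

        rng = np.random.default_rng(99)
        genome = {"c1": "".join(rng.choice(list("ACGT"), size=3000))}
        calls = call_genome(genome, {"lacI": "ATG" + "CAC" * 98 + "TAA"},
                            trained_model, genome_id="gX")
        assert calls[0].flags == ("absent",)
        assert sum(calls[0].weights.values()) == 0

    def test_reverse_complement_invariance(self, trained_model):
        """Calling a gene on the - strand equals calling its + strand mirror."""
        spec = PlantedGeneSpec("cra", orf_length=240, start_codon="TTG",
                               sd_spacer=6, strand="-")
        cfg = SimulationConfig(seed=31, n_genomes=1, contig_length=3000,
                               genes=[spec])
        cohort = generate_cohort(cfg)
        genome = cohort.genomes["g000"]
        refs = cohort.reference_sequences()
        fwd = call_genome(genome, refs, trained_model, genome_id="g000")
        mirrored = {cid: revcomp(seq) for cid, seq in genome.items()}
        rev = call_genome(mirrored, refs, trained_model, genome_id="g000")
        assert fwd[0].weights == rev[0].weights
        assert fwd[0].weights["TTG"] == 1
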