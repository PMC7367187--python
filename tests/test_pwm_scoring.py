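"""PWM construction and 5'SS / branch-point log-ratio scoring."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronclass.pwm import (
    PositionWeightMatrix,
    build_pwm,
    position_labels,
    read_pwms,
    score_log_ratio,
    write_pwms,
)
from intronclass.scoring import (
    ScoreVector,
    best_bps,
    best_u12_motif,
    derive_empirical_u2_bps,
    score_five_prime,
    score_genome,
)

from conftest import make_intron, random_seq


def _random_pwm(rng, width=12, **kwargs):
    freqs = rng.dirichlet(np.ones(4), size=width)
    return PositionWeightMatrix(
        name="r", intron_class=kwargs.pop("intron_class", "U2"),
        motif=kwargs.pop("motif", "5SS"), subtype="GT-AG",
        offset=kwargs.pop("offset", -3), freqs=freqs,
    )


class TestBuildPwm:
    def test_unanimous_columns(self):
        pwm = build_pwm(["AG", "AG"])
        assert pwm.freqs[0].tolist() == [1.0, 0, 0, 0]
        assert pwm.freqs[1].tolist() == [0, 0, 1.0, 0]

    def test_split_column(self):
        pwm = build_pwm(["AG", "CG"])
        assert pwm.freqs[0].tolist() == [0.5, 0.5, 0, 0]

    def test_matches_counting_oracle(self, rng):
        seqs = [random_seq(rng, 12) for _ in range(50)]
        pwm = build_pwm(seqs)
        for i in range(12):
            for j, base in enumerate("ACGT"):
                count = sum(1 for s in seqs if s[i] == base)
                assert pwm.freqs[i, j] == pytest.approx(count / 50)

    def test_n_excluded_from_counts_and_totals(self):
        pwm = build_pwm(["AN", "AN", "AG"])
        assert pwm.freqs[0, 0] == 1.0
        assert pwm.freqs[1].tolist() == [0, 0, 1.0, 0]

    def test_empty_or_ragged_input_errors(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["AG", "AGG"])

    def test_position_labels_skip_zero(self):
        assert position_labels(-3, 12) == [-3, -2, -1] + list(range(1, 10))

    def test_pseudocount_never_flips_argmax(self, rng):
        """Adding the flat pseudo-count preserves each column's most
        frequent base whenever the frequency gap exceeds 0.002."""
        for _ in range(200):
            col = rng.dirichlet(np.ones(4))
            top2 = np.sort(col)[-2:]
            if top2[1] - top2[0] <= 0.002:
                continue
            assert np.argmax(col) == np.argmax(col + 0.001)


class TestScoreLogRatio:
    def test_identical_matrices_score_zero(self, rng):
        pwm = _random_pwm(rng)
        assert score_log_ratio(pwm, pwm, random_seq(rng, 12)) == pytest.approx(0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_swap_negates_score(self, seed):
        rng = np.random.default_rng(seed)
        u12, u2 = _random_pwm(rng), _random_pwm(rng)
        seq = random_seq(rng, 12)
        assert score_log_ratio(u12, u2, seq) == pytest.approx(
            -score_log_ratio(u2, u12, seq), abs=1e-9
        )

    def test_matches_product_then_log_oracle(self, rng):
        for _ in range(30):
            u12, u2 = _random_pwm(rng), _random_pwm(rng)
            seq = random_seq(rng, 12)
            num = math.prod(
                u12.freqs[i, "ACGT".index(b)] + 0.001 for i, b in enumerate(seq)
            )
            den = math.prod(
                u2.freqs[i, "ACGT".index(b)] + 0.001 for i, b in enumerate(seq)
            )
            assert score_log_ratio(u12, u2, seq) == pytest.approx(
                math.log2(num / den), abs=1e-9
            )

    def test_n_contributes_zero(self, rng):
        u12, u2 = _random_pwm(rng), _random_pwm(rng)
        seq = random_seq(rng, 12)
        with_n = "N" + seq[1:]
        expect = score_log_ratio(u12, u2, seq) - math.log2(
            (u12.freqs[0, "ACGT".index(seq[0])] + 0.001)
            / (u2.freqs[0, "ACGT".index(seq[0])] + 0.001)
        )
        assert score_log_ratio(u12, u2, with_n) == pytest.approx(expect, abs=1e-9)

    def test_length_mismatch_errors(self, rng):
        u12, u2 = _random_pwm(rng), _random_pwm(rng)
        with pytest.raises(ValueError):
            score_log_ratio(u12, u2, "ACGT")


class TestFivePrimeScoring:
    def test_u12_consensus_scores_positive(self, pwm_set):
        u12 = pwm_set.select("U12", "5SS", "GT-AG")
        intron = make_intron(
            u12.consensus()[3:] + "C" * 80 + "AG",
            upstream="A" * 47 + u12.consensus()[:3],
        )
        assert score_five_prime(intron, pwm_set) > 0

    def test_u2_consensus_scores_negative(self, pwm_set):
        u2 = pwm_set.select("U2", "5SS", "GT-AG")
        intron = make_intron(
            u2.consensus()[3:] + "C" * 80 + "AG",
            upstream="A" * 47 + u2.consensus()[:3],
        )
        assert score_five_prime(intron, pwm_set) < 0

    def test_matches_log_ratio_oracle_per_intron(self, pwm_set, rng):
        for _ in range(100):
            intron = make_intron("GT" + random_seq(rng, 60) + "AG",
                                 upstream=random_seq(rng, 50))
            got = score_five_prime(intron, pwm_set)
            u12 = pwm_set.select("U12", "5SS", intron.subtype)
            u2 = pwm_set.select("U2", "5SS", intron.subtype)
            assert got == pytest.approx(
                score_log_ratio(u12, u2, intron.seq_5ss), abs=1e-12
            )

    def test_too_short_intron_returns_none(self, pwm_set):
        intron = make_intron("GT" + "A" * 16 + "AG")  # 20 nt
        assert intron.too_short
        assert score_five_prime(intron, pwm_set) is None


class TestBestBps:
    def test_51nt_region_scans_exactly_40_candidates(self, rng):
        """Oracle: enumerate the 12-mers of a 51-nt region by hand."""
        u12, u2 = _random_pwm(rng), _random_pwm(rng)
        intron = make_intron("GT" + random_seq(rng, 96) + "AG")
        region = intron.seq_bps_region
        assert len(region) == 51
        candidates = [region[i:i + 12] for i in range(len(region) - 11)]
        assert len(candidates) == 40
        hit = best_bps(intron, u12, u2)
        scores = [score_log_ratio(u12, u2, k) for k in candidates]
        assert hit.log_ratio == pytest.approx(max(scores))
        assert hit.motif_seq == candidates[hit.position]

    def test_planted_motif_position_returned(self, pwm_set, rng):
        u12 = pwm_set.select("U12", "BPS", "GT-AG")
        u2 = _random_pwm(rng, motif="BPS", offset=1)
        motif = u12.consensus()
        for planted in (3, 20, 39):
            region = random_seq(rng, 51)
            region = region[:planted] + motif + region[planted + 12:]
            intron = make_intron(
                "GT" + random_seq(rng, 43) + region + "AG"[-2:])
            intron.seq_bps_region = region  # plant directly in the window
            hit = best_bps(intron, u12, u2)
            assert hit.position == planted
            assert hit.motif_seq == motif

    def test_tie_broken_to_three_prime_most(self, rng):
        motif = "ACGTACGTACGT"
        u12 = build_pwm([motif], intron_class="U12", motif="BPS")
        u2 = PositionWeightMatrix(
            "uniform", "U2", "BPS", "GT-AG", 1, np.full((12, 4), 0.25))
        region = motif + "C" * 10 + motif + "C" * 17
        intron = make_intron("GT" + "A" * 80 + "AG")
        intron.seq_bps_region = region
        hit = best_bps(intron, u12, u2)
        assert hit.position == 22

    def test_region_shorter_than_12_returns_none(self, rng):
        u12, u2 = _random_pwm(rng), _random_pwm(rng)
        intron = make_intron("GT" + "A" * 10 + "AG")
        assert len(intron.seq_bps_region) < 12
        assert best_bps(intron, u12, u2) is None


class TestEmpiricalU2Bps:
    def _introns(self, rng, n=100):
        return [
            make_intron("GT" + random_seq(rng, 70) + "AG",
                        upstream=random_seq(rng, 50))
            for _ in range(n)
        ]

    def test_matches_quantile_then_filter_oracle(self, pwm_set, rng):
        introns = self._introns(rng)
        scores = [score_five_prime(i, pwm_set) for i in introns]
        pwm = derive_empirical_u2_bps(introns, scores, pwm_set)
        # oracle: numpy linear-interpolation quantile, strict filter,
        # independent best-motif search, counting PWM
        cutoff = np.percentile(np.array(scores), 95)
        u12_bps = pwm_set.select("U12", "BPS", "GT-AG")
        motifs = []
        for intron, s in zip(introns, scores):
            if s >= cutoff:
                continue
            region = intron.seq_bps_region
            best = max(
                (u12_bps.log_probability(region[i:i + 12]), i)
                for i in range(len(region) - 11)
            )
            motifs.append(region[best[1]:best[1] + 12])
        oracle = build_pwm(motifs)
        assert np.allclose(pwm.freqs, oracle.freqs)
        assert pwm.intron_class == "U2"

    def test_homogeneous_scores_hit_error_path(self, pwm_set, rng):
        introns = self._introns(rng, n=30)
        scores = [1.5] * 30
        with pytest.raises(ValueError, match="degenerate|no introns"):
            derive_empirical_u2_bps(introns, scores, pwm_set)

    def test_too_few_introns_error(self, pwm_set, rng):
        introns = self._introns(rng, n=10)
        scores = [float(i) for i in range(10)]
        with pytest.raises(ValueError, match="at least"):
            derive_empirical_u2_bps(introns, scores, pwm_set)

    def test_selection_distribution_converges(self, pwm_set, rng):
        """On uniform-random BPS regions the derived matrix converges (by
        the law of large numbers) to a fixed selection distribution: two
        independent halves at n=5000 agree columnwise within 0.05.

        The limit is not the uniform distribution: picking each region's
        best-scoring 12-mer biases columns toward the U12 consensus, and
        that selection bias does not vanish with n.
        """
        halves = []
        for _ in range(2):
            introns = self._introns(rng, n=2500)
            scores = [score_five_prime(i, pwm_set) for i in introns]
            halves.append(
                derive_empirical_u2_bps(introns, scores, pwm_set).freqs)
        assert np.abs(halves[0] - halves[1]).max() < 0.05


class TestScoreGenome:
    def test_empty_input_empty_output(self, pwm_set):
        vectors, pwm = score_genome([], pwm_set)
        assert vectors == [] and pwm is None

    def test_composition_oracle_single_intron(self, pwm_set, rng):
        """Scoring many introns then reading one off equals composing
        score_five_prime and best_bps by hand with the same empirical
        U2 BPS matrix."""
        introns = [
            make_intron("GT" + random_seq(rng, 70) + "AG",
                        upstream=random_seq(rng, 50))
            for _ in range(50)
        ]
        vectors, u2_bps = score_genome(introns, pwm_set)
        target = introns[7]
        v = vectors[7]
        assert v.five_ss == pytest.approx(score_five_prime(target, pwm_set))
        hit = best_bps(target, pwm_set.select("U12", "BPS", "GT-AG"), u2_bps)
        assert v.bps == pytest.approx(hit.log_ratio)
        assert v.bps_motif.motif_seq == hit.motif_seq

    def test_too_short_flagged_never_dropped(self, pwm_set, rng):
        introns = [
            make_intron("GT" + random_seq(rng, 70) + "AG") for _ in range(30)
        ] + [make_intron("GT" + "A" * 16 + "AG")]
        vectors, _ = score_genome(introns, pwm_set)
        assert len(vectors) == len(introns)
        assert vectors[-1].too_short and vectors[-1].five_ss is None

    def test_planted_classes_separate(self, pwm_set, sim_genome):
        """Planted U12 introns occupy the positive-positive quadrant of
        the (5'SS, BPS) score plane and 5'SS scores separate the classes
        when the consensus motifs differ at several positions."""
        from intronclass.pipeline import extract_all_introns

        introns = extract_all_introns(
            sim_genome.gff3, sim_genome.genome, feature="cds",
            assembly=sim_genome.config.assembly,
        )
        vectors, _ = score_genome(introns, pwm_set)
        truth = sim_genome.truth.set_index("intron_id")["intron_class"]
        u12 = [v for v in vectors if truth[v.intron_id] == "U12"]
        u2 = [v for v in vectors if truth[v.intron_id] == "U2"]
        assert u12 and u2
        assert all(v.five_ss > 0 and v.bps > 0 for v in u12)
        assert min(v.five_ss for v in u12) > max(v.five_ss for v in u2)


def test_pwm_file_round_trip(pwm_set):
    buf = io.StringIO()
    write_pwms(pwm_set.matrices(), buf)
    back = read_pwms(buf)
    originals = {p.name: p for p in pwm_set.matrices()}
    assert set(p.name for p in back) == set(originals)
    for p in back:
        o = originals[p.name]
        assert (p.intron_class, p.motif, p.subtype, p.offset) == (
            o.intron_class, o.motif, o.subtype, o.offset)
        assert np.array_equal(p.freqs, o.freqs)
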