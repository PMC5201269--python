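import itertools
import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chapnet.io import GeneModel
from chapnet.motifs import (
    EBOX_CONSENSUS,
    MotifHit,
    consensus_to_pwm,
    extract_promoter,
    mutation_effect,
    pwm_null_distribution,
    revcomp,
    scan_consensus,
    scan_pwm,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=200)


def regex_oracle_positions(seq: str, consensus: str = EBOX_CONSENSUS) -> set[int]:
    """Overlapping match starts of the consensus on the + reading, by regex."""
    iupac = {"C": "C", "A": "A", "N": "[ACGT]", "T": "T", "G": "G"}
    pat = "(?=(" + "".join(iupac[c] for c in consensus) + "))"
    return {m.start() for m in re.finditer(pat, seq)}


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------


class TestExtractPromoter:
    def test_plus_strand_coordinates(self):
        rng = np.random.default_rng(0)
        contig = "".join(rng.choice(list("ACGT"), size=1500))
        genome = {"chrI": contig}
        model = GeneModel("g", "chrI", 1001, 1200, "+")
        prom = extract_promoter(genome, model, length=1000)
        assert prom.sequence == contig[:1000]
        assert not prom.truncated

    def test_minus_strand_ends_with_revcomp_of_downstream(self):
        # - gene with TSS at its end; the 6-mer just 3' of the TSS on the -
        # strand is the revcomp of the 6-mer just right of TSS on +
        contig = "A" * 100 + "CAGGTG" + "A" * 100
        genome = {"c": contig}
        model = GeneModel("g", "c", 50, 100, "-")  # TSS at 1-based 100
        prom = extract_promoter(genome, model, length=20)
        assert prom.sequence.endswith(revcomp("CAGGTG"))

    def test_truncation_flagged(self):
        genome = {"c": "ACGT" * 200}
        model = GeneModel("g", "c", 501, 600, "+")
        prom = extract_promoter(genome, model, length=1000)
        assert prom.truncated
        assert len(prom) == 500

    def test_missing_contig_raises(self):
        with pytest.raises(KeyError):
            extract_promoter({}, GeneModel("g", "c", 10, 20, "+"))


# ---------------------------------------------------------------------------
# consensus scanning
# ---------------------------------------------------------------------------


class TestScanConsensus:
    def test_direct_match(self):
        hits = scan_consensus("TTCAGGTGAA")
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "±"
        assert h.tss_relative_position == 2 - 10  # leftmost base of CAGGTG

    def test_mutated_site_no_hits(self):
        assert scan_consensus("TTCAGGTGAA") != []
        assert scan_consensus("TTACGCGTAA") == []

    def test_palindromic_class_reported_once(self):
        seq = "AACATTTGAA"  # CATTTG matches; revcomp window CAAATG also matches
        hits = scan_consensus(seq)
        assert [h.strand for h in hits] == ["±"]

    def test_case_invariance(self):
        assert scan_consensus("ttcaggtgaa") == scan_consensus("TTCAGGTGAA")

    def test_non_palindromic_consensus_reports_both_strands(self):
        # ACGG on + at 1; CCGT (its revcomp) on + at 8 means a - strand hit
        hits = scan_consensus("AACGGTTTCCGTAA", consensus="ACGG")
        strands = {h.strand for h in hits}
        assert strands == {"+", "-"}

    @given(DNA)
    @settings(max_examples=100, deadline=None)
    def test_matches_regex_oracle(self, seq):
        got = {h.tss_relative_position + len(seq) for h in scan_consensus(seq)}
        assert got == regex_oracle_positions(seq)

    def test_random_10kb_matches_oracle(self):
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        got = {h.tss_relative_position + len(seq) for h in scan_consensus(seq)}
        assert got == regex_oracle_positions(seq)


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------


class TestConsensusToPwm:
    def test_n_column_uniform_background_zero_log_odds(self):
        model = consensus_to_pwm("N")
        np.testing.assert_allclose(model.log_odds, np.zeros((4, 1)), atol=1e-12)

    def test_fixed_column_limit(self):
        alpha = 1e-9
        model = consensus_to_pwm("C", pseudocount=alpha)
        c_row = model.log_odds[1, 0]
        assert c_row == pytest.approx(math.log2(4 * (1 - 3 * alpha)), abs=1e-6)
        assert model.log_odds[0, 0] < -20  # strongly negative, finite

    def test_max_word_symmetry_across_n_positions(self):
        model = consensus_to_pwm(EBOX_CONSENSUS, pseudocount=0.01)
        def score(word):
            idx = {"A": 0, "C": 1, "G": 2, "T": 3}
            return sum(model.log_odds[idx[b], j] for j, b in enumerate(word))
        scores = {w: score(f"CA{w}TG") for w in ("AA", "AC", "GT", "TT", "CG")}
        vals = list(scores.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            consensus_to_pwm("CANNTG", pseudocount=0.0)
        with pytest.raises(ValueError):
            consensus_to_pwm("CAXNTG")


# ---------------------------------------------------------------------------
# exact null distribution
# ---------------------------------------------------------------------------


def brute_force_tail(model, score, bin_width=1e-3):
    """P(score >= s) by enumerating all 4^w words (probabilities from background)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    sbin = round(score / bin_width)
    total = 0.0
    for word in itertools.product("ACGT", repeat=model.width):
        wbin = sum(round(model.log_odds[idx[b], j] / bin_width) for j, b in enumerate(word))
        if wbin >= sbin:
            total += math.prod(model.background[idx[b]] for b in word)
    return total


class TestPwmNullDistribution:
    def test_width_one_uniform(self):
        model = consensus_to_pwm("A", pseudocount=0.1)
        null = pwm_null_distribution(model)
        # 4 distinct scores, each with mass 0.25 under uniform background
        masses = np.diff(np.concatenate([null.tail_probs[::-1], [1.0]]))
        assert null.tail(null.max_score) == pytest.approx(0.25)

    def test_total_mass_one(self):
        model = consensus_to_pwm(EBOX_CONSENSUS)
        null = pwm_null_distribution(model)
        assert null.tail_probs[0] == pytest.approx(1.0, abs=1e-9)

    def test_ebox_max_score_tail_is_1_over_256(self):
        model = consensus_to_pwm(EBOX_CONSENSUS, pseudocount=0.01)
        null = pwm_null_distribution(model)
        assert null.tail(null.max_score) == pytest.approx(1 / 256, rel=1e-9)

    @pytest.mark.parametrize("consensus", ["A", "CG", "CAT", "RYN", "CANNTG", "SWKMBD"])
    def test_matches_brute_force_enumeration(self, consensus):
        model = consensus_to_pwm(consensus, pseudocount=0.05)
        null = pwm_null_distribution(model)
        # probe the tail at every achieved bin score
        for b in null.bins:
            s = float(b) * null.bin_width
            assert null.tail(s) == pytest.approx(
                brute_force_tail(model, s), abs=1e-9
            ), (consensus, s)

    def test_nonuniform_background(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        model = consensus_to_pwm("CAT", pseudocount=0.05, background=bg)
        null = pwm_null_distribution(model)
        for b in null.bins[::3]:
            s = float(b) * null.bin_width
            assert null.tail(s) == pytest.approx(brute_force_tail(model, s), abs=1e-9)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------


class TestScanPwm:
    def test_planted_site_recovered(self):
        rng = np.random.default_rng(7)
        # AT-only background cannot contain CANNTG or score high
        seq = list("".join(rng.choice(list("AT"), size=300)))
        seq[100:106] = list("CAGGTG")
        seq = "".join(seq)
        model = consensus_to_pwm(EBOX_CONSENSUS)
        hits = scan_pwm(seq, model, p_threshold=1 / 256 + 1e-9)
        assert [h.tss_relative_position for h in hits] == [100 - 300]

    def test_vacuous_threshold_hits_every_window(self):
        seq = "ACGTACGTACGT"
        model = consensus_to_pwm("NN")
        hits = scan_pwm(seq, model, p_threshold=1.0)
        # palindromic NN model: every window reported once with strand ±
        assert len(hits) == len(seq) - 2 + 1

    def test_revcomp_mirrors_hits(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        model = consensus_to_pwm(EBOX_CONSENSUS)
        fwd = scan_pwm(seq, model, p_threshold=0.01)
        rev = scan_pwm(revcomp(seq), model, p_threshold=0.01)
        L = len(seq)
        fwd_pos = sorted(h.tss_relative_position + L for h in fwd)
        # a window at i maps to L - w - i on the reverse complement
        rev_pos = sorted(L - model.width - (h.tss_relative_position + L) for h in rev)
        assert fwd_pos == rev_pos

    def test_short_sequence_empty(self):
        model = consensus_to_pwm(EBOX_CONSENSUS)
        assert scan_pwm("ACG", model) == []


# ---------------------------------------------------------------------------
# mutation effects
# ---------------------------------------------------------------------------


class TestMutationEffect:
    def _promoter_with_sites(self, positions, L=1000, seed=4):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list("AT"), size=L)))
        for pos in positions:
            i = L + pos
            seq[i : i + 6] = list("CAGGTG")
        return "".join(seq)

    def test_acgcgt_substitution_abolishes_hit(self):
        model = consensus_to_pwm(EBOX_CONSENSUS)
        for pos in (-432, -921, -266):
            seq = self._promoter_with_sites([pos])
            before, after = mutation_effect(seq, pos, "ACGCGT", model)
            assert pos in {h.tss_relative_position for h in before}
            assert pos not in {h.tss_relative_position for h in after}

    def test_identity_substitution_keeps_hits(self):
        seq = self._promoter_with_sites([-432])
        model = consensus_to_pwm(EBOX_CONSENSUS)
        window = seq[1000 - 432 : 1000 - 432 + 6]
        before, after = mutation_effect(seq, -432, window, model)
        assert before == after

    def test_locality_of_edits(self):
        # windows farther than w-1 from the edit are unchanged
        model = consensus_to_pwm(EBOX_CONSENSUS)
        rng = np.random.default_rng(21)
        for trial in range(20):
            L = 400
            seq = "".join(rng.choice(list("ACGT"), size=L))
            pos = int(rng.integers(-L + 6, -6))
            repl = "".join(rng.choice(list("ACGT"), size=6))
            before, after = mutation_effect(seq, pos, repl, model)
            edit_lo, edit_hi = pos, pos + 6
            w = 6
            far_before = {
                h.tss_relative_position
                for h in before
                if h.tss_relative_position + w <= edit_lo - 0 or h.tss_relative_position >= edit_hi
            }
            far_after = {
                h.tss_relative_position
                for h in after
                if h.tss_relative_position + w <= edit_lo - 0 or h.tss_relative_position >= edit_hi
            }
            assert far_before == far_after

    def test_out_of_bounds_edit_raises(self):
        model = consensus_to_pwm(EBOX_CONSENSUS)
        with pytest.raises(ValueError):
            mutation_effect("ACGTACGT", -20, "ACGCGT", model)


def test_motif_hit_validation():
    with pytest.raises(ValueError):
        MotifHit("g", -10, "+", 1.0, 0.0)
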