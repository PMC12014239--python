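"""Leader motif compilation, mismatch counting and tandem parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinoretro import (
    DINORL,
    DINOSL,
    DINOSL_TRUNC,
    build_pfm,
    classify_arrangements,
    compile_motif,
    count_mismatches,
    default_motifs,
    scan_5prime,
)
from dinoretro.transcripts import Transcript

from conftest import random_seq

SL_A = "A" + DINOSL[1:]  # DinoSL with the degenerate D resolved to A


def brute_force_mismatches(window, motif):
    """Independent per-position loop over expanded IUPAC sets."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return sum(
        1
        for w, p in zip(window.upper().replace("U", "T"), motif.pattern)
        if w not in iupac[p]
    )


def brute_force_retro_call(seq, budget=5, max_offset=0, allow_truncated=False,
                           budget_scope="total"):
    """Exhaustive search over all SL placements and RL segmentations."""
    motifs = default_motifs()
    sl, rl, trunc = motifs["DinoSL"], motifs["DinoRL"], motifs["DinoSL_trunc"]
    seq = seq.upper().replace("U", "T")
    specs = [sl] + ([trunc] if allow_truncated else [])
    for spec in specs:
        for start in range(max_offset + 1):
            if start + len(spec) > len(seq):
                continue
            mm = brute_force_mismatches(seq[start:start + len(spec)], spec)
            if mm > budget:
                continue
            # try every possible number of consecutive RL units
            pos, total, n_rl = start + len(spec), mm, 0
            while pos + len(rl) <= len(seq):
                unit = brute_force_mismatches(seq[pos:pos + len(rl)], rl)
                if budget_scope == "total":
                    if total + unit > budget:
                        break
                    total += unit
                else:
                    if unit > budget:
                        break
                pos += len(rl)
                n_rl += 1
            if n_rl >= 1:
                return True
    return False


class TestCompileMotif:
    def test_dinosl_degenerate_first_position(self):
        spec = compile_motif("DinoSL", DINOSL)
        assert len(spec) == 22
        assert spec.allowed_sets[0] == frozenset("AGT")
        assert all(len(s) == 1 for s in spec.allowed_sets[1:])

    def test_acgt_singletons_and_case_u_normalization(self):
        assert compile_motif("X", "acgu") == compile_motif("X", "ACGT")
        assert all(len(s) == 1 for s in compile_motif("X", "ACGT").allowed_sets)

    def test_unknown_code_names_position_and_char(self):
        with pytest.raises(ValueError, match=r"'X' at position 2"):
            compile_motif("bad", "ACXGT")

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            compile_motif("empty", "")


class TestCountMismatches:
    def test_self_match_and_single_violation(self):
        sl = compile_motif("DinoSL", DINOSL)
        assert count_mismatches(SL_A, sl) == 0
        assert count_mismatches("C" + DINOSL[1:], sl) == 1  # C not in D={A,G,T}

    def test_n_in_window_always_mismatches(self):
        rl = compile_motif("DinoRL", DINORL)
        assert count_mismatches("N" + DINORL[1:], rl) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_mismatches("ACGT", compile_motif("DinoRL", DINORL))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        sl = compile_motif("DinoSL", DINOSL)
        window = random_seq(rng, 22)
        assert count_mismatches(window, sl) == brute_force_mismatches(window, sl)


class TestScan5Prime:
    def test_perfect_tandem_is_sl_rl(self, rng):
        seq = SL_A + DINORL + random_seq(rng, 300)
        arr = scan_5prime(seq, budget=5)
        assert arr is not None
        assert arr.arrangement_class == "SL-RL"
        assert arr.total_mismatches == 0
        assert (arr.leader_start, arr.leader_end) == (0, 37)

    def test_sl_without_rl_is_absent(self, rng):
        while True:
            tail = random_seq(rng, 300)
            if brute_force_mismatches(tail[:15], compile_motif("rl", DINORL)) > 5:
                break
        assert scan_5prime(SL_A + tail) is None

    def test_mutated_double_rl_within_and_beyond_budget(self, rng):
        leader = list(SL_A + DINORL + DINORL)
        for pos in (3, 25, 30):  # one substitution in SL, two in the first RL
            leader[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[leader[pos]]
        seq = "".join(leader) + random_seq(rng, 200)
        arr = scan_5prime(seq, budget=5)
        assert arr is not None and arr.arrangement_class == "SL-RL-RL"
        assert arr.total_mismatches == 3
        assert scan_5prime(seq, budget=2) is None

    def test_short_transcript_is_absent_not_error(self):
        assert scan_5prime(SL_A) is None

    def test_case_and_u_spelling_invariance(self, rng):
        seq = SL_A + DINORL + random_seq(rng, 100)
        arr = scan_5prime(seq)
        low = scan_5prime(seq.lower())
        rna = scan_5prime(seq.replace("T", "U"))
        assert low is not None and rna is not None
        for other in (low, rna):
            assert other.arrangement_class == arr.arrangement_class
            assert other.total_mismatches == arr.total_mismatches

    def test_budget_monotonicity(self, rng):
        seqs = []
        for _ in range(80):
            core = list(SL_A + DINORL * int(rng.integers(1, 3)))
            for pos in rng.choice(len(core), size=int(rng.integers(0, 7)), replace=False):
                core[pos] = str(rng.choice([b for b in "ACGT" if b != core[pos]]))
            seqs.append("".join(core) + random_seq(rng, 60))
        for b in range(0, 8):
            called_b = {i for i, s in enumerate(seqs) if scan_5prime(s, budget=b)}
            called_b1 = {i for i, s in enumerate(seqs) if scan_5prime(s, budget=b + 1)}
            assert called_b <= called_b1

    def test_truncated_leader_only_called_when_allowed(self, rng):
        seq = DINOSL_TRUNC + DINORL + random_seq(rng, 200)
        assert scan_5prime(seq) is None
        arr = scan_5prime(seq, allow_truncated=True)
        assert arr is not None and arr.truncated_leader
        assert arr.arrangement_class == "SLt-RL"

    def test_matches_brute_force_on_random_and_planted_battery(self, rng):
        for allow_trunc in (False, True):
            for i in range(200):
                kind = i % 4
                if kind == 0:
                    seq = random_seq(rng, int(rng.integers(20, 400)))
                else:
                    head = DINOSL_TRUNC if kind == 3 else SL_A
                    core = list(head + DINORL * int(rng.integers(0, 4)))
                    nmut = int(rng.integers(0, 8))
                    for pos in rng.choice(len(core), size=min(nmut, len(core)), replace=False):
                        core[pos] = str(rng.choice([b for b in "ACGT" if b != core[pos]]))
                    seq = "".join(core) + random_seq(rng, 150)
                got = scan_5prime(seq, budget=5, max_offset=2,
                                  allow_truncated=allow_trunc) is not None
                want = brute_force_retro_call(seq, budget=5, max_offset=2,
                                              allow_truncated=allow_trunc)
                assert got == want, seq[:60]


class TestClassifyArrangements:
    def test_counts_and_multi_fraction(self, rng):
        arrs = [scan_5prime(SL_A + DINORL + random_seq(rng, 50)) for _ in range(3)]
        arrs.append(scan_5prime(SL_A + DINORL * 2 + random_seq(rng, 50)))
        summary = classify_arrangements(arrs)
        assert summary.counts == {"SL-RL": 3, "SL-RL-RL": 1}
        assert summary.multi_rl_fraction == pytest.approx(0.25)

    def test_empty_input(self):
        summary = classify_arrangements([])
        assert summary.counts == {}
        assert np.isnan(summary.multi_rl_fraction)

    def test_simulated_class_fractions_match_planted_weights(self):
        from dinoretro import SimParams, generate_transcriptome

        params = SimParams(
            n_normal=0, n_retro=400, rl_count_weights={1: 0.95, 2: 0.05},
            p_truncate5=0, p_trunc_leader=0, leader_mut_rate=0, dup_rate=0,
            seed=5,
        )
        res = generate_transcriptome(params)
        arrs = [a for t in res.transcripts if (a := scan_5prime(t)) is not None]
        summary = classify_arrangements(arrs)
        frac2 = summary.counts.get("SL-RL-RL", 0) / summary.n_total
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(frac2 - 0.05) <= 3 * se
        assert summary.multi_rl_fraction == pytest.approx(frac2)


class TestBuildPfm:
    def test_identical_leaders_give_unit_columns(self, rng):
        txs = [Transcript(f"t{i}", SL_A + DINORL + random_seq(rng, 40)) for i in range(5)]
        arrs = [scan_5prime(t) for t in txs]
        pfm = build_pfm(arrs, txs, window_len=37)
        assert pfm.covered.all()
        assert np.allclose(np.nanmax(pfm.frequencies[:37], axis=1), 1.0)

    def test_degenerate_first_column_near_uniform_thirds(self):
        from dinoretro import SimParams, generate_transcriptome

        params = SimParams(n_normal=0, n_retro=600, p_truncate5=0,
                           p_trunc_leader=0, leader_mut_rate=0, dup_rate=0, seed=9)
        res = generate_transcriptome(params)
        arrs = [scan_5prime(t) for t in res.transcripts]
        pfm = build_pfm(arrs, res.transcripts, window_len=22)
        se = np.sqrt((1 / 3) * (2 / 3) / 600)
        for base_idx in (0, 2, 3):  # A, G, T
            assert abs(pfm.frequencies[0, base_idx] - 1 / 3) <= 3 * se
        assert pfm.frequencies[0, 1] == 0.0  # C never at D

    def test_column_frequencies_sum_to_one(self, rng):
        txs = [Transcript(f"t{i}", SL_A + DINORL + random_seq(rng, 10)) for i in range(4)]
        arrs = [scan_5prime(t) for t in txs]
        pfm = build_pfm(arrs, txs, window_len=60)
        sums = np.nansum(pfm.frequencies[pfm.covered], axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert not pfm.covered[55]  # past every transcript end
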