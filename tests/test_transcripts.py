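"""Length filter, redundancy collapse and ORF extraction."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from dinoretro import (
    Transcript,
    collapse_redundancy,
    find_longest_orf,
    length_filter,
    pairwise_identity,
)

from conftest import random_seq

_GAP = 1.0 + 2.0**-20


def dp_identity(sa: str, sb: str) -> float:
    """Semiglobal DP oracle: match 1, mismatch 0, internal gap -(1+2^-20),
    end gaps free; identity = matched positions / shorter length."""
    n, m = len(sa), len(sb)
    S = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = S[i - 1][j - 1] + (1.0 if sa[i - 1] == sb[j - 1] else 0.0)
            up = S[i - 1][j] - (0.0 if j == m else _GAP)
            left = S[i][j - 1] - (0.0 if i == n else _GAP)
            S[i][j] = max(diag, up, left)
    score = S[n][m]
    q = math.ceil(score - 1e-9)
    g = round((q - score) * 2**20)
    return (q + g) / min(n, m)


def brute_force_orf(seq, min_aa, require_start):
    """Enumerate every candidate (start, stop-or-end) pair in all 3 frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for frame in range(3):
        starts = []
        if not require_start:
            starts.append(frame)
        for p in range(frame, len(seq) - 2, 3):
            if seq[p : p + 3] == "ATG":
                starts.append(p)
        for s in starts:
            e = None
            has_stop = False
            p = s
            while p + 3 <= len(seq):
                if seq[p : p + 3] in stops:
                    e, has_stop = p + 3, True
                    break
                p += 3
            if e is None:
                e = s + 3 * ((len(seq) - s) // 3)
            n_aa = (e - s) // 3 - (1 if has_stop else 0)
            if n_aa < min_aa:
                continue
            # drop candidates that merely shorten another in the same segment
            key = (-n_aa, s)
            if best is None or key < best[0]:
                pep = str(Seq(seq[s : e - (3 if has_stop else 0)]).translate())
                best = (key, s, e, n_aa, pep)
    return best


class TestLengthFilter:
    def test_boundary_kept_at_geq(self, rng):
        txs = [Transcript(f"t{n}", random_seq(rng, n)) for n in (150, 200, 450)]
        kept = length_filter(txs, 200)
        assert [t.length for t in kept] == [200, 450]

    def test_empty_input(self):
        assert length_filter([], 200) == []

    def test_matches_predicate_filter(self, rng):
        txs = [
            Transcript(f"t{i}", random_seq(rng, int(rng.integers(50, 400))))
            for i in range(60)
        ]
        assert length_filter(txs, 200) == [t for t in txs if t.length >= 200]


class TestPairwiseIdentity:
    def test_identical_and_prefix(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0
        assert pairwise_identity("ACGTACGT", "ACGT") == 1.0

    def test_symmetry(self, rng):
        a, b = random_seq(rng, 80), random_seq(rng, 120)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_matches_dp_oracle_on_random_60mers(self, rng):
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(40, 61)))
            b = random_seq(rng, int(rng.integers(40, 61)))
            assert pairwise_identity(a, b) == pytest.approx(dp_identity(a, b))

    def test_unrelated_unequal_lengths_stay_below_threshold(self, rng):
        a, b = random_seq(rng, 200), random_seq(rng, 2000)
        assert pairwise_identity(a, b) < 0.9


class TestCollapseRedundancy:
    def test_identical_pair_plus_unrelated(self, rng):
        seq = random_seq(rng, 300)
        txs = [
            Transcript("b", seq),
            Transcript("a", seq),
            Transcript("c", random_seq(rng, 300)),
        ]
        clusters = collapse_redundancy(txs)
        assert len(clusters) == 2
        pair = next(c for c in clusters if len(c.member_ids) == 2)
        assert pair.representative_id == "a"  # lexicographic tie-break

    def test_truncated_mutated_copy_joins_parent(self, rng):
        a = random_seq(rng, 1000)
        b = list(a[:900])
        for i in rng.choice(900, size=18, replace=False):  # 2% substitutions
            b[i] = str(rng.choice([c for c in "ACGT" if c != b[i]]))
        b = "".join(b)
        assert dp_identity(a, b) >= 0.90  # oracle confirms designed identity
        clusters = collapse_redundancy([Transcript("A", a), Transcript("B", b)], 0.90)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "A"

    def test_every_transcript_in_exactly_one_cluster(self, noisy_sim):
        txs = noisy_sim.transcripts[:80]
        clusters = collapse_redundancy(txs)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(t.id for t in txs)

    def test_representative_dominates_members(self, noisy_sim):
        txs = noisy_sim.transcripts[:80]
        lengths = {t.id: t.length for t in txs}
        for c in collapse_redundancy(txs):
            assert all(lengths[m] <= lengths[c.representative_id] for m in c.member_ids)

    def test_idempotent_on_representatives(self, noisy_sim):
        txs = noisy_sim.transcripts[:80]
        clusters = collapse_redundancy(txs)
        by_id = {t.id: t for t in txs}
        reps = [by_id[c.representative_id] for c in clusters]
        again = collapse_redundancy(reps)
        assert all(len(c.member_ids) == 1 for c in again)


class TestFindLongestOrf:
    def test_minimal_orf_with_stop(self):
        call = find_longest_orf(Transcript("t", "ATGAAATAA"), min_aa=2)
        assert (call.start, call.end) == (0, 9)
        assert call.peptide == "MK"
        assert call.frame == 0 and not call.partial5

    def test_all_stops_gives_absent(self):
        assert find_longest_orf(Transcript("t", "TAATAATAATAA"), min_aa=1) is None

    def test_partial5_without_start_codon(self):
        seq = "AAAAAACCCCCCTAA"
        call = find_longest_orf(Transcript("t", seq), min_aa=3, require_start=False)
        assert call is not None and call.partial5
        assert call.start == 0

    def test_translation_reproduces_peptide(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 600)
            call = find_longest_orf(Transcript("t", seq), min_aa=10)
            if call is None:
                continue
            cds = seq[call.start : call.end]
            assert (call.end - call.start) % 3 == 0
            pep = str(Seq(cds).translate())
            assert pep.rstrip("*") == call.peptide

    @pytest.mark.parametrize("require_start", [True, False])
    def test_matches_brute_force_enumeration(self, rng, require_start):
        for _ in range(100):
            seq = random_seq(rng, 1000)
            call = find_longest_orf(Transcript("t", seq), min_aa=5,
                                    require_start=require_start)
            want = brute_force_orf(seq, 5, require_start)
            if want is None:
                assert call is None
            else:
                assert call is not None
                assert (call.start, call.end) == (want[1], want[2])
                assert call.peptide == want[4]

    def test_intact_cds_longer_than_decayed(self, clean_sim):
        # retrogenes with premature stops injected mid-CDS yield shorter
        # peptides than their intact counterparts
        peps_intact, peps_decayed = [], []
        for t in clean_sim.transcripts[:80]:
            call = find_longest_orf(t, min_aa=10)
            if call is None:
                continue
            peps_intact.append(len(call.peptide))
            mid = call.start + 3 * (len(call.peptide) // 3)
            broken = t.seq[:mid] + "TAA" + t.seq[mid + 3 :]
            bcall = find_longest_orf(Transcript(t.id, broken), min_aa=10)
            if bcall is not None:
                peps_decayed.append(len(bcall.peptide))
        assert np.mean(peps_intact) > np.mean(peps_decayed)
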