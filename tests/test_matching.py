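import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import porescreen as ps
from porescreen.reference import concatenate_documents

from .oracles import NaiveFM, lcp_strings, naive_ms

dna = st.text(alphabet="ACGT", min_size=1, max_size=50)
patterns = st.text(alphabet="ACGT", min_size=1, max_size=12)


def index_of(doc: str, mode=ps.MODE_MS):
    return ps.build_index(concatenate_documents([doc]), mode=mode)


class TestLF:
    def test_lf_is_a_permutation(self):
        idx = index_of("ACGTACGT")
        row, seen = 0, set()
        for _ in range(idx.n):
            assert row not in seen
            seen.add(row)
            row = ps.lf_step(idx, row)
        assert seen == set(range(idx.n))
        assert row == 0  # one full cycle

    @settings(derandomize=True, max_examples=30)
    @given(dna)
    def test_matches_naive_rank(self, s):
        idx = index_of(s)
        fm = NaiveFM(idx.text.text)
        for row in range(idx.n):
            ch = fm.bwt[row]
            if ch != "$":
                assert ps.lf_step(idx, row) == fm.C[ch] + fm.rank(ch, row)

    def test_run_linearity(self):
        idx = index_of("ACGTACGTACGTTTT")
        lens = np.diff(np.append(idx.run_starts, idx.n))
        for start, length in zip(idx.run_starts, lens):
            base = ps.lf_step(idx, int(start))
            for k in range(int(length)):
                assert ps.lf_step(idx, int(start) + k) == base + k


class TestJump:
    def test_single_candidate_sides(self):
        idx = index_of("ACGTACGT")
        bwt = idx.decode_bwt()
        for c in "ACGT":
            rows = [i for i, ch in enumerate(bwt) if ch == c]
            # row above all c-runs -> first row of the first c-run below
            for row in range(rows[0]):
                if bwt[row] != c:
                    assert ps.jump(idx, row, c) == (rows[0], "succ")
            # row below all c-runs -> last row of the last c-run above
            for row in range(rows[-1] + 1, idx.n):
                if bwt[row] != c:
                    assert ps.jump(idx, row, c) == (rows[-1], "pred")

    def test_absent_character_raises(self):
        idx = index_of("AAAA")
        with pytest.raises(ValueError):
            ps.jump(idx, 0, "G")

    @settings(derandomize=True, max_examples=30)
    @given(dna)
    def test_jump_maximizes_common_prefix(self, s):
        """The threshold rule must pick whichever boundary row's suffix has
        the longest common prefix with the current row's suffix."""
        idx = index_of(s)
        fm = NaiveFM(idx.text.text)
        suffixes = [idx.text.text[p:] for p in fm.sa]
        for row in range(idx.n):
            for c in set(s):
                if fm.bwt[row] == c:
                    continue
                new_row, side = ps.jump(idx, row, c)
                assert fm.bwt[new_row] == c
                above = [i for i in range(row) if fm.bwt[i] == c]
                below = [i for i in range(row + 1, idx.n) if fm.bwt[i] == c]
                candidates = ([above[-1]] if above else []) + (
                    [below[0]] if below else []
                )
                best = max(
                    lcp_strings(suffixes[row], suffixes[cand]) for cand in candidates
                )
                assert lcp_strings(suffixes[row], suffixes[new_row]) == best


class TestMatchingStatistics:
    def test_worked_example(self):
        idx = index_of("ACGTACGT")
        assert ps.matching_statistics(idx, "GTAC").values.tolist() == [4, 3, 2, 1]

    def test_full_document_self_match(self):
        doc = "ACGTGGATCC"
        idx = index_of(doc)
        ms = ps.matching_statistics(idx, doc).values
        assert ms.tolist() == [len(doc) - i for i in range(len(doc))]

    def test_absent_characters_give_zero(self):
        idx = index_of("ACGTACGT")
        assert ps.matching_statistics(idx, "NNN").values.tolist() == [0, 0, 0]

    def test_empty_pattern(self):
        idx = index_of("ACGT")
        assert len(ps.matching_statistics(idx, "")) == 0

    def test_requires_ms_mode(self):
        idx = index_of("ACGT", mode=ps.MODE_PML)
        with pytest.raises(ps.CapabilityError):
            ps.matching_statistics(idx, "ACGT")

    @settings(derandomize=True, max_examples=150)
    @given(dna, patterns)
    def test_equals_brute_force_oracle(self, s, p):
        idx = index_of(s)
        assert ps.matching_statistics(idx, p).values.tolist() == naive_ms([s], p)

    @settings(derandomize=True, max_examples=50)
    @given(dna, patterns)
    def test_ms_recurrence_bound(self, s, p):
        """MS[i] <= MS[i+1] + 1: dropping the first character costs at
        most one unit of match length."""
        idx = index_of(s)
        ms = ps.matching_statistics(idx, p).values
        assert all(ms[i] <= ms[i + 1] + 1 for i in range(len(ms) - 1))

    def test_multidoc_matches_do_not_cross_documents(self):
        idx = ps.build_index(concatenate_documents(["AAAA", "CCCC"]), mode=ps.MODE_MS)
        # "AACC" spans the document boundary and must not be found whole
        ms = ps.matching_statistics(idx, "AACC").values
        assert ms.tolist() == naive_ms(["AAAA", "CCCC"], "AACC")
        assert ms[0] == 2


class TestPMLStep:
    def test_first_base_mismatch_resets_to_zero(self):
        # BWT row 0 holds the character preceding the terminator ('G'
        # here), so feeding 'C' is a genuine first-base mismatch
        idx = index_of("CCGG", mode=ps.MODE_PML)
        state = ps.StreamState()
        state, value = ps.pml_step(idx, state, "C")
        assert value == 0
        assert state.bases_consumed == 1

    @settings(derandomize=True, max_examples=40)
    @given(dna, patterns)
    def test_increment_or_reset_semantics(self, s, p):
        """Each PML is either the previous one plus one (BWT agreement)
        or exactly zero (jump/reset); the first value is 0 or 1."""
        idx = index_of(s, mode=ps.MODE_PML)
        vals = ps.pseudo_matching_lengths(idx, p)[0].values
        assert vals[0] in (0, 1)
        for prev, cur in zip(vals, vals[1:]):
            assert cur == prev + 1 or cur == 0

    def test_homopolymer_climb(self):
        # every step over an all-A index matches the BWT character, so the
        # PML climbs by exactly one per base after the initial step
        idx = index_of("AAAAAAAA", mode=ps.MODE_PML)
        vals = ps.pseudo_matching_lengths(idx, "AAAA")[0].values
        assert np.all(np.diff(vals) == 1)

    def test_absent_character_is_universal_mismatch(self, toy_pml_index):
        state = ps.StreamState(row=5, length=3, bases_consumed=7)
        new_state, value = ps.pml_step(toy_pml_index, state, "N")
        assert value == 0
        assert new_state.length == 0
        assert new_state.row == 5  # row unchanged
        assert new_state.bases_consumed == 8

    @settings(derandomize=True, max_examples=60)
    @given(dna, patterns)
    def test_equals_naive_fm_oracle(self, s, p):
        """The streaming engine must agree base-for-base with the same
        rules run over flat (non-run-length) FM structures."""
        idx = index_of(s, mode=ps.MODE_PML)
        fm = NaiveFM(s + "$")
        profile, _ = ps.pseudo_matching_lengths(idx, p)
        assert profile.values.tolist() == fm.pml(p)


class TestStreaming:
    @settings(derandomize=True, max_examples=50)
    @given(dna, patterns, st.integers(min_value=1, max_value=11))
    def test_chunked_equals_whole(self, s, p, cut):
        idx = index_of(s, mode=ps.MODE_PML)
        whole, end_state = ps.pseudo_matching_lengths(idx, p)
        cut = min(cut, len(p))
        first, state = ps.pseudo_matching_lengths(idx, p[:cut])
        second, state = ps.pseudo_matching_lengths(idx, p[cut:], state)
        assert np.concatenate([first.values, second.values]).tolist() == (
            whole.values.tolist()
        )
        assert state == end_state

    def test_empty_pattern_keeps_state(self, toy_pml_index):
        state = ps.StreamState(row=3, length=2, bases_consumed=5)
        profile, out = ps.pseudo_matching_lengths(toy_pml_index, "", state)
        assert len(profile) == 0
        assert out == state


class TestPMLDominance:
    @settings(derandomize=True, max_examples=100)
    @given(dna, patterns)
    def test_pml_never_exceeds_ms(self, s, p):
        """PMLs ignore jump-mediated extensions, so they can only
        undershoot the true matching statistics."""
        idx = index_of(s, mode=ps.MODE_MS)
        # consuming the read in arrival order computes the statistics of
        # the reversed read as a pattern
        pml, _ = ps.pseudo_matching_lengths(idx, p)
        ms = ps.matching_statistics(idx, p[::-1]).values
        assert np.all(pml.values[::-1] <= ms)


class TestComplexity:
    def test_probe_count_scales_linearly(self):
        """Run-table probes per base stay O(1) as the query doubles."""
        rng = np.random.default_rng(99)
        doc = "".join(rng.choice(list("ACGT"), size=4000))
        idx = index_of(doc, mode=ps.MODE_PML)
        per_base = []
        for m in (250, 500, 1000, 2000):
            read = "".join(rng.choice(list("ACGT"), size=m))
            idx.probes = 0
            ps.pseudo_matching_lengths(idx, read)
            per_base.append(idx.probes / m)
        assert max(per_base) <= 4  # bounded probes per base
        assert max(per_base) / min(per_base) < 1.5  # no growth with m
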