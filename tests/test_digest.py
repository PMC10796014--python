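"""Chitinosanase cleavage, the block theorem and block statistics."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chitosim import (
    PaSequence,
    block_stats,
    digest,
    digest_and_score,
    parse_sequence,
    patterned_polymer,
    random_polymer,
    true_blocks,
)
from chitosim._errors import UndefinedStatisticsError

sequences = st.text(alphabet="AD", min_size=1, max_size=200)


def oracle_fragments(units: str) -> list[str]:
    """Independent regex route: shortest prefixes ending in DA, then the rest."""
    return re.findall(r"[AD]*?DA|[AD]+$", units)


class TestDigest:
    @pytest.mark.parametrize(
        "units,expected",
        [
            ("DDAAADDA", ["DDA", "AADDA"]),
            ("ADADAD", ["ADA", "DA", "D"]),
            ("AAAA", ["AAAA"]),
            ("DA", ["DA"]),
        ],
    )
    def test_examples(self, units, expected):
        fragments = digest(parse_sequence(units))
        assert [f.sequence.units for f in fragments] == expected
        assert fragments[0].is_leading
        assert fragments[-1].is_trailing

    @settings(max_examples=300, derandomize=True)
    @given(sequences)
    def test_partition_and_conservation(self, units):
        fragments = digest(parse_sequence(units))
        assert "".join(f.sequence.units for f in fragments) == units
        assert sum(f.nA for f in fragments) == units.count("A")
        assert [f.sequence.units for f in fragments] == oracle_fragments(units)

    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_interior_fragments_end_with_da(self, units):
        for f in digest(parse_sequence(units)):
            if not f.is_trailing:
                assert f.sequence.units.endswith("DA")


class TestTrueBlocks:
    @pytest.mark.parametrize(
        "units,a_blocks,d_blocks",
        [
            ("DDAAADDA", [3, 1], [2, 2]),
            ("AAAA", [4], []),
            ("ADADAD", [1, 1, 1], [1, 1, 1]),
        ],
    )
    def test_examples(self, units, a_blocks, d_blocks):
        assert true_blocks(parse_sequence(units)) == (a_blocks, d_blocks)

    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_lengths_sum_to_dp(self, units):
        a, d = true_blocks(parse_sequence(units))
        assert sum(a) + sum(d) == len(units)


def interior_block_oracle(units: str) -> list[tuple[int, int]]:
    """(nA, nD) expected for each interior fragment, from run lengths.

    Cleavage happens after the first A of every A-run preceded by a D-run, so
    the k-th interior fragment holds the full k-th cut A-run (tail + the next
    fragment-opening A) and the D-run before the (k+1)-th cut.
    """
    runs = [(m.group(0)[0], len(m.group(0))) for m in re.finditer(r"A+|D+", units)]
    # every A-run preceded by a D-run carries a cut after its first A, except
    # a single final A, whose cut would coincide with the chain end
    cut_runs = [
        i for i in range(1, len(runs))
        if runs[i][0] == "A" and not (i == len(runs) - 1 and runs[i][1] == 1)
    ]
    out = []
    for k in range(len(cut_runs) - 1):
        a_len = runs[cut_runs[k]][1]
        d_len = runs[cut_runs[k + 1] - 1][1]
        out.append((a_len, d_len))
    return out


class TestBlockTheorem:
    @settings(max_examples=200, derandomize=True)
    @given(sequences)
    def test_interior_composition_equals_block_sizes(self, units):
        fragments = [f for f in digest(parse_sequence(units)) if f.is_interior]
        assert [(f.nA, f.nD) for f in fragments] == interior_block_oracle(units)

    def test_on_random_polymers(self):
        for seed in range(25):
            seq = random_polymer(800, 0.35, seed)
            fragments = [f for f in digest(seq) if f.is_interior]
            assert [(f.nA, f.nD) for f in fragments] == interior_block_oracle(seq.units)

    def test_blocky_polymer_fragments(self):
        seq = patterned_polymer(1000, "blocky", a_len=3, d_len=2)
        for f in digest(seq):
            if f.is_interior:
                assert (f.nA, f.nD) == (3, 2)


class TestBlockStats:
    def test_printed_formula_oracle(self):
        table = pd.DataFrame(
            {"DP": [2, 5], "NA": [1, 3], "ND": [1, 2], "I": [2.0, 1.0]}
        )
        stats = block_stats(table)
        assert stats.blockA_w == pytest.approx(19 / 9, abs=1e-12)
        # blockD_w from the same weights: (2·2·1 + 5·1·2) / 9
        assert stats.blockD_w == pytest.approx(14 / 9, abs=1e-12)

    def test_alternating_dimer(self):
        table = pd.DataFrame({"DP": [2], "NA": [1], "ND": [1], "I": [1.0]})
        stats = block_stats(table)
        assert stats.blockA_w == 1.0
        assert stats.blockD_w == 1.0
        assert stats.oligomeric_fraction == 1.0

    def test_window_share(self):
        table = pd.DataFrame(
            {"DP": [2, 20], "NA": [1, 10], "ND": [1, 10], "I": [2.0, 5.0]}
        )
        stats = block_stats(table)
        assert stats.oligomeric_fraction == pytest.approx(4 / (4 + 100))

    def test_all_zero_intensity_errors(self):
        table = pd.DataFrame({"DP": [2], "NA": [1], "ND": [1], "I": [0.0]})
        with pytest.raises(UndefinedStatisticsError):
            block_stats(table)


class TestDigestAndScore:
    def test_alternating_polymer(self):
        _, stats = digest_and_score(patterned_polymer(1000, "alternating"))
        assert stats.blockA_w == 1.0
        assert stats.blockD_w == 1.0

    def test_oracle_equality_with_true_blocks(self):
        """Digest-based block(A)_w equals the DP·I-weighted mean over the
        interior run-length pairs from true_blocks."""
        seq = random_polymer(2000, 0.4, seed=42)
        table, stats = digest_and_score(seq, weighting="mass",
                                        dp_window=(2, 10**9))
        pairs = interior_block_oracle(seq.units)
        dp = np.array([a + d for a, d in pairs])
        na = np.array([a for a, _ in pairs])
        nd = np.array([d for _, d in pairs])
        w = dp * dp  # mass weighting: I ∝ count·DP, formula weights by DP·I
        assert stats.blockA_w == pytest.approx((w * na).sum() / w.sum())
        assert stats.blockD_w == pytest.approx((w * nd).sum() / w.sum())

    def test_homopolymer_errors(self):
        with pytest.raises(UndefinedStatisticsError):
            digest_and_score(PaSequence("A" * 100))

    def test_molar_vs_mass_weighting(self):
        seq = random_polymer(2000, 0.4, seed=7)
        t_molar, _ = digest_and_score(seq, weighting="molar")
        t_mass, _ = digest_and_score(seq, weighting="mass")
        merged = t_molar.merge(t_mass, on=["DP", "NA", "ND"], suffixes=("_m", "_w"))
        assert np.allclose(merged["I_w"], merged["I_m"] * merged["DP"])

    def test_oligomeric_fraction_monotone_in_block_size(self):
        """Larger blocks at fixed F_A push signal beyond DP 14."""
        fractions = []
        for a_len in (2, 6, 12, 20):
            seq = patterned_polymer(4000, "blocky", a_len=a_len, d_len=a_len)
            _, stats = digest_and_score(seq)
            fractions.append(stats.oligomeric_fraction)
        assert all(x >= y - 1e-12 for x, y in zip(fractions, fractions[1:]))

    def test_bernoulli_closed_form_convergence(self):
        """For i.i.d. chains, digest block(A)_w converges to the run-length
        expectation simulated directly from true_blocks with mass weighting.

        Interior products pair each cut A-block (one preceded by a D-block)
        with the D-block before the next cut, so the expectation is computed
        from the true run-length lists alone.
        """

        def pairs_from_true_blocks(units: str) -> list[tuple[int, int]]:
            a, d = true_blocks(parse_sequence(units))
            cut_a = a[1:] if units[0] == "A" else a
            return [
                (cut_a[k], d[k + 1])
                for k in range(len(cut_a) - 1)
                if k + 1 < len(d)
            ]

        digest_vals, oracle_vals = [], []
        for seed in range(20):
            seq = random_polymer(100_000, 0.3, seed)
            _, stats = digest_and_score(seq, weighting="mass", dp_window=(2, 10**9))
            digest_vals.append(stats.blockA_w)
            pairs = pairs_from_true_blocks(seq.units)
            w = np.array([(a + d) ** 2 for a, d in pairs], dtype=float)
            na = np.array([a for a, _ in pairs], dtype=float)
            oracle_vals.append(float((w * na).sum() / w.sum()))
        assert np.mean(digest_vals) == pytest.approx(np.mean(oracle_vals), rel=0.02)
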