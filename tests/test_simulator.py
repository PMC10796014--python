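"""Binding-frame enumeration, Boltzmann event selection and trajectories."""

import math

import numpy as np
import pytest
import scipy.stats

from chitosim import (
    PRESETS,
    PaSequence,
    SimulationConfig,
    SubsiteProfile,
    enumerate_frames,
    frame_energy,
    parse_sequence,
    product_distribution,
    simulate_polymer,
    step,
)
from chitosim._errors import (
    ChitosimValidationError,
    EnumerationTooLargeError,
    StalledReactionError,
)
from chitosim.digest import digest_and_score

# the worked example profile: GlcNAc favoured at −2 and −1, +1 occupancy term
EXAMPLE = SubsiteProfile.from_dict(
    {-2: {"A": -3.0}, -1: {"A": -1.0}, 1: {"empty": 1.0}}
)
NEUTRAL = PRESETS["neutral"]


class TestFrames:
    def test_all_a_tetramer(self):
        frames = enumerate_frames(parse_sequence("AAAA"), "deacetylate")
        assert [f.span_label for f in frames] == ["[0,+3]", "[-1,+2]", "[-2,+1]", "[-3,0]"]

    def test_eligibility(self):
        frames = enumerate_frames(parse_sequence("AADA"), "deacetylate")
        assert [f.subsite0_position for f in frames] == [1, 2, 4]
        assert enumerate_frames(parse_sequence("DDDD"), "deacetylate") == []
        assert [
            f.subsite0_position
            for f in enumerate_frames(parse_sequence("AADA"), "N-acetylate")
        ] == [3]

    def test_covered_subsites(self):
        frame = enumerate_frames(parse_sequence("AAAA"), "deacetylate")[2]
        assert frame.span_label == "[-2,+1]"
        assert frame.covered_subsites == (-2, -1, 0, 1)


class TestFrameEnergy:
    def test_worked_sum(self):
        seq = parse_sequence("AAAA")
        frame = enumerate_frames(seq, "deacetylate")[2]  # [-2,+1]
        assert frame_energy(seq, frame, EXAMPLE) == pytest.approx(-4.0)

    def test_neutral_profile_is_zero(self):
        seq = parse_sequence("ADAD")
        for frame in enumerate_frames(seq, "deacetylate"):
            assert frame_energy(seq, frame, NEUTRAL) == 0.0

    def test_hard_exclusion_propagates(self):
        profile = SubsiteProfile.from_dict({-2: {"D": "inf"}})
        seq = parse_sequence("DAAA")
        frame = [f for f in enumerate_frames(seq, "deacetylate") if f.subsite0_position == 3][0]
        assert frame_energy(seq, frame, profile) == math.inf


class TestStep:
    def test_uniform_limit(self, rng):
        """With a neutral profile all four frames of A4 are equally likely."""
        counts = np.zeros(4)
        seq = parse_sequence("AAAA")
        for _ in range(10_000):
            _, frame = step(seq, NEUTRAL, "deacetylate", rng)
            counts[frame.subsite0_position - 1] += 1
        assert scipy.stats.chisquare(counts).pvalue > 0.01

    def test_boltzmann_frequencies(self, rng):
        """Empirical frame frequencies match exp(−E) shares within 3σ."""
        seq = parse_sequence("AAAA")
        frames = enumerate_frames(seq, "deacetylate")
        energies = np.array([frame_energy(seq, f, EXAMPLE) for f in frames])
        expected = np.exp(-energies) / np.exp(-energies).sum()
        n = 10_000
        counts = np.zeros(4)
        for _ in range(n):
            _, frame = step(seq, EXAMPLE, "deacetylate", rng)
            counts[frame.subsite0_position - 1] += 1
        for k in range(4):
            sigma = math.sqrt(n * expected[k] * (1 - expected[k]))
            assert abs(counts[k] - n * expected[k]) < 3 * sigma

    def test_stalled(self, rng):
        with pytest.raises(StalledReactionError):
            step(parse_sequence("DDDD"), NEUTRAL, "deacetylate", rng)
        all_inf = SubsiteProfile.from_dict({0: {"A": "inf"}})
        with pytest.raises(StalledReactionError):
            step(parse_sequence("AAAA"), all_inf, "deacetylate", rng)


class TestProductDistribution:
    def test_uniform_single_event(self):
        dist = product_distribution(parse_sequence("AAAA"), NEUTRAL, "deacetylate", 1)
        assert set(dist) == {"DAAA", "ADAA", "AADA", "AAAD"}
        for p in dist.values():
            assert p == pytest.approx(0.25)

    def test_boltzmann_share_closed_form(self):
        dist = product_distribution(parse_sequence("AAAA"), EXAMPLE, "deacetylate", 1)
        w = [math.exp(0), math.exp(1), math.exp(4), math.exp(3)]
        assert dist["AADA"] == pytest.approx(w[2] / sum(w), abs=1e-12)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_strong_minus2_preference_dominates(self):
        profile = SubsiteProfile.from_dict({-2: {"A": -10.0}})
        dist = product_distribution(parse_sequence("AAAA"), profile, "deacetylate", 1)
        # frames placing an A at subsite −2 are those at positions 3 and 4
        assert dist["AADA"] + dist["AAAD"] > 0.99

    def test_matches_monte_carlo(self, rng):
        dist = product_distribution(parse_sequence("AAAA"), EXAMPLE, "deacetylate", 2)
        n = 4000
        counts: dict[str, int] = {}
        seq = parse_sequence("AAAA")
        for _ in range(n):
            s1, _ = step(seq, EXAMPLE, "deacetylate", rng)
            s2, _ = step(s1, EXAMPLE, "deacetylate", rng)
            counts[s2.units] = counts.get(s2.units, 0) + 1
        for product, p in dist.items():
            sigma = math.sqrt(n * p * (1 - p)) or 1.0
            assert abs(counts.get(product, 0) - n * p) < 3 * sigma + 1

    def test_size_cap(self):
        with pytest.raises(EnumerationTooLargeError):
            product_distribution(PaSequence("A" * 20), NEUTRAL, "deacetylate", 5)


class TestSimulatePolymer:
    def test_stop_criterion_and_snapshot(self, d_polymer):
        config = SimulationConfig(
            direction="N-acetylate", seed=1, target_fa=0.3, checkpoints=(0.3,)
        )
        traj = simulate_polymer(d_polymer, NEUTRAL, config)
        assert traj.final.fa == pytest.approx(0.3, abs=1 / d_polymer.dp)
        assert traj.snapshots[0.3].fa == pytest.approx(0.3, abs=1 / d_polymer.dp)
        assert not traj.stalled

    def test_determinism(self, d_polymer):
        config = SimulationConfig(
            direction="N-acetylate", seed=7, target_fa=0.2, checkpoints=(0.1, 0.2)
        )
        t1 = simulate_polymer(d_polymer, PRESETS["nm"], config)
        t2 = simulate_polymer(d_polymer, PRESETS["nm"], config)
        assert t1.final.units == t2.final.units
        assert [e.position for e in t1.events] == [e.position for e in t2.events]
        assert {k: v.units for k, v in t1.snapshots.items()} == {
            k: v.units for k, v in t2.snapshots.items()
        }

    def test_conservation_along_trajectory(self, d_polymer):
        config = SimulationConfig(direction="N-acetylate", seed=3, max_events=50)
        traj = simulate_polymer(d_polymer, PRESETS["H199Y"], config)
        assert traj.final.dp == d_polymer.dp
        fas = [e.fa for e in traj.events]
        # F_A strictly increases by exactly 1/dp per N-acetylation event
        deltas = np.diff([d_polymer.fa] + fas)
        assert np.allclose(deltas, 1 / d_polymer.dp)

    def test_large_polymer(self):
        seq = PaSequence("D" * 10_000)
        config = SimulationConfig(direction="N-acetylate", seed=5, target_fa=0.1)
        traj = simulate_polymer(seq, PRESETS["nm"], config)
        assert traj.final.fa == pytest.approx(0.1, abs=1e-4)

    def test_stall_flag_on_exhaustion(self):
        seq = PaSequence("DDDD")
        config = SimulationConfig(direction="N-acetylate", seed=1, max_events=10)
        traj = simulate_polymer(seq, NEUTRAL, config)
        assert traj.stalled
        assert traj.final.units == "AAAA"

    def test_direction_precondition(self, d_polymer):
        config = SimulationConfig(direction="deacetylate", seed=1, target_fa=0.3)
        with pytest.raises(ChitosimValidationError):
            simulate_polymer(d_polymer, NEUTRAL, config)  # fa already below target

    def test_checkpoint_monotonicity_validated(self):
        with pytest.raises(ChitosimValidationError):
            SimulationConfig(
                direction="N-acetylate", seed=1, target_fa=0.5, checkpoints=(0.3, 0.1)
            )


class TestPreferenceEffects:
    def test_blocky_preset_exceeds_random(self):
        """GlcNAc preference at −2/−1 yields larger digest A-blocks than random."""
        from chitosim import random_polymer

        block_enzyme, block_random = [], []
        for seed in range(8):
            config = SimulationConfig(
                direction="N-acetylate", seed=seed, target_fa=0.3
            )
            traj = simulate_polymer(PaSequence("D" * 1000), PRESETS["H199K"], config)
            _, stats = digest_and_score(traj.final)
            block_enzyme.append(stats.blockA_w)
            _, stats = digest_and_score(random_polymer(1000, 0.3, seed + 100))
            block_random.append(stats.blockA_w)
        assert np.mean(block_enzyme) > np.mean(block_random)

    def test_alternating_preset_enriches_a1d1(self):
        """GlcN acceptance at −1 with GlcNAc preference at −2 gives A1D1 products."""
        from chitosim import random_polymer

        def a1d1_share(seq):
            table, _ = digest_and_score(seq, weighting="molar")
            return float(
                table.loc[(table.DP == 2) & (table.NA == 1), "I"].sum()
                / table["I"].sum()
            )

        enz, ctrl = [], []
        for seed in range(8):
            config = SimulationConfig(direction="N-acetylate", seed=seed, target_fa=0.5)
            traj = simulate_polymer(PaSequence("D" * 1000), PRESETS["H199Y"], config)
            enz.append(a1d1_share(traj.final))
            ctrl.append(a1d1_share(random_polymer(1000, 0.5, seed + 200)))
        assert np.mean(enz) > np.mean(ctrl)

    def test_monotone_minus1_penalty_ladder(self):
        """Penalizing GlcN at −1 never shrinks mean digest block(A)_w."""
        means = []
        for penalty in (0.0, 0.75, 1.5):
            profile = SubsiteProfile.from_dict({-1: {"D": penalty}})
            vals = []
            for seed in range(12):
                config = SimulationConfig(
                    direction="N-acetylate", seed=seed, target_fa=0.3
                )
                traj = simulate_polymer(PaSequence("D" * 1000), profile, config)
                _, stats = digest_and_score(traj.final)
                vals.append(stats.blockA_w)
            means.append(np.mean(vals))
        assert means[0] <= means[1] + 0.05
        assert means[1] <= means[2] + 0.05
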