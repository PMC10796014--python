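"""Stochastic subsite-preference model of chitin deacetylase (CDA) action.

A CDA binds an A/D chain across a groove of six subsites, −3…+2, with the
unit to be (de)acetylated held at subsite 0.  Each placement of the catalytic
subsite over an eligible unit (A for deacetylation, D for N-acetylation) is a
*binding frame*.  A frame's energy is the sum of per-subsite terms: eA or eD
for the residue actually held at that subsite, or eEmpty when the subsite
extends past a chain end (occupancy term).  Catalytic events are memoryless
Boltzmann choices over frames, P(frame) ∝ exp(−E) with energies in kT
(β = 1; only energy differences matter).

There is no explicit time axis and no processivity: trajectories are indexed
by event count and checkpointed by the fraction of acetylation F_A, which is
how enzymatically produced chitosans are characterised.

Bundled presets encode qualitative subsite preferences of the engineered
enzyme variants: ``nm`` (nonmutated: strong GlcNAc preference at −2, moderate
at −1), ``H199K`` (stronger −1 GlcNAc preference, yielding the blockiest
products), ``H199Y`` (GlcN tolerated or slightly preferred at −1, yielding
near-alternating products), and ``neutral`` (all-zero reference).  The
presets' only contract is the direction of the product shifts they induce;
no quantitative binding energies are claimed.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import (
    ChitosimValidationError,
    EnumerationTooLargeError,
    StalledReactionError,
)
from .core import DEACETYLATE, N_ACETYLATE, PaSequence, apply_modification

__all__ = [
    "SUBSITE_RANGE",
    "SubsiteProfile",
    "BindingFrame",
    "SimulationConfig",
    "Trajectory",
    "TrajectoryEvent",
    "PRESETS",
    "enumerate_frames",
    "frame_energy",
    "step",
    "product_distribution",
    "simulate_polymer",
]

SUBSITE_RANGE = tuple(range(-3, 3))  # subsites −3 … +2

_STATE_A, _STATE_D, _STATE_EMPTY = 0, 1, 2


def _parse_energy(value) -> float:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("inf", "+inf", "infinity"):
            return math.inf
        return float(value)
    return float(value)


@dataclass(frozen=True)
class SubsiteProfile:
    """Per-subsite energies (kT) for A, D and uncovered (empty) states.

    ``energies`` maps each subsite in −3…+2 to an (eA, eD, eEmpty) triple.
    Values are finite or +inf (hard exclusion); NaN is rejected.
    """

    energies: dict[int, tuple[float, float, float]]
    name: str = ""

    def __post_init__(self) -> None:
        for s in SUBSITE_RANGE:
            if s not in self.energies:
                raise ChitosimValidationError(f"profile missing subsite {s}")
        for s, triple in self.energies.items():
            if s not in SUBSITE_RANGE:
                raise ChitosimValidationError(f"subsite {s} outside range [-3,+2]")
            if len(triple) != 3 or any(math.isnan(e) for e in triple):
                raise ChitosimValidationError(f"bad energies at subsite {s}: {triple}")

    @classmethod
    def from_dict(cls, mapping: dict, name: str = "") -> "SubsiteProfile":
        """Build from ``{subsite: {"A": e, "D": e, "empty": e}}``.

        Unspecified subsites and states default to 0; ``"inf"`` is accepted.
        """
        energies = {}
        for s in SUBSITE_RANGE:
            entry = mapping.get(s, mapping.get(str(s), {}))
            energies[s] = (
                _parse_energy(entry.get("A", 0.0)),
                _parse_energy(entry.get("D", 0.0)),
                _parse_energy(entry.get("empty", 0.0)),
            )
        return cls(energies=energies, name=name)

    @classmethod
    def from_file(cls, path) -> "SubsiteProfile":
        """Load a profile from a JSON or YAML file mapping subsite → states."""
        text = open(path).read()
        try:
            mapping = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            mapping = yaml.safe_load(text)
        return cls.from_dict(mapping, name=str(path))

    def as_array(self) -> np.ndarray:
        """(6, 3) array: rows are subsites −3…+2, columns A/D/empty."""
        out = np.empty((len(SUBSITE_RANGE), 3))
        for i, s in enumerate(SUBSITE_RANGE):
            out[i] = self.energies[s]
        return out

    def to_dict(self) -> dict:
        return {
            s: {"A": eA, "D": eD, "empty": eE}
            for s, (eA, eD, eE) in sorted(self.energies.items())
        }


def _preset(name: str, spec: dict) -> SubsiteProfile:
    return SubsiteProfile.from_dict(spec, name=name)


#: Qualitative subsite-preference presets (negative = favourable, kT).
PRESETS: dict[str, SubsiteProfile] = {
    "neutral": _preset("neutral", {}),
    "nm": _preset("nm", {-2: {"A": -4.0}, -1: {"A": -2.0}, 1: {"empty": 1.0}}),
    "H199K": _preset("H199K", {-2: {"A": -4.0}, -1: {"A": -3.0}, 1: {"empty": 1.0}}),
    "H199Y": _preset("H199Y", {-2: {"A": -4.0}, -1: {"D": -1.0}, 1: {"empty": 1.0}}),
}


def _span_label(position: int, dp: int) -> str:
    lo = -(position - 1)
    hi = dp - position
    def fmt(v: int) -> str:
        return f"+{v}" if v > 0 else str(v)
    return f"[{fmt(lo)},{fmt(hi)}]"


@dataclass(frozen=True)
class BindingFrame:
    """Placement of the subsite-0 catalytic site over substrate position p."""

    subsite0_position: int  # 1-based substrate position
    dp: int

    @property
    def span_label(self) -> str:
        return _span_label(self.subsite0_position, self.dp)

    @property
    def covered_subsites(self) -> tuple[int, ...]:
        p = self.subsite0_position
        return tuple(s for s in SUBSITE_RANGE if 1 <= p + s <= self.dp)


def _eligible_code(direction: str) -> str:
    if direction == DEACETYLATE:
        return "A"
    if direction == N_ACETYLATE:
        return "D"
    raise ChitosimValidationError(f"unknown direction {direction!r}")


def enumerate_frames(seq: PaSequence, direction: str) -> list[BindingFrame]:
    """One frame per eligible subsite-0 position; may be empty."""
    code = _eligible_code(direction)
    return [
        BindingFrame(subsite0_position=i, dp=seq.dp)
        for i, ch in enumerate(seq.units, start=1)
        if ch == code
    ]


def frame_energy(seq: PaSequence, frame: BindingFrame, profile: SubsiteProfile) -> float:
    """Total binding energy (kT) of a frame: Σ_s e(s, state at p+s)."""
    p = frame.subsite0_position
    total = 0.0
    for s in SUBSITE_RANGE:
        pos = p + s
        eA, eD, eE = profile.energies[s]
        if 1 <= pos <= seq.dp:
            total += eA if seq.units[pos - 1] == "A" else eD
        else:
            total += eE
    return total


def _frame_weights(energies: np.ndarray) -> np.ndarray:
    """Boltzmann weights exp(−E), shifted for overflow safety; inf → 0."""
    finite = np.isfinite(energies)
    if not finite.any():
        return np.zeros_like(energies)
    shifted = energies - energies[finite].min()
    with np.errstate(over="ignore"):
        w = np.exp(-shifted)
    w[~finite] = 0.0
    return w


# --- vectorised energy evaluation -------------------------------------------


def _encode(units: str) -> np.ndarray:
    raw = np.frombuffer(units.encode("ascii"), dtype=np.uint8)
    return np.where(raw == ord("A"), _STATE_A, _STATE_D).astype(np.int8)


def _pad(arr: np.ndarray) -> np.ndarray:
    padded = np.full(arr.size + 5, _STATE_EMPTY, dtype=np.int8)
    padded[3 : 3 + arr.size] = arr
    return padded


def _energies_at(padded: np.ndarray, positions0: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Frame energies for 0-based positions; ``table`` is profile.as_array()."""
    energy = np.zeros(positions0.size)
    for i, s in enumerate(SUBSITE_RANGE):
        energy += table[i, padded[positions0 + (s + 3)]]
    return energy


def step(
    seq: PaSequence,
    profile: SubsiteProfile,
    direction: str,
    rng: np.random.Generator,
) -> tuple[PaSequence, BindingFrame]:
    """One catalytic event: sample a frame ∝ exp(−E) and modify subsite 0."""
    frames = enumerate_frames(seq, direction)
    if not frames:
        raise StalledReactionError(f"no eligible unit for {direction} in {seq.units}")
    arr = _encode(seq.units)
    padded = _pad(arr)
    positions0 = np.array([f.subsite0_position - 1 for f in frames])
    energies = _energies_at(padded, positions0, profile.as_array())
    weights = _frame_weights(energies)
    total = weights.sum()
    if total <= 0.0:
        raise StalledReactionError("all binding frames have infinite energy")
    idx = rng.choice(len(frames), p=weights / total)
    chosen = frames[idx]
    return apply_modification(seq, chosen.subsite0_position, direction), chosen


def product_distribution(
    seq: PaSequence,
    profile: SubsiteProfile,
    direction: str,
    n_events: int,
    max_states: int = 50_000,
) -> dict[str, float]:
    """Exact product distribution after ``n_events`` catalytic events.

    Recursively enumerates every frame choice, weighting branches by their
    Boltzmann probabilities.  Sequences that stall early (no finite-energy
    frame left) are absorbing.  Intended for oligomers; the state space is
    capped at ``max_states`` distinct intermediate sequences.
    """
    if n_events < 1:
        raise ChitosimValidationError("n_events must be ≥ 1")
    if seq.dp > 12 and n_events > 3:
        raise EnumerationTooLargeError(
            f"exact enumeration of DP {seq.dp} with {n_events} events is too large; "
            "use Monte-Carlo sampling via step()/simulate_polymer()"
        )
    table = profile.as_array()
    acc: dict[str, float] = {}
    seen: set[str] = set()

    def recurse(units: str, events_left: int, prob: float) -> None:
        seen.add(units)
        if len(seen) > max_states:
            raise EnumerationTooLargeError(
                f"enumeration exceeded {max_states} states; use Monte-Carlo sampling"
            )
        if events_left == 0:
            acc[units] = acc.get(units, 0.0) + float(prob)
            return
        s = PaSequence(units)
        frames = enumerate_frames(s, direction)
        if not frames:
            acc[units] = acc.get(units, 0.0) + prob
            return
        padded = _pad(_encode(units))
        positions0 = np.array([f.subsite0_position - 1 for f in frames])
        weights = _frame_weights(_energies_at(padded, positions0, table))
        total = weights.sum()
        if total <= 0.0:
            acc[units] = acc.get(units, 0.0) + prob
            return
        for f, w in zip(frames, weights):
            if w <= 0.0:
                continue
            child = apply_modification(s, f.subsite0_position, direction)
            recurse(child.units, events_left - 1, float(prob * w / total))

    recurse(seq.units, n_events, 1.0)
    return acc


@dataclass(frozen=True)
class SimulationConfig:
    """Stop criterion, checkpoints and seed for a polymer trajectory.

    Exactly one of ``target_fa`` or ``max_events`` must be set.  Checkpoints
    are F_A values snapshotted the first time the trajectory crosses them;
    they must be monotone in the direction of the reaction.
    """

    direction: str
    seed: int
    target_fa: float | None = None
    max_events: int | None = None
    checkpoints: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.target_fa is None) == (self.max_events is None):
            raise ChitosimValidationError(
                "set exactly one of target_fa or max_events"
            )
        if self.target_fa is not None and not 0.0 <= self.target_fa <= 1.0:
            raise ChitosimValidationError("target_fa must lie in [0, 1]")
        cps = list(self.checkpoints)
        increasing = self.direction == N_ACETYLATE
        if cps != sorted(cps, reverse=not increasing):
            raise ChitosimValidationError(
                "checkpoints must be monotone in the reaction direction"
            )


@dataclass(frozen=True)
class TrajectoryEvent:
    index: int
    position: int  # 1-based unit modified
    span_label: str
    fa: float  # F_A after the event


@dataclass
class Trajectory:
    """Event log plus F_A-indexed snapshots of one seeded simulation."""

    initial: PaSequence
    events: list[TrajectoryEvent]
    snapshots: dict[float, PaSequence]
    final: PaSequence
    stalled: bool
    config: SimulationConfig

    @property
    def n_events(self) -> int:
        return len(self.events)


def simulate_polymer(
    seq: PaSequence, profile: SubsiteProfile, config: SimulationConfig
) -> Trajectory:
    """Run repeated catalytic events on a polymer until the stop criterion.

    Identical (sequence, profile, config) including the seed yield an
    identical trajectory.  If the reaction stalls before the stop criterion
    is met, the partial trajectory is returned with ``stalled=True``.
    """
    direction = config.direction
    code = _eligible_code(direction)
    dp = seq.dp
    if config.target_fa is not None:
        if direction == N_ACETYLATE and seq.fa >= config.target_fa:
            raise ChitosimValidationError("target_fa must exceed the starting F_A")
        if direction == DEACETYLATE and seq.fa <= config.target_fa:
            raise ChitosimValidationError("target_fa must be below the starting F_A")

    rng = np.random.default_rng(config.seed)
    table = profile.as_array()
    arr = _encode(seq.units)
    padded = _pad(arr)
    target_state = _STATE_A if code == "A" else _STATE_D
    new_state = _STATE_D if code == "A" else _STATE_A

    n_a = int((arr == _STATE_A).sum())
    events: list[TrajectoryEvent] = []
    snapshots: dict[float, PaSequence] = {}
    pending = list(config.checkpoints)
    increasing = direction == N_ACETYLATE
    stalled = False

    def maybe_snapshot(fa: float) -> None:
        while pending and (fa >= pending[0] if increasing else fa <= pending[0]):
            cp = pending.pop(0)
            snapshots[cp] = PaSequence(_decode(arr))

    maybe_snapshot(n_a / dp)
    event_index = 0
    while True:
        fa = n_a / dp
        if config.target_fa is not None:
            if increasing and fa >= config.target_fa:
                break
            if not increasing and fa <= config.target_fa:
                break
        if config.max_events is not None and event_index >= config.max_events:
            break
        eligible0 = np.flatnonzero(arr == target_state)
        if eligible0.size == 0:
            stalled = True
            break
        energies = _energies_at(padded, eligible0, table)
        weights = _frame_weights(energies)
        total = weights.sum()
        if total <= 0.0:
            stalled = True
            break
        pos0 = int(rng.choice(eligible0, p=weights / total))
        arr[pos0] = new_state
        padded[pos0 + 3] = new_state
        n_a += 1 if increasing else -1
        event_index += 1
        fa = n_a / dp
        events.append(
            TrajectoryEvent(
                index=event_index,
                position=pos0 + 1,
                span_label=_span_label(pos0 + 1, dp),
                fa=fa,
            )
        )
        maybe_snapshot(fa)

    final = PaSequence(_decode(arr))
    return Trajectory(
        initial=seq,
        events=events,
        snapshots=copy.deepcopy(snapshots),
        final=final,
        stalled=stalled,
        config=config,
    )


def _decode(arr: np.ndarray) -> str:
    raw = np.where(arr == _STATE_A, ord("A"), ord("D")).astype(np.uint8)
    return raw.tobytes().decode("ascii")
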