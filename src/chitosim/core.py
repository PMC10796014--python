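"""Sequence and composition model for partially acetylated chitooligosaccharides.

Chitosan chains are copolymers of N-acetylglucosamine (GlcNAc, written ``A``)
and glucosamine (GlcN, written ``D``).  A chain is written from the
nonreducing to the reducing end, e.g. ``AADA`` for chitotetraose deacetylated
at the third unit.  Two derived quantities characterise a chain: its degree of
polymerization (DP, the number of units) and its fraction of acetylation
(F_A, the proportion of A units).

This module also carries the monoisotopic mass model used for MS work:
residue (dehydro) masses for A and D, water and proton, and the [M+H]+ m/z of
an A_nD_m species.  Only singly protonated adducts are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from ._errors import InfeasibleModificationError, InvalidSequenceError

__all__ = [
    "Residue",
    "PaSequence",
    "Composition",
    "MassConstants",
    "MASSES",
    "parse_sequence",
    "render_sequence",
    "composition_of",
    "mz_mh",
    "apply_modification",
    "DEACETYLATE",
    "N_ACETYLATE",
]

# Reaction directions. A CDA hydrolyses the N-acetyl group of an A unit; run
# in reverse (with excess acetate) it N-acetylates a D unit.
DEACETYLATE = "deacetylate"
N_ACETYLATE = "N-acetylate"

_VALID = frozenset("AD")


class Residue:
    """The two sugar units: ``A`` = GlcNAc, ``D`` = GlcN."""

    A = "A"
    D = "D"

    codes = ("A", "D")


@dataclass(frozen=True)
class PaSequence:
    """An ordered A/D chain, nonreducing end first.

    Attributes
    ----------
    units : str
        Residue string over {A, D}, nonreducing → reducing.
    """

    units: str

    def __post_init__(self) -> None:
        _validate(self.units)

    @property
    def dp(self) -> int:
        """Degree of polymerization (number of sugar units)."""
        return len(self.units)

    @property
    def fa(self) -> float:
        """Fraction of acetylation: (#A)/DP, in [0, 1]."""
        return self.units.count("A") / len(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, position: int) -> str:
        """1-based access to residue codes (matching field convention)."""
        if not 1 <= position <= len(self.units):
            raise IndexError(
                f"position {position} out of range for DP {len(self.units)}"
            )
        return self.units[position - 1]

    def __str__(self) -> str:
        return self.units


class Composition(NamedTuple):
    """Number of A and D units of a species, e.g. A3D1 = (nA=3, nD=1)."""

    nA: int
    nD: int

    @property
    def dp(self) -> int:
        return self.nA + self.nD

    @property
    def label(self) -> str:
        return f"A{self.nA}D{self.nD}"

    @classmethod
    def from_label(cls, label: str) -> "Composition":
        """Parse labels like ``A3D1``, ``A4`` or ``D4``."""
        import re

        m = re.fullmatch(r"A(\d+)D(\d+)|A(\d+)|D(\d+)", label.strip().upper())
        if m is None:
            raise InvalidSequenceError(f"not a composition label: {label!r}")
        if m.group(1) is not None:
            return cls(int(m.group(1)), int(m.group(2)))
        if m.group(3) is not None:
            return cls(int(m.group(3)), 0)
        return cls(0, int(m.group(4)))


def _validate(text: str) -> None:
    if not text:
        raise InvalidSequenceError("empty sequence", position=None)
    for i, ch in enumerate(text, start=1):
        if ch not in _VALID:
            raise InvalidSequenceError(
                f"invalid residue {ch!r} at position {i} (expected A or D)",
                position=i,
            )


def parse_sequence(text: str) -> PaSequence:
    """Parse a residue string (case-insensitive) into a :class:`PaSequence`.

    Raises
    ------
    InvalidSequenceError
        If the string is empty or contains a character other than A/D; the
        error carries the 1-based offending position.
    """
    return PaSequence(text.strip().upper())


def render_sequence(seq: PaSequence) -> str:
    """Inverse of :func:`parse_sequence`; always uppercase."""
    return seq.units


def composition_of(seq: PaSequence | str) -> Composition:
    units = seq.units if isinstance(seq, PaSequence) else parse_sequence(seq).units
    nA = units.count("A")
    return Composition(nA=nA, nD=len(units) - nA)


# --- monoisotopic masses ---------------------------------------------------

_H = 1.0078250319
_C = 12.0
_N = 14.0030740
_O = 15.9949146


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic masses (Da) for A_nD_m species.

    residue masses are dehydro (in-chain) masses: GlcNAc residue C8H13NO5,
    GlcN residue C6H11NO4.  Their difference is the acetyl delta C2H2O
    (≈42.0106 Da).
    """

    residue_mass_A: float = 8 * _C + 13 * _H + _N + 5 * _O
    residue_mass_D: float = 6 * _C + 11 * _H + _N + 4 * _O
    water: float = 2 * _H + _O
    proton: float = 1.00727646688

    @property
    def acetyl_delta(self) -> float:
        return self.residue_mass_A - self.residue_mass_D


MASSES = MassConstants()


def mz_mh(comp: Composition | str, masses: MassConstants = MASSES) -> float:
    """m/z of the singly protonated species [M+H]+ of composition A_nD_m.

    >>> round(mz_mh(Composition(3, 1)), 3)
    789.325
    """
    if isinstance(comp, str):
        comp = Composition.from_label(comp)
    if comp.nA < 0 or comp.nD < 0 or comp.nA + comp.nD < 1:
        raise InvalidSequenceError(f"invalid composition {comp}")
    return (
        comp.nA * masses.residue_mass_A
        + comp.nD * masses.residue_mass_D
        + masses.water
        + masses.proton
    )


def apply_modification(seq: PaSequence, position: int, direction: str) -> PaSequence:
    """Return ``seq`` with the unit at 1-based ``position`` (de)acetylated.

    ``deacetylate`` turns an A into a D; ``N-acetylate`` turns a D into an A.
    DP is conserved and F_A changes by exactly ±1/DP.
    """
    if not 1 <= position <= seq.dp:
        raise IndexError(f"position {position} out of range for DP {seq.dp}")
    current = seq.units[position - 1]
    if direction == DEACETYLATE:
        if current != "A":
            raise InfeasibleModificationError(
                f"cannot deacetylate {current} at position {position}: not GlcNAc"
            )
        new = "D"
    elif direction == N_ACETYLATE:
        if current != "D":
            raise InfeasibleModificationError(
                f"cannot N-acetylate {current} at position {position}: not GlcN"
            )
        new = "A"
    else:
        raise InvalidSequenceError(f"unknown direction {direction!r}")
    return PaSequence(seq.units[: position - 1] + new + seq.units[position:])


# --- sequence file I/O -----------------------------------------------------


def read_sequences(path) -> list[PaSequence]:
    """Read sequences from a FASTA-like or one-per-line text file.

    Lines starting with ``>`` start a new record; otherwise each nonempty
    line is one sequence.
    """
    seqs: list[PaSequence] = []
    fasta_chunks: list[str] = []
    in_fasta = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if fasta_chunks:
                    seqs.append(parse_sequence("".join(fasta_chunks)))
                    fasta_chunks = []
                in_fasta = True
            elif in_fasta:
                fasta_chunks.append(line)
            else:
                seqs.append(parse_sequence(line))
    if fasta_chunks:
        seqs.append(parse_sequence("".join(fasta_chunks)))
    if not seqs:
        raise InvalidSequenceError(f"no sequences found in {path}")
    return seqs


def write_sequences(path, seqs: Iterable[PaSequence], names: Iterable[str] | None = None,
                    width: int = 80) -> None:
    """Write sequences in FASTA-like format, uppercase, wrapped at ``width``."""
    seqs = list(seqs)
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(seqs))]
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f">{name}\n")
            s = seq.units
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
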