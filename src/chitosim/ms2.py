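"""B/Y fragment-ion ladders and acetylation-pattern deconvolution.

In glycan MS², glycosidic-bond cleavage of a [M+H]+ precursor yields
nonreducing-end oxocarbenium (B) ions and reducing-end-retaining (Y) ions:

    B_i = Σ residue masses of the first i units + proton
    Y_j = Σ residue masses of the last j units + water + proton

so B_i and Y_(dp−i) are complementary: B_i + Y_(dp−i) = [M+H]+ + proton.
Sequence isomers share every m/z, so the observable is the ion *species*
(ion type, length, composition), not a specific pattern.  A mixture of
acetylation patterns is recovered from observed ion-species intensities by
nonnegative least squares onto the candidates' 0/1 incidence profiles,
assuming equal response for every B/Y ion of a pattern (only intensity
shares enter the fit).  Fractions are renormalized to sum to one and the
residual norm is reported as a fit diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.optimize

from ._errors import (
    AmbiguousPatternsWarning,
    ChitosimValidationError,
    NoSignalError,
)
from .core import MASSES, Composition, PaSequence, composition_of, parse_sequence

__all__ = [
    "FragmentIon",
    "IonSpecies",
    "PatternDistribution",
    "theoretical_ions",
    "candidate_patterns",
    "incidence_matrix",
    "deconvolute",
    "read_ion_table",
]

#: Observable ion species: sequence isomers collapse onto (type, length, nA).
IonSpecies = tuple[str, int, int]


@dataclass(frozen=True)
class FragmentIon:
    ion_type: str  # "B" or "Y"
    length: int  # number of sugar units retained
    composition: Composition
    mz: float

    @property
    def species(self) -> IonSpecies:
        return (self.ion_type, self.length, self.composition.nA)


def theoretical_ions(pattern: PaSequence | str) -> list[FragmentIon]:
    """All B_i and Y_j ions, i, j in 1..dp−1 (2·(dp−1) ions)."""
    if isinstance(pattern, str):
        pattern = parse_sequence(pattern)
    if pattern.dp < 2:
        raise ChitosimValidationError("fragmentation requires DP ≥ 2")
    ions: list[FragmentIon] = []
    units = pattern.units
    for i in range(1, pattern.dp):
        b_comp = composition_of(parse_sequence(units[:i]))
        b_mz = (
            b_comp.nA * MASSES.residue_mass_A
            + b_comp.nD * MASSES.residue_mass_D
            + MASSES.proton
        )
        ions.append(FragmentIon("B", i, b_comp, b_mz))
        y_comp = composition_of(parse_sequence(units[-i:]))
        y_mz = (
            y_comp.nA * MASSES.residue_mass_A
            + y_comp.nD * MASSES.residue_mass_D
            + MASSES.water
            + MASSES.proton
        )
        ions.append(FragmentIon("Y", i, y_comp, y_mz))
    return ions


def candidate_patterns(comp: Composition | str) -> list[str]:
    """All distinct A/D arrangements of a composition, lexicographic order."""
    if isinstance(comp, str):
        comp = Composition.from_label(comp)
    return sorted({"".join(p) for p in permutations("A" * comp.nA + "D" * comp.nD)})


def incidence_matrix(
    candidates: list[str],
) -> tuple[list[IonSpecies], np.ndarray]:
    """0/1 matrix of observable ion species (rows) × candidate patterns (cols)."""
    if not candidates:
        raise ChitosimValidationError("no candidate patterns")
    comps = {composition_of(parse_sequence(c)) for c in candidates}
    if len(comps) != 1:
        raise ChitosimValidationError(
            f"candidates mix compositions: {sorted(c.label for c in comps)}"
        )
    species_sets = [
        {ion.species for ion in theoretical_ions(c)} for c in candidates
    ]
    all_species = sorted(set().union(*species_sets))
    matrix = np.zeros((len(all_species), len(candidates)))
    for j, produced in enumerate(species_sets):
        for i, sp in enumerate(all_species):
            if sp in produced:
                matrix[i, j] = 1.0
    return all_species, matrix


@dataclass
class PatternDistribution:
    """Nonnegative, sum-to-one fractions over candidate acetylation patterns."""

    fractions: dict[str, float]
    residual: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions.values()):
            raise ChitosimValidationError("pattern fractions must be nonnegative")
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ChitosimValidationError(f"fractions sum to {total}, expected 1")

    def get(self, pattern: str) -> float:
        return self.fractions.get(pattern.upper(), 0.0)


_RIDGE = 1e-9


def deconvolute(
    observed: dict[IonSpecies, float],
    candidates: list[str],
) -> PatternDistribution:
    """Recover a pattern mixture from observed ion-species intensities.

    Intensity shares are fitted by NNLS onto the candidates' incidence
    profiles (columns normalized to their ion counts).  Ion species with
    identical incidence across all candidates are uninformative and dropped
    before fitting.  Rank deficiency (indistinguishable candidates) triggers
    an :class:`AmbiguousPatternsWarning` naming the tied classes; the ridge
    term then shares mass evenly within a tied class rather than breaking
    the tie silently.
    """
    if not observed:
        raise ChitosimValidationError("no observed ion intensities")
    candidates = [parse_sequence(c).units for c in candidates]
    species, matrix = incidence_matrix(candidates)
    b = np.array([float(observed.get(sp, 0.0)) for sp in species])
    if b.sum() <= 0.0:
        raise NoSignalError("all observed ion intensities are zero")

    # share model: each pattern distributes its signal evenly over its ions
    col_counts = matrix.sum(axis=0)
    design = matrix / col_counts
    b = b / b.sum()

    if len(candidates) > 1:
        informative = ~np.all(matrix == matrix[:, [0]], axis=1)
        if informative.any():
            design = design[informative]
            b_fit = b[informative]
        else:
            b_fit = b
    else:
        b_fit = b

    rank = np.linalg.matrix_rank(matrix)
    if rank < len(candidates):
        classes: dict[bytes, list[str]] = {}
        for j, cand in enumerate(candidates):
            classes.setdefault(matrix[:, j].tobytes(), []).append(cand)
        tied = [grp for grp in classes.values() if len(grp) > 1]
        if tied:
            msg = f"indistinguishable candidate patterns: {tied}"
        else:
            msg = (
                "ion incidence matrix is rank-deficient; some mixtures of these "
                "candidates are ambiguous (nonnegativity may still identify the fit)"
            )
        warnings.warn(msg, AmbiguousPatternsWarning, stacklevel=2)

    n = len(candidates)
    design_r = np.vstack([design, np.sqrt(_RIDGE) * np.eye(n)])
    b_r = np.concatenate([b_fit, np.zeros(n)])
    x, _ = scipy.optimize.nnls(design_r, b_r)
    if x.sum() <= 0.0:
        raise NoSignalError("deconvolution yielded an all-zero solution")
    fractions = x / x.sum()
    residual = float(np.linalg.norm(design @ x - b_fit))
    return PatternDistribution(
        fractions={c: float(f) for c, f in zip(candidates, fractions)},
        residual=residual,
    )


def read_ion_table(path) -> dict[IonSpecies, float]:
    """Read observed ions from CSV with header ion_type,length,nA,nD,intensity."""
    df = pd.read_csv(path)
    needed = {"ion_type", "length", "nA", "intensity"}
    if not needed.issubset(df.columns):
        raise ChitosimValidationError(
            "ion table needs columns ion_type,length,nA,nD,intensity"
        )
    out: dict[IonSpecies, float] = {}
    for r in df.itertuples():
        key = (str(r.ion_type).upper(), int(r.length), int(r.nA))
        out[key] = out.get(key, 0.0) + float(r.intensity)
    return out
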