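"""MS¹ species quantification of partially acetylated chitooligosaccharides.

Peak lists (m/z, intensity) are matched to [M+H]+ targets of A_nD_m species
within an absolute m/z tolerance, and relative amounts are computed under an
equal-ionization-response assumption (all species of equal DP respond alike;
relative amounts are normalized over matched intensity including residual
substrate).  From the relative amounts of a deacetylation assay the relative
acetate release is

    rar = Σ_species k · ra(species),   k = nD(species) − nD(substrate),

the mean number of acetate groups released per substrate molecule.  For an A4
substrate this reduces to rar = raA3D1 + 2·raA2D2 (+ 3·raA1D3 + 4·raD4), and
for an A3D1 substrate to rar = raA2D2 + 2·raA1D3 + 3·raD4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import (
    ChitosimValidationError,
    InconsistentSpeciesError,
    NormalizationError,
    NoSignalError,
    WindowOverlapError,
)
from .core import Composition, mz_mh

__all__ = [
    "Peak",
    "SpeciesTarget",
    "RelativeAmounts",
    "targets_for_substrate",
    "quantify",
    "relative_acetate_release",
    "normalize_to_reference",
    "read_peaklist",
]

DEFAULT_TOLERANCE = 0.02  # Da; singly charged small glycans


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ChitosimValidationError(f"nonpositive m/z {self.mz}")
        if self.intensity < 0:
            raise ChitosimValidationError(f"negative intensity {self.intensity}")


@dataclass(frozen=True)
class SpeciesTarget:
    """An A_nD_m species with its [M+H]+ target m/z and matching tolerance."""

    composition: Composition
    target_mz: float
    tolerance: float = DEFAULT_TOLERANCE

    @classmethod
    def for_composition(
        cls, comp: Composition | str, tolerance: float = DEFAULT_TOLERANCE
    ) -> "SpeciesTarget":
        if isinstance(comp, str):
            comp = Composition.from_label(comp)
        return cls(composition=comp, target_mz=mz_mh(comp), tolerance=tolerance)


def targets_for_substrate(
    substrate: Composition | str, tolerance: float = DEFAULT_TOLERANCE
) -> list[SpeciesTarget]:
    """Targets for a substrate and all of its (partial) deacetylation products."""
    if isinstance(substrate, str):
        substrate = Composition.from_label(substrate)
    return [
        SpeciesTarget.for_composition(
            Composition(substrate.nA - k, substrate.nD + k), tolerance
        )
        for k in range(substrate.nA + 1)
    ]


@dataclass
class RelativeAmounts:
    """Normalized species abundances; fractions sum to 1 over matched species."""

    substrate: Composition
    amounts: dict[Composition, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp, ra in self.amounts.items():
            if ra < 0:
                raise ChitosimValidationError(f"negative relative amount for {comp.label}")
        total = sum(self.amounts.values())
        if self.amounts and abs(total - 1.0) > 1e-9:
            raise ChitosimValidationError(
                f"relative amounts sum to {total}, expected 1"
            )

    def get(self, comp: Composition | str) -> float:
        if isinstance(comp, str):
            comp = Composition.from_label(comp)
        return self.amounts.get(comp, 0.0)


def quantify(
    peaks: list[Peak] | pd.DataFrame, targets: list[SpeciesTarget],
    substrate: Composition | str | None = None,
) -> RelativeAmounts:
    """Assign peak intensities to species windows and normalize.

    Each species' intensity is the sum of peak intensities within ±tolerance
    of its target m/z; relative amounts divide by the total matched intensity.
    Windows must not overlap (targets pairwise separated by more than twice
    the larger tolerance).
    """
    if isinstance(peaks, pd.DataFrame):
        peaks = [Peak(float(r.mz), float(r.intensity)) for r in peaks.itertuples()]
    if not targets:
        raise ChitosimValidationError("no species targets given")
    for i, a in enumerate(targets):
        for b in targets[i + 1 :]:
            if abs(a.target_mz - b.target_mz) <= a.tolerance + b.tolerance:
                raise WindowOverlapError(
                    f"windows of {a.composition.label} and {b.composition.label} overlap"
                )
    mz = np.array([p.mz for p in peaks])
    inten = np.array([p.intensity for p in peaks])
    raw: dict[Composition, float] = {}
    for t in targets:
        matched = np.abs(mz - t.target_mz) <= t.tolerance
        raw[t.composition] = float(inten[matched].sum())
    total = sum(raw.values())
    if total <= 0.0:
        raise NoSignalError("no peak intensity within any target window")
    if substrate is None:
        substrate = max(raw, key=lambda c: c.nA)
    elif isinstance(substrate, str):
        substrate = Composition.from_label(substrate)
    return RelativeAmounts(
        substrate=substrate, amounts={c: v / total for c, v in raw.items()}
    )


def relative_acetate_release(ra: RelativeAmounts) -> float:
    """Mean acetates released per substrate molecule: Σ k·ra, k = ΔnD ≥ 1."""
    sub = ra.substrate
    rar = 0.0
    for comp, fraction in ra.amounts.items():
        k = comp.nD - sub.nD
        if k < 0 and fraction > 0:
            raise InconsistentSpeciesError(
                f"species {comp.label} is more acetylated than substrate {sub.label}"
            )
        if k >= 1:
            rar += k * fraction
    return rar


def normalize_to_reference(
    values: dict[str, float], reference_ids: list[str]
) -> dict[str, float]:
    """Divide every value by the mean over reference ids (references → 1.0 mean)."""
    refs = [
        values[r]
        for r in reference_ids
        if r in values and np.isfinite(values[r])
    ]
    if not refs:
        raise NormalizationError("no finite reference value present")
    mean_ref = float(np.mean(refs))
    if mean_ref <= 0.0:
        raise NormalizationError(f"mean reference value {mean_ref} is not positive")
    return {k: v / mean_ref for k, v in values.items()}


def read_peaklist(path) -> list[Peak]:
    """Read a CSV peak list with header ``mz,intensity``."""
    df = pd.read_csv(path)
    if not {"mz", "intensity"}.issubset(df.columns):
        raise ChitosimValidationError("peak list needs columns mz,intensity")
    return [Peak(float(r.mz), float(r.intensity)) for r in df.itertuples()]
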