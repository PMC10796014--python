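"""Site-saturation mutagenesis (SSM) plate-screen analytics.

A complete SSM library substitutes each chosen position of the wild-type
protein with all 19 non-wild-type amino acids.  Activity is read out with a
fluorescamine assay for free primary amines: a glucosamine standard series
(0, 75, 150, 250 µM) fixes a linear standard curve per plate, well
fluorescences are converted to amine concentrations, each mutein is
normalized to the mean of the nonmutated-control wells on its own plate, and
replicate values are summarized with a guarded outlier rule: if the sample
standard deviation exceeds 0.2 the value furthest from the mean is removed,
and the removal is withdrawn unless it lowers the SD by more than 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._errors import (
    ChitosimValidationError,
    DegenerateFitError,
    InsufficientDataError,
    NormalizationError,
)

__all__ = [
    "AMINO_ACIDS",
    "STANDARD_CONCENTRATIONS",
    "SsmLibrary",
    "StandardCurve",
    "WellRecord",
    "ActivityResult",
    "enumerate_ssm",
    "fit_standard",
    "amine_concentration",
    "normalize_plate",
    "robust_mean",
    "read_plate_csv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard residues

#: Glucosamine standard series (µM) used to calibrate fluorescence.
STANDARD_CONCENTRATIONS = (0.0, 75.0, 150.0, 250.0)

SD_THRESHOLD = 0.2
SD_IMPROVEMENT = 0.2


@dataclass(frozen=True)
class SsmLibrary:
    """Enumerated single-substitution variants at chosen positions."""

    wt_sequence: str
    positions: tuple[int, ...]  # 1-based
    variants: tuple[tuple[int, str], ...]  # (position, substituted residue)

    def variant_ids(self) -> list[str]:
        """Conventional mutein names, e.g. ``H199Y``."""
        return [
            f"{self.wt_sequence[pos - 1]}{pos}{res}" for pos, res in self.variants
        ]

    def __len__(self) -> int:
        return len(self.variants)


def enumerate_ssm(
    wt_sequence: str, positions: list[int] | dict[int, str]
) -> SsmLibrary:
    """All 19 non-wild-type substitutions at each position.

    ``positions`` may be a list of 1-based indices, or a mapping
    ``{index: declared_wt_residue}`` which is checked against the sequence.
    Variant order is deterministic: by position, then alphabetical residue.
    """
    wt_sequence = wt_sequence.strip().upper()
    declared = (
        positions if isinstance(positions, dict) else {p: None for p in positions}
    )
    variants: list[tuple[int, str]] = []
    for pos in sorted(declared):
        if not 1 <= pos <= len(wt_sequence):
            raise ChitosimValidationError(
                f"position {pos} outside sequence of length {len(wt_sequence)}"
            )
        wt_res = wt_sequence[pos - 1]
        want = declared[pos]
        if want is not None and want.upper() != wt_res:
            raise ChitosimValidationError(
                f"declared wild-type {want} at position {pos}, sequence has {wt_res}"
            )
        variants.extend((pos, aa) for aa in AMINO_ACIDS if aa != wt_res)
    return SsmLibrary(
        wt_sequence=wt_sequence,
        positions=tuple(sorted(declared)),
        variants=tuple(variants),
    )


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # fluorescence units per µM
    intercept: float  # fluorescence at 0 µM
    r_squared: float


def fit_standard(standards: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares line through (concentration µM, fluorescence)."""
    if len(standards) < 2:
        raise DegenerateFitError("need at least 2 standard points")
    conc = np.array([c for c, _ in standards], dtype=float)
    fluo = np.array([f for _, f in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise DegenerateFitError("all standard concentrations identical")
    fit = scipy.stats.linregress(conc, fluo)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def amine_concentration(
    fluorescence: float, curve: StandardCurve
) -> tuple[float, bool]:
    """Invert the standard curve; negatives clamp to 0 with a flag."""
    if curve.slope == 0:
        raise DegenerateFitError("standard curve has zero slope")
    raw = (fluorescence - curve.intercept) / curve.slope
    if raw < 0:
        return 0.0, True
    return raw, False


@dataclass(frozen=True)
class WellRecord:
    plate: str
    well: str
    role: str  # standard | control | mutein | empty
    payload: str  # concentration for standards, mutein id otherwise
    fluorescence: float

    def __post_init__(self) -> None:
        if self.role not in ("standard", "control", "mutein", "empty"):
            raise ChitosimValidationError(f"unknown well role {self.role!r}")
        if self.role == "standard":
            try:
                float(self.payload)
            except (TypeError, ValueError):
                raise ChitosimValidationError(
                    f"standard well {self.well} lacks a concentration payload"
                ) from None


def normalize_plate(records: list[WellRecord]) -> dict[str, list[float]]:
    """Per-plate normalization of mutein amine concentrations to controls.

    Fits the plate's own standard curve, converts every control/mutein well
    to µM, and divides mutein concentrations by the mean control
    concentration of the same plate (controls average to 1).
    """
    plates = {r.plate for r in records}
    if len(plates) != 1:
        raise ChitosimValidationError("normalize_plate expects wells of one plate")
    standards = [
        (float(r.payload), r.fluorescence) for r in records if r.role == "standard"
    ]
    curve = fit_standard(standards)
    controls = [
        amine_concentration(r.fluorescence, curve)[0]
        for r in records
        if r.role == "control"
    ]
    if not controls:
        raise NormalizationError("plate has no control wells")
    mean_control = float(np.mean(controls))
    if mean_control <= 0.0:
        raise NormalizationError(
            f"mean control amine concentration {mean_control} is not positive"
        )
    out: dict[str, list[float]] = {}
    for r in records:
        if r.role != "mutein":
            continue
        conc, _ = amine_concentration(r.fluorescence, curve)
        out.setdefault(r.payload, []).append(conc / mean_control)
    return out


@dataclass(frozen=True)
class ActivityResult:
    mutein: str
    mean: float
    sd: float
    n_total: int
    n_used: int
    outlier_removed: bool


def robust_mean(mutein: str, replicates: list[float]) -> ActivityResult:
    """Summarize replicates with the guarded single-outlier elimination.

    Sample (n−1) SD throughout.  If SD > 0.2, the value furthest from the
    mean is removed (ties broken toward the larger value); the removal is
    withdrawn unless it lowers the SD by more than 20%.  At most one value
    is ever removed, and the rule is disabled below 3 replicates.
    """
    values = np.asarray([v for v in replicates if np.isfinite(v)], dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"{mutein}: need ≥2 finite replicates, got {values.size}"
        )
    n_total = values.size
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if n_total < 3 or sd <= SD_THRESHOLD:
        return ActivityResult(mutein, mean, sd, n_total, n_total, False)
    dev = np.abs(values - mean)
    # furthest from the mean; on a tie remove the larger value
    furthest = max(range(n_total), key=lambda i: (dev[i], values[i]))
    kept = np.delete(values, furthest)
    sd_after = float(kept.std(ddof=1))
    if sd > 0 and (sd - sd_after) / sd > SD_IMPROVEMENT:
        return ActivityResult(
            mutein, float(kept.mean()), sd_after, n_total, n_total - 1, True
        )
    return ActivityResult(mutein, mean, sd, n_total, n_total, False)


def read_plate_csv(path) -> list[WellRecord]:
    """Read well records from CSV with header plate,well,role,payload,fluorescence."""
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "payload": str})
    needed = {"plate", "well", "role", "payload", "fluorescence"}
    if not needed.issubset(df.columns):
        raise ChitosimValidationError(f"plate CSV needs columns {sorted(needed)}")
    return [
        WellRecord(
            plate=str(r.plate),
            well=str(r.well),
            role=str(r.role),
            payload=str(r.payload),
            fluorescence=float(r.fluorescence),
        )
        for r in df.itertuples()
    ]
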