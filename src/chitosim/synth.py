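"""Seeded generators for every input the pipeline consumes.

Each generator emulates one experimental data stream with known ground truth:

- chitosan chains with random (Bernoulli), blocky or alternating patterns of
  acetylation — the chemical-control and idealized enzymatic patterns;
- MS¹ peak lists for mixtures of A_nD_m species, with Gaussian m/z jitter and
  multiplicative intensity noise;
- MS² B/Y ion-species intensity tables generated from a known mixture of
  acetylation patterns (multiplicative noise);
- 96-well plate fluorescence tables with a glucosamine standard series,
  nonmutated-control wells, mutein wells at planted activities, additive
  concentration noise and optionally planted outlier wells.

All generators are deterministic under their seed.  Real data differ in ways
these generators deliberately omit: ionization response factors, isotope
envelopes, chromatographic carry-over, plate edge effects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ChitosimValidationError
from .core import Composition, PaSequence, mz_mh
from .ms1 import Peak
from .ms2 import IonSpecies, theoretical_ions
from .screen import STANDARD_CONCENTRATIONS, WellRecord

__all__ = [
    "random_polymer",
    "patterned_polymer",
    "synth_peaklist",
    "synth_ms2",
    "synth_plate",
    "make_synthetic",
]

# Fluorescamine response model used for synthetic plates (fluorescence units).
PLATE_SLOPE = 2.0  # per µM
PLATE_INTERCEPT = 100.0


def random_polymer(dp: int, fa: float, seed: int) -> PaSequence:
    """i.i.d. Bernoulli chain: each unit is A with probability ``fa``."""
    if dp < 1:
        raise ChitosimValidationError("dp must be ≥ 1")
    if not 0.0 <= fa <= 1.0:
        raise ChitosimValidationError("fa must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(dp) < fa
    return PaSequence("".join("A" if d else "D" for d in draws))


def patterned_polymer(
    dp: int, kind: str = "alternating", a_len: int = 1, d_len: int = 1
) -> PaSequence:
    """Deterministic repetition of a motif, truncated to ``dp`` units.

    ``alternating`` repeats "AD"; ``blocky`` repeats ``a_len`` A's followed
    by ``d_len`` D's.
    """
    if dp < 1:
        raise ChitosimValidationError("dp must be ≥ 1")
    if kind == "alternating":
        motif = "AD"
    elif kind == "blocky":
        if a_len < 1 or d_len < 1:
            raise ChitosimValidationError("block lengths must be ≥ 1")
        motif = "A" * a_len + "D" * d_len
    else:
        raise ChitosimValidationError(f"unknown pattern kind {kind!r}")
    reps = dp // len(motif) + 1
    return PaSequence((motif * reps)[:dp])


def synth_peaklist(
    true_ra: dict[Composition | str, float],
    total_intensity: float = 1e6,
    mz_sd: float = 0.0,
    intensity_cv: float = 0.0,
    seed: int = 0,
) -> list[Peak]:
    """One peak per species at its [M+H]+ m/z, with optional jitter and noise.

    Peak m/z ~ target + Normal(0, mz_sd); intensity = total·ra·(1 + N(0, cv))
    clamped at 0.  Species with zero relative amount are omitted.
    """
    ra = {
        (Composition.from_label(c) if isinstance(c, str) else c): float(v)
        for c, v in true_ra.items()
    }
    total_ra = sum(ra.values())
    if abs(total_ra - 1.0) > 1e-9:
        raise ChitosimValidationError(f"true_ra sums to {total_ra}, expected 1")
    if mz_sd < 0 or intensity_cv < 0:
        raise ChitosimValidationError("noise parameters must be ≥ 0")
    rng = np.random.default_rng(seed)
    peaks = []
    for comp, fraction in sorted(ra.items(), key=lambda kv: kv[0].label):
        if fraction <= 0:
            continue
        mz = mz_mh(comp) + rng.normal(0.0, mz_sd) if mz_sd > 0 else mz_mh(comp)
        inten = total_intensity * fraction
        if intensity_cv > 0:
            inten *= 1.0 + rng.normal(0.0, intensity_cv)
        peaks.append(Peak(mz=mz, intensity=max(inten, 0.0)))
    return peaks


def synth_ms2(
    mixture: dict[str, float],
    intensity: float = 1e5,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> dict[IonSpecies, float]:
    """Ion-species intensities for a mixture of acetylation patterns.

    Each pattern contributes ``fraction·intensity`` to each of its B/Y ion
    species (equal response); multiplicative Gaussian noise is then applied
    per observed ion species.
    """
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ChitosimValidationError(f"mixture sums to {total}, expected 1")
    out: dict[IonSpecies, float] = {}
    for pattern, fraction in mixture.items():
        if fraction <= 0:
            continue
        for ion in theoretical_ions(pattern):
            out[ion.species] = out.get(ion.species, 0.0) + fraction * intensity
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        for key in sorted(out):
            out[key] = max(out[key] * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
    return out


def synth_plate(
    true_activities: dict[str, float],
    control_conc: float = 150.0,
    noise_sd: float = 0.0,
    outlier_prob: float = 0.0,
    outlier_scale: float = 3.0,
    seed: int = 0,
    replicates: int = 4,
    muteins_per_plate: int = 76,
    controls_per_plate: int = 4,
) -> list[WellRecord]:
    """Synthetic fluorescamine screen: standards, controls and mutein wells.

    Every replicate is an independent plate set.  Standards sit at the
    glucosamine series (0, 75, 150, 250 µM) in triplicate on each plate;
    control wells at ``control_conc`` µM; mutein wells at
    ``activity × control_conc`` µM.  Gaussian concentration noise (µM) is
    added to every non-standard well, standards carry the same noise on
    their fluorescence-equivalent concentration, and a mutein well becomes an
    outlier (concentration × ``outlier_scale``) with probability
    ``outlier_prob``.
    """
    if not 0.0 <= outlier_prob <= 1.0:
        raise ChitosimValidationError("outlier_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mutein_ids = list(true_activities)
    records: list[WellRecord] = []

    def fluor(conc_um: float) -> float:
        return PLATE_INTERCEPT + PLATE_SLOPE * conc_um

    for rep in range(1, replicates + 1):
        for start in range(0, len(mutein_ids), muteins_per_plate):
            chunk = mutein_ids[start : start + muteins_per_plate]
            plate_id = f"P{start // muteins_per_plate + 1:02d}-R{rep}"
            well_no = 0
            for conc in STANDARD_CONCENTRATIONS:
                for _ in range(3):
                    well_no += 1
                    c = conc + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    records.append(
                        WellRecord(plate_id, f"W{well_no:02d}", "standard",
                                   f"{conc:g}", fluor(c))
                    )
            for _ in range(controls_per_plate):
                well_no += 1
                c = control_conc + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                records.append(
                    WellRecord(plate_id, f"W{well_no:02d}", "control", "nm", fluor(c))
                )
            for mid in chunk:
                well_no += 1
                c = true_activities[mid] * control_conc
                if outlier_prob > 0 and rng.random() < outlier_prob:
                    c *= outlier_scale
                if noise_sd > 0:
                    c += rng.normal(0.0, noise_sd)
                records.append(
                    WellRecord(plate_id, f"W{well_no:02d}", "mutein", mid,
                               fluor(max(c, 0.0)))
                )
    return records


def make_synthetic(spec: dict, outdir, seed: int | None = None) -> dict:
    """Write a complete synthetic fixture set plus its ground truth.

    ``spec`` chooses parameters per data kind (missing kinds use defaults);
    files written: sequences.fasta, peaklist.csv, ms2_ions.csv, plates.csv
    and truth.json.  Returns the truth dictionary.
    """
    from .core import write_sequences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(spec.get("seed", 0) if seed is None else seed)
    truth: dict = {"seed": seed}

    poly = spec.get("polymers", {"dp": 1000, "fa": 0.3})
    seqs = {
        "random": random_polymer(int(poly.get("dp", 1000)),
                                 float(poly.get("fa", 0.3)), seed),
        "alternating": patterned_polymer(int(poly.get("dp", 1000)), "alternating"),
        "blocky": patterned_polymer(int(poly.get("dp", 1000)), "blocky",
                                    a_len=3, d_len=2),
    }
    write_sequences(outdir / "sequences.fasta", seqs.values(), names=seqs.keys())
    truth["polymers"] = {k: {"dp": s.dp, "fa": s.fa} for k, s in seqs.items()}

    ms1_spec = spec.get(
        "peaklist",
        {"ra": {"A4": 0.25, "A3D1": 0.5, "A2D2": 0.25}, "intensity_cv": 0.02,
         "mz_sd": 0.005},
    )
    peaks = synth_peaklist(
        ms1_spec["ra"],
        total_intensity=float(ms1_spec.get("total_intensity", 1e6)),
        mz_sd=float(ms1_spec.get("mz_sd", 0.0)),
        intensity_cv=float(ms1_spec.get("intensity_cv", 0.0)),
        seed=seed + 1,
    )
    pd.DataFrame([{"mz": p.mz, "intensity": p.intensity} for p in peaks]).to_csv(
        outdir / "peaklist.csv", index=False
    )
    truth["peaklist"] = {"ra": dict(ms1_spec["ra"])}

    ms2_spec = spec.get(
        "ms2", {"mixture": {"ADDA": 2 / 3, "AADD": 1 / 3}, "noise_cv": 0.05}
    )
    ions = synth_ms2(
        ms2_spec["mixture"],
        noise_cv=float(ms2_spec.get("noise_cv", 0.0)),
        seed=seed + 2,
    )
    pd.DataFrame(
        [
            {"ion_type": t, "length": ln, "nA": na, "nD": ln - na, "intensity": v}
            for (t, ln, na), v in sorted(ions.items())
        ]
    ).to_csv(outdir / "ms2_ions.csv", index=False)
    truth["ms2"] = {"mixture": dict(ms2_spec["mixture"])}

    plate_spec = spec.get("plate", {})
    activities = plate_spec.get("activities")
    if activities is None:
        rng = np.random.default_rng(seed + 3)
        activities = {
            f"M{i + 1:03d}": float(a)
            for i, a in enumerate(rng.uniform(0.0, 1.2, size=40))
        }
    wells = synth_plate(
        activities,
        control_conc=float(plate_spec.get("control_conc", 150.0)),
        noise_sd=float(plate_spec.get("noise_sd", 0.0)),
        outlier_prob=float(plate_spec.get("outlier_prob", 0.0)),
        outlier_scale=float(plate_spec.get("outlier_scale", 3.0)),
        seed=seed + 4,
        replicates=int(plate_spec.get("replicates", 4)),
    )
    pd.DataFrame(
        [
            {"plate": w.plate, "well": w.well, "role": w.role,
             "payload": w.payload, "fluorescence": w.fluorescence}
            for w in wells
        ]
    ).to_csv(outdir / "plates.csv", index=False)
    truth["plate"] = {"activities": activities}

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
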