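# chitosim

Subsite-preference simulation and mass-spectrometry analytics for chitin
deacetylase (CDA) engineering.

Chitosans are β-1,4-linked copolymers of N-acetylglucosamine (GlcNAc, **A**)
and glucosamine (GlcN, **D**). Their biological activity depends not only on
chain length (DP) and acetylation fraction (F_A) but on the *pattern of
acetylation* (PA) — and CDAs, which deacetylate chitin or, run in reverse,
N-acetylate polyglucosamine, imprint nonrandom PAs that reflect their
subsite preferences for A or D units along the binding groove. This package
is for enzyme engineers and glycobiologists who want to reason about that
chain of cause and effect quantitatively: from per-subsite preference
energies, through simulated (de)acetylation trajectories, to the analytical
readouts used in practice.

It provides, as composable library modules with a CLI on top:

- **Sequence/mass core** — A/D chains (nonreducing → reducing), compositions
  A_nD_m, exact monoisotopic [M+H]+ masses (A3D1 789.325, A2D2 747.314,
  A1D3 705.304 Da).
- **Subsite-energy simulator** — binding frames over subsites −3…+2, frame
  energy E = Σ_s e(s, occupant), memoryless Boltzmann events P ∝ exp(−E);
  exact product distributions for oligomers, seeded trajectories with F_A
  checkpoints for polymers (DP up to 10⁴). Presets: `nm`, `H199K`, `H199Y`,
  `neutral`.
- **Chitinosanase fingerprinting** — in silico digestion (cleaves after
  every D,A dimer; interior products report the originating block sizes) and
  the weight-average block statistics
  block(A)_w = Σ DP_i·I_i·N(A)_i / Σ DP_i·I_i plus the DP 2–14 oligomeric
  fraction.
- **MS¹ quantification** — peak-list → relative species amounts →
  relative acetate release rar = Σ k·ra (k = ΔnD), e.g.
  rar(A4) = ra_A3D1 + 2·ra_A2D2.
- **MS² pattern deconvolution** — theoretical B/Y ion ladders and NNLS
  recovery of acetylation-pattern mixtures from ion-species intensities.
- **Plate-screen analytics** — SSM library enumeration (27 positions × 19 =
  513 variants), glucosamine standard curves, per-plate control
  normalization, and the guarded SD>0.2 outlier rule.
- **Synthetic data** — seeded generators for every input, with ground truth.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Simulate N-acetylation of polyglucosamine with the nonmutated-enzyme preset
and fingerprint the product:

```python
from chitosim import (PRESETS, PaSequence, SimulationConfig,
                      digest_and_score, simulate_polymer, random_polymer)

config = SimulationConfig(direction="N-acetylate", seed=1, target_fa=0.3)
traj = simulate_polymer(PaSequence("D" * 2000), PRESETS["nm"], config)
_, stats = digest_and_score(traj.final, dp_window=(2, 10**9))
_, ctrl = digest_and_score(random_polymer(2000, 0.3, seed=1),
                           dp_window=(2, 10**9))
print(f"block(A)_w enzyme={stats.blockA_w:.2f} random={ctrl.blockA_w:.2f}")
```

prints

```
block(A)_w enzyme=11.76 random=1.66
```

— the enzyme's GlcNAc preference at subsites −2/−1 concentrates acetylation
next to existing A units, building A-blocks roughly seven times larger than
the Bernoulli control at the same F_A. The same comparison across presets
(`analysis/01_polymer_patterns.py`, 20 seeds) gives mean block(A)_w at
F_A 0.3 of 22.2 (H199K) > 12.5 (nm) > 1.6 (random) ≈ 1.3 (H199Y), with
oligomeric fractions 0.01, 0.04, 0.87 and 0.28: blockier chitosans resist
chitinosanase digestion into short oligomers, while the H199Y preset's
near-alternating product digests almost completely.

The numbered scripts under `analysis/` run the three studies end to end
(polymer patterns, 470-mutein screen, oligomer MS) and write their tables to
`results/`.

## Command line

```bash
chitosim make-synthetic --seed 3 --out fixtures/
chitosim screen --plates fixtures/plates.csv --out screen.csv
chitosim simulate --seq start.txt --profile H199Y --direction ac \
    --target-fa 0.5 --checkpoints 0.1,0.3,0.5 --seed 4 --out run
chitosim digest --seq run_snapshots.fasta --out table.csv,stats.json
chitosim ms1-quant --peaks fixtures/peaklist.csv --substrate A4 --out ra.json
chitosim rar --ra ra.json
chitosim ms2-pa --obs fixtures/ms2_ions.csv --composition A2D2 --out pa.json
```

Exit codes: 0 success, 2 invalid input/configuration, 1 runtime failure.

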