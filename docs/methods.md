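# Methods

## Scope and model overview

`chitosim` models how the subsite preferences of a chitin deacetylase (CDA)
shape the pattern of acetylation (PA) of its products, and implements the
analytics used to read that pattern out: in silico chitinosanase
fingerprinting, MS¹/MS² quantification of partially acetylated
chitooligosaccharides (paCOS), and site-saturation-mutagenesis (SSM)
plate-screen analytics. All stages run on seeded synthetic data with known
ground truth.

## Sequence and mass model

Chains are strings over {A, D} (A = GlcNAc, D = GlcN), written nonreducing →
reducing; user-facing positions are 1-based. Derived quantities are the
degree of polymerization DP and the fraction of acetylation F_A = #A/DP.

Masses are monoisotopic, built from C 12.000000, H 1.0078250319,
N 14.0030740, O 15.9949146 and proton 1.00727646688 Da. Residue (in-chain)
masses are GlcNAc C8H13NO5 = 203.0794 Da and GlcN C6H11NO4 = 161.0688 Da;
their difference is the acetyl delta C2H2O = 42.0106 Da. The [M+H]+ of
A_nD_m is n·mA + m·mD + water + proton, e.g. A3D1 789.325, A2D2 747.314,
A1D3 705.304. Only singly protonated adducts are modelled; Na/K adducts,
isotope envelopes and charge states ≥2 are out of scope.

## Subsite-energy simulator

The enzyme groove spans subsites −3…+2 with the catalytic site at subsite 0.
A *binding frame* places subsite 0 over an eligible unit (A for
deacetylation, D for N-acetylation). Its energy is

    E(frame) = Σ_s e(s, state at p+s),   s ∈ {−3…+2},

where the state is A, D, or *empty* when p+s falls outside the chain; the
empty term encodes occupancy effects (a frame that leaves a favourable
subsite uncovered pays a penalty). Energies are in kT with β = 1 — only
differences matter. Each catalytic event is a memoryless Boltzmann choice,
P(frame) ∝ exp(−E); +inf energies are hard exclusions, and defaults are
finite (soft) so that, e.g., N-acetylation of pure polyglucosamine can
initiate even with D at every subsite. There is no explicit time axis, no
processivity and no enzyme concentration: trajectories are indexed by event
count and checkpointed by F_A, which is how enzymatically produced chitosans
are characterised. One seeded PCG64 generator drives a whole trajectory;
identical inputs reproduce trajectories bit for bit.

For oligomers, `product_distribution` enumerates all frame choices exactly
(capped; DP ≤ 12 with ≤ 3 events); `simulate_polymer` handles chains to
DP 10⁴ with vectorised energy evaluation.

### Presets

The bundled profiles are *qualitative*: no quantitative subsite energies are
available, so the presets' only contract is the direction of the product
shifts they induce.

| preset  | eA(−2) | −1 term  | eEmpty(+1) | intended behaviour            |
|---------|--------|----------|------------|-------------------------------|
| neutral | 0      | 0        | 0          | exchangeable (Bernoulli) ref. |
| nm      | −4     | eA = −2  | +1         | large A-blocks                |
| H199K   | −4     | eA = −3  | +1         | largest A-blocks              |
| H199Y   | −4     | eD = −1  | +1         | near-alternating PA           |

GlcNAc preference at −2 and −1 makes N-acetylation extend existing A-blocks
toward the reducing end; replacing the −1 preference with mild GlcN
acceptance (H199Y) makes acetylation land two units downstream of an A,
producing an alternating pattern. The +1 occupancy penalty encodes the
favourability of covering subsite +1.

Known limitation: for the specific case of deacetylating AADA, the model
lets the [−3,0] frame collect the −2 GlcNAc bonus and therefore favours
AADD, whereas the real nonmutated enzyme favours ADDA 2:1 via the −1
preference with −2 unoccupied. Capturing that would require mode-dependent
energies; the presets deliberately stay within the additive per-subsite
model, whose contract is the polymer-level orderings below.

## Chitinosanase digest and block statistics

Chitinosanase cleaves after every D,A dimer. Interior products (neither
chain terminus) therefore consist of the tail of one A-block, a full
D-block, and the first unit of the next A-block, so their (nA, nD) equal the
originating A- and D-block sizes — verified against run-length encoding on
seeded random sequences, including the edge case of a chain ending exactly
in "DA" (where the final cut coincides with the chain end and does not
happen). Terminal fragments are reported but excluded from statistics.

Species are keyed by (DP, nA) since MS cannot separate sequence isomers.
Intensities are `molar` (count, MS emulation) or `mass` (count·DP,
refractive-index emulation; the default). The weight-average block sizes are

    block(A)_w = Σ DP_i·I_i·N(A)_i / Σ DP_i·I_i     (block(D)_w analogous)

over species within a DP window, default 2–14 (the SEC-resolvable
oligomers), and the oligomeric fraction is the windowed share of Σ DP·I.

**Windowing caveat.** The windowed block(A)_w is monotone in true block size
only while blocks are commensurate with the window. With the preset
energies, simulated A-blocks at F_A 0.3 average ~10–30 units; the DP 2–14
statistic then collapses onto the small-fragment tail and can even invert
cross-enzyme comparisons. The workflow therefore reports both the windowed
statistics (`blockA_w`, experiment-faithful) and unwindowed ones
(`blockA_w_all`), and cross-enzyme orderings are asserted on the unwindowed
values. If all signal falls outside the window, the windowed averages are
NaN and the oligomeric fraction is 0.

## MS¹ quantification and relative acetate release

Peaks within ±0.02 Da (absolute tolerance; appropriate for 1+ ions over a
250 Da window) of a species' [M+H]+ are summed; relative amounts (ra)
normalize over all matched species *including residual substrate*, under an
equal-ionization-response assumption across species of equal DP. Overlapping
target windows are a configuration error. The relative acetate release is

    rar = Σ_species k·ra(species),  k = nD(species) − nD(substrate), k ≥ 1,

which specialises to rar(A4) = ra_A3D1 + 2·ra_A2D2 (+…) and
rar(A3D1) = ra_A2D2 + 2·ra_A1D3 + 3·ra_D4. rar is bounded by nA(substrate);
a species more acetylated than the substrate is rejected.

## MS² pattern deconvolution

Glycosidic cleavage of [M+H]+ precursors yields B (nonreducing oxocarbenium,
B1 of GlcNAc = 204.087 Da) and Y (reducing-end retaining) ions:
B_i = Σ first-i residue masses + proton, Y_j = Σ last-j residue masses +
water + proton, with B_i + Y_(dp−i) = [M+H]+ + proton exactly. The
observable is the ion *species* (type, length, composition).

A pattern mixture is recovered by NNLS of observed intensity shares onto the
candidates' 0/1 incidence profiles (columns normalized by ion count; equal
response within ion type is assumed). Ion species identical across all
candidates are uninformative and dropped. A ridge term (1e−9, via row
augmentation) stabilises degenerate fits; rank deficiency raises an
`AmbiguousPatternsWarning` (for same-composition patterns the B-ladder alone
distinguishes any two candidates, so exact ties cannot occur, but the full
A2D2 candidate set is rank-deficient as a linear system — nonnegativity
usually still identifies the fit). The residual norm is reported as a
diagnostic. Internal fragments, cross-ring cleavages, neutral losses and
reducing-end labels are out of scope; the equal-response share model is a
declared approximation validated only on synthetic data.

## Plate-screen analytics

SSM libraries substitute each chosen position with all 19 non-wild-type
amino acids (27 positions → 513 variants). Per plate: an OLS standard curve
through the glucosamine series (0, 75, 150, 250 µM), fluorescence → µM
inversion (negatives clamp to 0 with a flag), and division of mutein
concentrations by the plate's mean control concentration. Replicates pool
across plates and are summarized with a guarded outlier rule: with sample
(n−1) SD — the SD flavour is a documented choice — if SD > 0.2 (on the
normalized, unitless scale) the value furthest from the mean is removed
(ties broken toward the larger value, a documented deterministic choice);
the removal is withdrawn unless it lowers the SD by more than 20%. At most
one value is ever removed and the rule is disabled below three replicates
(a removal from two leaves the SD undefined).

## Synthetic data

Generators emulate each input stream with explicit ground truth: Bernoulli/
blocky/alternating chains; MS¹ peak lists (Gaussian m/z jitter, multiplicative
intensity noise, clamped at 0); MS² ion tables (equal-response forward model,
multiplicative noise); plate sets (fluorescence = 100 + 2·µM, additive µM
noise, outlier wells scaled ×3 with set probability; 12 standard wells, 4
controls and up to 76 muteins per plate, one plate set per replicate). All
generators are bit-reproducible under their seed. They deliberately omit
response factors, isotope envelopes, retention-time structure and plate edge
effects, so passing round-trip tests demonstrates correctness of the
analytics, not robustness to every artefact of real spectra and plates.

## Problem sizes and numerical choices

Polymer runs use DP 2000 and 12–20 seeds per condition (the simulator
handles DP 10⁴; DP 2000 keeps Monte-Carlo error on block statistics below
the effect sizes of interest). The neutral-profile exchangeability check
uses 50 seeds at DP 1000 with a two-sample KS test (p > 0.01). Boltzmann
weights are computed as exp(−(E − E_min)) for overflow safety; +inf maps to
weight 0, and a reaction with no finite-energy frame raises a stalled-
reaction error (polymer trajectories return partial results with a stalled
flag). Probabilities from exact enumeration sum to 1 within 1e−9.

## Directional findings reproduced on synthetic runs

At matched F_A ≤ 0.3 (20 seeds, DP 2000), unwindowed block(A)_w orders
H199K ≥ nm > random ≳ H199Y; the oligomeric fraction orders in reverse
(H199K ≤ nm < random); and at F_A 0.5 the H199Y digest is strongly enriched
in A1D1 fragments relative to the random control. Near the alternating-
saturation point (F_A → 0.5) the H199Y chain must fill residual gaps, which
creates occasional spurious blocks — comparisons against the random control
are therefore made below saturation. Magnitudes depend on the unquantified
preset energies and are not claims about any particular enzyme.
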