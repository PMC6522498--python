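# Methods

## Scope and model

The package analyses the residual structure of an intrinsically disordered
polyQ protein fragment from backbone chemical shifts, at three levels:
per-residue secondary-shift indicators, windowed SSP propensities, and a
weighted conformational ensemble whose averaged predicted shifts match the
measured ones. A fourth, independent observable — hydrogen/deuterium
exchange — is classified into slow/fast amides. All residue numbering is in
the normal-polyQ (10Q) frame; expanded variants carry their extra
glutamines as fractional insertion labels (39.01, 39.02, …) so that
variants of different tract lengths can be compared residue by residue.

## Reference data

Random-coil shifts are the Wishart et al. (1995) values, bundled with their
provenance string; glycine has no Cβ and proline no amide proton, so those
observables simply do not exist anywhere in the pipeline. A switchable
correction for residues preceding proline (Cα −2.0 ppm) is off by default
because the analyses here compare variants measured under identical
conditions. The fully-formed helix/strand secondary-shift offsets per
nucleus (e.g. Cα +2.8/−1.6 ppm) follow the CSI/SSP literature consensus and
are config-overridable; all downstream calibrations (a fully-formed helix
scores +1) are defined relative to whatever offset set is in use, so
substituting another published set rescales nothing structurally.

## SSP scoring

Each secondary shift is mapped onto a common propensity axis: divided by
the fully-formed helix offset when it deviates in the helical direction,
otherwise by the strand offset (with sign), so +1/0/−1 mean
helix/coil/strand. Scores are averaged over a 5-residue window with
per-nucleus weights {Cα 1.0, Cβ 1.0, Hα 0.8, Hᴺ 0.3, N 0.3}; amide shifts
are down-weighted because they respond strongly to solvent exposure, pH and
temperature rather than backbone conformation. Window members deviating
from the weighted window mean by more than one weighted standard deviation
are excluded once and the mean recomputed — this suppresses isolated
outliers (mis-referenced or exchange-broadened residues) without breaking
the linearity of the score in the underlying shifts. A score is reported
only where at least three residues, and at least half of the residues the
window covers, contribute a usable nucleus; chain termini therefore thin
out rather than extrapolate. Helical segments are maximal runs of ≥ 3
residues at or above a threshold (0.3 by default, matching the level at
which the ARR2 helix stands out of the disordered baseline).

## Conformers and the forward model

Pool members are backbone-only chains built from (φ, ψ) with ideal geometry
(N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å, C=O 1.23 Å; N–Cα–C 111.0°,
Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O 120.5°; ω = 180°), which fixes the
consecutive Cα–Cα distance at 3.80 Å. Secondary structure is assigned from
dihedral basins — helix φ∈[−100,−30], ψ∈[−80,0] for ≥ 3 consecutive
residues; extended φ∈[−180,−90], ψ∈[90,180] for ≥ 2 — a declared stand-in
for H-bond-based assignment that is exact on the ideal-geometry chains used
here; 3₁₀/π-helical states are not distinguished. Predicted shifts are
linear in the state: random coil plus the helix or strand offset, zero for
coil. This keeps ensemble-averaged shifts exactly linear in the weights,
which is the structural property the reweighting relies on; accuracy
relative to a trained predictor is deliberately not claimed, and an
externally computed prediction matrix can be imported as CSV.

## Reweighting

Weights minimise the plain sum of squared ppm residuals over all matched
observables, optionally with per-nucleus inverse-variance scaling and an l2
ridge (default 0), under wₖ ≥ 0 and Σwₖ = 1. The solver is SLSQP on the
precomputed quadratic form with an analytic gradient, initialised at
uniform weights, ftol 1e−10, at most 1000 iterations; the returned point is
clipped at zero and renormalised, and must not be worse than uniform
weights (otherwise a fit error carrying the last iterate is raised).
Identifiability is monitored rather than assumed: the rank of the
mean-centred prediction matrix is checked and the result flagged when it
cannot pin down K−1 independent weight directions (duplicate or
near-duplicate conformers), and the effective ensemble size 1/Σw² is always
reported. With the linear forward model the information content is at most
two directions per residue (helix and strand occupancy), so pools much
larger than twice the chain length are genuinely non-identifiable; the flag
makes that visible instead of letting the solver pick silently.

## HDX classification

The experimental readout being reproduced is peak presence after exchange,
not exchange-rate constants, so classification is a single ratio:
intensity at the reference time (15 min) over the H2O control, slow iff
≥ 0.2. The threshold is an operationalisation (config-exposed); the
qualitative map — which regions retain amides — is insensitive to it over a
wide range because protected and unprotected ratios separate by an order of
magnitude. An alternative criterion fits a log-linear decay over all time
points and evaluates it at the reference time; it agrees on clean decays
and is more robust when a single spectrum is noisy. Prolines and residues
without a control peak are excluded; slow unassigned tract glutamines are
reported as their own category, mirroring how repeat-region amides that
cannot be assigned site-specifically are presented.

## Synthetic scenarios

The generator replaces the two expensive inputs — conformer pools from
replica-exchange MD and measured spectra — while keeping the statistical
structure the analysis assumes.

*Sequence.* The 62-residue 10Q stand-in follows the block architecture of
the ataxin-7 N-terminus (N-terminal segment, Ala-rich ARR1 and ARR2, Arg29,
polyQ at 30–39, proline-rich region at 40–62) and is consistent with every
individually named residue position (Ala19, Ala24–Ala28, Arg29, the tract
glutamines); it is a synthetic construction, not the deposited wild-type
sequence, and is documented as such in the code.

*Propensities.* Defaults per preset: ARR2+Arg29 0.70, ARR1 0.30, tract 0.15
(normal) or 0.15 + 0.45·exp(−j/5) decaying from the ARR-adjacent end
(expanded presets), proline-rich region 0.02, N-terminus 0.05;
`helix_broken` sets ARR2 to 0.05 and removes the tract boost, emulating
helix-disrupting ARR mutations. These place the normal variant's overall
helicity low (SSP well under 0.5) with a clear local ARR2 helix, and give
the expanded variants the ARR-adjacent tract helicity the comparison
analyses look for.

*Pools.* Helix runs nucleate with probability p̄/(L·(1−p̄)) per coil
residue (L ≈ 5.86 the mean run length, minimum run 4) and extend with
per-step continuation damped by the local propensity, so that the renewal
process covers each residue with probability close to its propensity;
dihedrals are drawn inside the corresponding basin with jitter, coil
residues from a polyproline-II-like band with a 15 % admixture of strand
basin draws. The marginal helix frequency matches the propensity profile to
within a few hundredths in flat regions; sharp propensity steps smear by
roughly one residue and block edges carry biases up to ~0.04 — an inherent
property of run-based sampling that the end-to-end tolerance (profile MAE
≤ 0.1) absorbs. Pool generation, shift noise, HDX noise and ground-truth
weights each consume a fixed sub-stream of the scenario seed, so adding one
operation never perturbs another's draws.

*Shifts and HDX.* Synthetic experimental shifts are the weighted ensemble
average under a ground-truth weight vector (a flat-Dirichlet draw unless
fixed explicitly) plus i.i.d. Gaussian noise, default σ = 0.05 ppm — the
order of random-coil prediction uncertainty for carbons. Synthetic HDX
gives residues at propensity ≥ 0.5 a 15-min ratio in [0.55, 0.90] and all
others ≤ 0.04, with 5 % multiplicative log-normal noise; the margin around
the 0.2 classification threshold makes the slow/fast map deterministic in
practice.

*What is not emulated.* Real pools are force-field ensembles with
correlated tertiary structure; real shifts carry referencing offsets,
sequence-neighbour effects and nucleus-dependent noise; real HDX convolves
intrinsic rates with pH and temperature. Passing the synthetic suite
therefore demonstrates that the estimators are correct and well-conditioned
under the model's assumptions, not that the forward model is accurate for
real spectra.

## Problem sizes and numerics

The standard test and acceptance configuration uses K = 100 conformer
pools (≈ 300–350 observables on the 62–74-residue sequences), where the
noiseless ground-truth mixture is recovered to max weight error ≲ 1e−4 and
the σ = 0.1 ppm case to ≲ 0.05; the Monte-Carlo frequency check uses
K = 500. Grid-search oracles (step 1e−4 in 1-D, 1e−2 on the 2-simplex)
cross-check the solver for K ≤ 3. Equality of shift tables is tested to
0.001 ppm, matching the CSV output precision.

## Known limitations

- Bound checks against the deposited experimental shift sets require the
  NMR-STAR downloads under `tests/data/bmrb/`; without them those two tests
  fail rather than skip.
- The random-coil set the original SSP analyses used is not recorded
  anywhere authoritative; absolute SSP values on real data shift by a few
  hundredths between published random-coil sets, which is why real-data
  comparisons are phrased as bounds.
- The dihedral-basin SS assignment and the linear forward model are
  stand-ins chosen for transparency and testability; neither should be used
  to interpret fine per-residue detail of real spectra without swapping in
  a trained predictor via the matrix adapter.
- NMR-STAR support covers assigned-chemical-shift loops (2.1 and 3.1) only.
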