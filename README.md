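# polyq-ens

Chemical-shift-based structural analysis of the flanking regions of a
polyglutamine (polyQ) tract, built around the N-terminal fragment of
ataxin-7: an intrinsically disordered 62-residue chain in which an
alanine-rich region (ARR) just ahead of the tract forms a marginally stable
α-helix that can propagate into the polyQ sequence when the tract expands.

The package is for structural biologists and biophysicists who want to turn
backbone chemical shifts and a conformer pool into residue-level structural
statements: which residues are helical, how strongly, and how that changes
with polyQ length.

## What it computes

**Secondary chemical shifts.** For each residue and nucleus
(Hᴺ, N, Hα, Cα, Cβ), Δδ = δ_obs − δ_rc, with bundled random-coil reference
values. The per-residue indicator (ΔδCα − ΔδCβ) > 0 marks helical
population.

**SSP propensity score.** A sliding-window (default 5 residues),
nucleus-weighted average of secondary shifts, each normalised by the average
secondary shift of a fully-formed helix or extended strand, with window
outliers (> 1 SD from the window consensus) excluded. +1 means a well-formed
helix, −1 a well-formed strand, 0 random coil. Helical segments are called
as runs of ≥ 3 residues above a threshold.

**Ensemble reweighting.** Given a pool of K backbone conformers with
predicted shift matrix M (K × J) and J experimental shifts y, weights w on
the probability simplex are fitted with SLSQP to minimise

    ‖Mᵀw − y‖² + λ‖w‖²,   wₖ ≥ 0,  Σwₖ = 1,

yielding per-residue secondary-structure probabilities
p_S(i) = Σₖ wₖ·1[ssₖ(i) = S], per-nucleus fit RMSDs, and the effective
ensemble size 1/Σwₖ². Conformers are built from (φ, ψ) dihedrals with ideal
geometry and classified H/E/C by dihedral basins; predicted shifts come
from a declared linear forward model (random coil + per-state offset), with
a CSV adapter for externally predicted matrices.

**HDX classification.** Amides whose HSQC peak keeps ≥ 20 % of its control
intensity after 15 min of H/D exchange are labelled slow exchangers
(`+` assigned, `*` unassigned tract glutamine), reproducing the residue map
that localises protected amides to the ARR and polyQ regions.

**Synthetic data.** A generator stands in for molecular-dynamics sampling
and the spectrometer: preset scenarios (`normal_10Q`, `expanded_22Q`,
`expanded_33Q`, `helix_broken`) define per-residue helix propensities,
pools are sampled as nucleate-and-extend helix runs, and "experimental"
shifts are ensemble averages under a known ground-truth weight vector plus
Gaussian noise — so every stage of the pipeline is testable offline against
known truth.

## Worked example

```sh
polyq-ens demo --seed 1 --outdir demo_out
```

runs the full synthetic pipeline for the normal-length (10Q) scenario with
a 100-conformer pool and prints

```
demo complete: mean ARR2 p_H 0.68, 7 slow exchangers -> demo_out
```

The ensemble fitted to the noisy synthetic shifts recovers the generating
helix probabilities: mean p_H over the ARR2 helix (residues 23–28) is 0.684
against a generating propensity of 0.70, mean p_H over the 10Q tract
(residues 30–39) is 0.138 against 0.15, with effective ensemble size 32.6
of 100 and a Cα fit RMSD of 0.04 ppm (`demo_out/ensemble.json`). The SSP
profile computed from the same synthetic shifts (`demo_out/ssp.csv`) scores
0.49–0.69 across Ala24–Ala28, the helical ARR2 core, and `demo_out/hdx_map.csv`
marks 7 slow-exchanging amides, all in the high-propensity region. Rerunning
with the same seed reproduces every output byte for byte.

The same stages are available on files you supply:

```sh
polyq-ens ssp --shifts shifts.str --window 5 --out ssp.csv
polyq-ens reweight --pool pool.pdb --exp shifts.csv --nuclei CA,CB --out ens.json
polyq-ens hdx --in hdx.csv --out map.csv
polyq-ens simulate --preset expanded_22Q --k 500 --seed 42 --outdir sim/
```

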