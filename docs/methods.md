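# Methods

`biososs` simulates single-object X-ray scattering sampling (SOSS) of a
biomolecule labeled with two gold nanoparticles (AuNPs) and retrieves the
three-dimensional inter-particle vector from each single-shot image. This
note records the model, its assumptions, the numerical choices, and what
the synthetic test bed does and does not establish about real experiments.

## Forward model

An isolated molecule sits at the origin; an ultrashort coherent pulse of
photon energy `E` (wavelength `λ = 12.39842/E[keV]` Å) propagates along
+z. A square detector of `n × n` pixels with pitch `p` lies perpendicular
to the beam at distance `l`. Pixel `(i, j)` has its center at
`((i−(n−1)/2)p, (j−(n−1)/2)p, l)`; intensity is evaluated at pixel centers
only. With `k = 2π/λ` and `ŝ` the unit vector from sample to pixel, the
momentum transfer is `q = k(ŝ − ẑ)`, so `|q| = 4π sin θ/λ` and
`q_z = k(cos 2θ − 1) ≤ 0`. The Ewald-sphere curvature makes `q_z` second
order in the scattering angle; this asymmetry is the physical reason the
z-component of any retrieved vector is the least determined.

Expected photon counts per pixel are the coherent sum over scatterers

    S(q) = ½(1 + cos²2θ) · Ω · r_e² · Φ · |A(q)|²,
    A(q) = Σ_j f_j(|q|) e^{iq·x_j} + Σ_{k=1,2} f_NP(|q|, R) e^{iq·c_k},

with `Ω = p² cos³2θ / l²` the pixel solid angle, `r_e` the classical
electron radius, and `Φ = I/(π(f/2)²)` the fluence of a uniform circular
top-hat focal spot of diameter `f` (the molecule is assumed fully inside
the spot). Atomic form factors `f_j` are the Cromer–Mann 4-Gaussian
parameterization (gemmi's IT92 table), evaluated at `s = q/4π`; anomalous
dispersion and incoherent (Compton) scattering are not modeled. The
polarization factor is the unpolarized Thomson term as a deliberate
simplification. Images can be decomposed into the particle-only,
molecule-only, inter-particle and particle–molecule cross terms, which sum
to the composite exactly; this bookkeeping is tested to 1e-9 relative.

### Nanoparticle form factor and its normalization

A label is a homogeneous gold sphere of radius `R`:

    f_NP(q, R) = f_Au(q) · N_atoms(R) · 3[sin(qR) − qR cos(qR)]/(qR)³,
    N_atoms(R) = ρ_Au · (4π/3) R³,   ρ_Au = 4/a³,  a = 4.0782 Å,

with the removable `q → 0` singularity replaced by its series limit, so
`f_NP(0, R)` equals the particle's total electron count (≈ 14,240 e for
`R = 9` Å). A shorthand that appears in the literature writes the
amplitude as `3 f_Au(q)[sin(qR) − qR cos(qR)]/q³`, which omits the gold
number-density factor and overstates the forward amplitude by
`1/(ρ_Au·4π/3) ≈ 4.05`, i.e. the particle's scattering power by ~16×.
The package defaults to the physical normalization
(`aunp_f(..., normalization="sphere")`); the literal shorthand is
available as `normalization="verbatim"`. The choice matters: with the
verbatim prefactor the retrieval operates in an unrealistically
information-rich regime (errors several times smaller, and the
energy-dependence of the accuracy reverses sign), whereas the physical
normalization puts the pipeline in the shot-noise-limited regime in which
sub-Ångström distance retrieval is a meaningful, non-trivial claim.

### Noise

A mock experimental image adds, per pixel, Poisson sampling of the
expected counts (shot noise) and a uniform background draw
`U(0, uniform_max)` with `uniform_max = 1` count by default. Both are
seeded; images are bitwise reproducible.

## Labeling geometry

Candidate attachment sites are the free phosphate oxygens (O1P/O2P, also
OP1/OP2) for RNA and backbone carbonyl oxygens for proteins. A particle
center is placed at the labeled oxygen displaced outward by `R` along the
bonded-heavy-atom → oxygen direction, so the sphere surface passes
through the original oxygen site; the bonded partner is the nearest
non-oxygen heavy atom in the residue (P for phosphates, carbonyl C for
peptides). The labeled oxygens are removed from the molecular scattering
sum by default (`substitute_labeled_oxygens`), treating the label as a
substitution.

Steric feasibility: a placement is rejected if any heavy atom lies within
`R + clash_margin` of the center (margin default 0.5 Å), excluding the
labeled oxygen and its covalent attachment neighborhood (atoms within
4 Å of the oxygen). The exemption is forced by the geometry: because the
sphere surface passes through the oxygen, every atom within
`√(2R·margin + margin²)` of the oxygen violates a bare margin test
regardless of direction — with a 1.5 Å margin at `R = 12` Å that is a 6 Å
ball containing the site's own covalent environment on any real
structure, so a rule without the exemption rejects every bonded site.
Hydrogens are skipped, as in standard steric screens.

Label pairs are selected so that, in **every** conformer of the ensemble,
both placements are accepted and the center separation exceeds `2.4R`
(keeping the two particles well apart); across selected pairs the
ensemble-mean separations differ pairwise by at least `min_spread`
(default 10 Å) so the pairs probe a broad distance range. Selection
enumerates all feasible site pairs and packs them by mean distance
(sorted-greedy packing is optimal for this 1-D spread constraint;
seeded random restarts provide variety). Radius sweeps keep the labeling
sites fixed across the grid — chosen at the largest, most constrained
radius — and rebuild only the particle centers, so the accuracy trend
reflects the particle size rather than a changing site composition.

## Distance retrieval

The fitted model is the idealized two-sphere pattern

    S_theo(d) = ½(1+cos²2θ)·Ω·r_e²·Φ·2 f_NP²(|q|,R)·(1 + cos(q·d)),

and the objective is the per-pixel error-weighted misfit
`χ²(d) = Σ (S_exp − S_theo)²/σ²` with `σ² = max(S_exp, 1)` — measured-
variance (Poisson-style) weighting. Model-variance (Pearson) weighting
was evaluated and rejected: the two-sphere model omits the molecular
scattering, and weighting by the model's own near-zero values at the
envelope nulls amplifies exactly the pixels where that unmodeled signal
dominates, degrading the fit markedly.

Because `cos` is even, the pattern determines `d` only up to a global
sign; every vector (fitted and truth alike) is canonicalized to `z > 0`
(tie-break `x > 0`, then `y ≥ 0`) before comparison.

Initialization is a chirp-matched fringe search:

1. The smooth single-particle envelope `2 f_NP²·(prefactors)` is
   subtracted; the residual oscillates as `envelope·cos(q·d)`. For
   nonzero `d_z` this is a *chirped* transverse oscillation — the
   Ewald-curvature phase `q_z(q)·d_z` is quadratic in the pixel radius —
   which smears the plain 2-D Fourier peak badly enough that molecular
   speckle can outshine it. Keeping the envelope as an implicit SNR
   weight (rather than dividing it out, which would let noise-dominated
   high-q pixels swamp the spectrum), the residual is demodulated by
   `exp(−i q_z z)` on a z grid and Fourier transformed per slice; the
   fringe refocuses into a sharp peak exactly when `z` matches.
2. The z grid is sampled at least twice per Ewald-curvature basin
   (`~π/q_z,max`, ≈ 2.7 Å at the baseline geometry); a coarser scan
   silently converges to false minima several Å off for near-axial
   vectors. Spectrum bins whose implied separation `√(x²+y²+z²)` falls
   below a known lower bound on `|d|` are masked: when labels are placed
   under the `2.4R` separation rule that region of the spectrum carries
   only intramolecular pair correlations, which otherwise dominate the
   peak search.
3. Per-slice peak positions (parabolic sub-bin interpolation, mapped
   through the small-angle dispersion `q_xy ≈ kp/l` per pixel) rank
   `(x, y, z)` candidates; sub-bin transverse offsets are added, the top
   candidates ranked by χ², and each refined with a bounded trust-region
   least-squares minimization using the analytic Jacobian. The lowest χ²
   wins. Images whose total counts fall far below the envelope's
   expectation, or with no spectral peak above the noise floor, are
   reported as featureless (no fit). The whole procedure is
   deterministic.

Even with a correct global optimizer, the unmodeled molecular scattering
biases the χ² minimum of individual near-axial samples by a few Å in z
(the envelope decays before `q_z` grows, so little genuine z information
remains); these samples form heavy tails in the `Δz` and `Δr`
distributions that the Gaussian-fit widths partially absorb.

## Accuracy statistics

For each (conformer, label pair) sample the pipeline records
`Δr = r_fit − r_AuNP` and the canonicalized component errors
`Δx, Δy, Δz`. Samples are pooled across all label pairs before fitting a
Gaussian (least squares on a Freedman–Diaconis histogram) to each error
distribution; per-pair counts alone are too small for stable widths. The
Gaussian-fit width is the headline accuracy figure and is robust to the
rare heavy-tail events (a fit caught by a false χ² minimum); the plain
sample standard deviation is reported alongside and is sensitive to them.
Failed fits are excluded from statistics and counted.

Parameter sweeps (`R`, energy, pixel count, photons, focal size,
detector distance) rerun the full pipeline at each grid value with all
other settings at the baseline and with common random numbers across grid
points, so trend comparisons are not swamped by resampling noise.

## Baseline conditions and problem sizes

The baseline configuration is `R = 9` Å, 12 keV, `I = 10¹⁴` photons,
`f = 100` nm, `n = 250` pixels, `p = 234` µm, `l = 40` mm, Poisson +
uniform(0, 1) noise. The headline runs use a 30-snapshot, 6-pair ensemble
(180 pooled samples); sweep trend checks use 12 snapshots × 6 pairs per
grid point with a 64-pixel detector (128 pixels for the energy sweep, so
its low-energy points are limited by the single-pixel `dq` rather than by
the scaled detector's q range). Shrinking the detector at fixed pixel
pitch leaves `dq` — the quantity that controls retrieval accuracy —
unchanged. These sizes are the package's default study scale; all of them
are plain arguments.

## Synthetic conformer ensembles

The generator emulates MD snapshots of a ~2255-atom single-stranded RNA:
70 nucleotide-like residues of 32 atoms each (phosphate, ribose-like
sugar, purine-like base, 10 hydrogens) plus a 15-atom terminal cap. The
backbone is a compact solenoid — a local helix (radius 5 Å, rise 4.5 Å
per residue, twist 72°) wound on a gently climbing circular axis of
radius 23 Å — giving a globule ~65 Å across whose inter-site distances
(≈ 17–88 Å) stay below the fringe Nyquist bound `π/dq` of the baseline
detector, as they do for a folded RNA domain. Per snapshot, structural
fluctuation combines three low-frequency backbone bending modes (RMS
amplitude `fluctuation_amplitude`, default 2 Å, producing correlated
inter-site distance spreads of 2–4 Å) with i.i.d. atomic jitter at 0.15×
that amplitude — larger jitter fractions visibly break bond-level
topology. Each snapshot then receives an independent uniform random
orientation, as each recorded molecule in a single-object experiment
arrives isotropically oriented; the degenerate `fluctuation_amplitude=0`
case skips both and returns bitwise-identical snapshots.

Idealizations to keep in mind: residue geometry is schematic (the two
free phosphate oxygens are compressed toward the outward radial direction
and sit closer together than in a real phosphate; ring geometry is
approximate); the fold is a regular solenoid rather than a specific RNA
tertiary structure; fluctuations are harmonic and orientation-decorrelated
between snapshots. Passing tests on this ensemble establish that the
retrieval machinery reaches the stated accuracy under the stated
noise and geometry — not that any particular real RNA would be labeled
feasibly, nor that real conformational distributions look like these.

## Numerical choices and degenerate inputs

- Euler convention: intrinsic z-y′-z″ everywhere; random orientations are
  drawn uniformly on SO(3) (uniform α, γ; cos β uniform).
- `q_max` for the resolution limit `r_lim = 2π/q_max` is evaluated at the
  detector edge midpoint (half-width `np/2`); the corner convention is
  inconsistent with the single-pixel `dq` list by construction of the
  geometry.
- The sphere form factor's `q → 0` singularity uses the series limit
  below `qR < 10⁻³`; the Gaussian fit falls back to sample moments if the
  histogram fit fails; all-equal samples yield width 0 with a warning.
- Expected counts are capped at a configurable ceiling (default 10¹⁵)
  with a logged warning — an overflow guard, not a detector model.
- Empty scatterers produce an all-zero image; featureless images produce
  a failed retrieval (`converged=False`, `r_fit = NaN`), not an exception.
- Per-sample noise seeds derive from one run seed via `SeedSequence`, so
  ensembles are reproducible and individual samples re-simulable.

## Known limitations

- No detector quantum efficiency, gaps, tilts or point-spread function;
  no polychromatic beams; no radiation damage; single molecule per shot.
- AuNP–biomolecule chemistry (linkers, surface charge, conformational
  perturbation) is outside the model; the label is a rigid ideal sphere.
- The two-sphere fit floats no intensity scale or background by default
  (fluence and `R` are known exactly in simulation); an experimental
  pipeline would need both.
- Accuracy figures depend on the noise amplitude assumed for the uniform
  background (1 count/pixel), for which no measured value exists here.
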