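# Methods

`dnapmf` computes effective pair potentials `V_eff(r)` between two
coarse-grained DNA molecules — a 24-bp linear duplex or a 65-bp
torsionally relaxed minicircle — in 0.1 M NaCl or CaCl₂, using umbrella
sampling along the centre-of-mass (COM) separation and the weighted
histogram analysis method (WHAM), together with the conformational and
ion-atmosphere observables (orientation angles, RMSF, radial
distribution functions, coordination numbers) that rationalise how
topology and counterion valence shape the repulsion.

## Coarse-grained model

**DNA.** One bead per base pair carries the charge of both strands'
phosphates (−2 e) and has radius 1.0 nm, matching the ~2 nm B-DNA
diameter; the linear charge density (−2 e / 0.338 nm) therefore matches
double-stranded DNA. Linear duplexes are straight rods with the
B-DNA rise of 0.338 nm per bead and a neutral first bead, giving
−2 (n_bp − 1) e in total: a duplex with free 5′ ends has n_bp − 1
phosphates per strand, and this convention reproduces the charge balance
implied by the monovalent box composition (295 Na⁺ − 203 Cl⁻ = 92 e for
the pair, i.e. 46 e per 24-bp molecule). Minicircles are planar regular
n-gons of perimeter n_bp × rise with −2 e on every bead (−130 e for
65 bp). For an ideal rigid ring the radius of gyration equals the circle
radius, n_bp·rise/2π = 3.50 nm at 65 bp.

**Ions and box.** Explicit counterions (+1 or +2) and Cl⁻ co-ions in a
cubic periodic box of edge 15.0 nm. The inventory first neutralises the
DNA pair, then adds salt pairs for the target molarity computed from the
nominal cube volume: `n_anions = round(c · V · N_A)`, rounded **up** to
the nearest even integer for divalent salt so that CaCl₂ units are
integral (203.25 → 203 for NaCl, → 204 for CaCl₂; hence 295 Na⁺ / 148
Ca²⁺ for the linear pair). For the minicircle pair the same rule yields
463 Na⁺ / 232 Ca²⁺ from the builder's −130 e per ring. A published
composition for these boxes lists 459 Na⁺ / 230 Ca²⁺, which implies
−128 e per ring; the two-charge difference (probably one phosphate per
strand dropped during circularisation in the original structure
preparation) is deliberately not replicated: the builder computes from
its own charge model and the discrepancy is noted here. If the DNA
charge is not a multiple of the valence, the residue is absorbed by
adjusting a single counterion so every assembled ionic system is exactly
neutral.

Ions are placed by rejection sampling at least 0.5 nm from any DNA bead
and 0.35 nm from one another; the two molecules are parallel-oriented
(rod axes parallel, ring planes stacked) with COMs on the box z axis.

## Interactions

All energies in kJ/mol, lengths in nm, kT = R·300 K = 2.494 kJ/mol.

* **Bonds**: ½ k_b (r − r₀)² along each backbone (ring closure included),
  r₀ from the constructed geometry, k_b = 50 000 kJ/mol/nm² (stiff;
  bond-length fluctuations ~0.007 nm).
* **Bending**: ½ k_θ (θ − θ₀)² on consecutive triplets, θ₀ = π for rods
  and the polygon interior angle for rings. k_θ = 369 kJ/mol/rad²
  ≈ L_p kT / rise with L_p = 50 nm, the DNA persistence length.
* **Excluded volume**: WCA (LJ truncated at 2^{1/6}σ and shifted) with
  additive contact distance σ_ij = radius_i + radius_j; ions contribute
  `wca_sigma`/2 = 0.15 nm. Intramolecular WCA is excluded entirely —
  beads spaced 0.338 nm along the contour overlap hugely at 1 nm radius
  by construction, and chain geometry is maintained by the bonded terms.
  WCA acts between sites of different molecules and any pair involving
  an ion.
* **Electrostatics**: U = kT · l_B · z_i z_j · exp(−r/λ_D)/r between all
  distinct charged pairs, minimum image, with l_B = 0.7 nm (water,
  300 K). The default is λ_D = 0, i.e. *bare* Coulomb between the
  explicit charges: counterion condensation and release are the
  mechanism of interest and must emerge from the explicit ions rather
  than be absorbed into a mean-field screening length. A spherical
  cutoff at half the box edge with energy shift is applied in periodic
  boxes; the analytic two-particle tests disable it.

Water is implicit; there is no hydration-shell structure, no
sequence-specific geometry, no helical twist or grooves, and rings are
built torsionally relaxed (zero superhelical density).

## Sampling

A Metropolis Monte Carlo chain replaces molecular dynamics: only
equilibrium averages enter the analyses, and MC avoids timestep and
thermostat choices. One sweep performs a trial displacement of every ion
plus, per molecule, one single-bead displacement, one rigid rotation
about the COM and one rigid COM translation; each is accepted with
min(1, e^{−ΔE/kT}) where ΔE includes the umbrella bias
½ k (r − c)² on the COM separation (k = 5000 kJ/mol/nm² in the
production protocol, windows 2.0–7.0 nm every 0.1 nm). COM separation is
computed on unwrapped molecular coordinates — no minimum image along
the reaction coordinate — which is safe because the largest sampled
separation (7 nm) is below half the box edge. Move amplitudes are tuned
toward 30–50 % acceptance during equilibration and frozen for
production (tuning during production would violate detailed balance).
Every chain is bitwise reproducible from its seed; a pipeline's master
seed maps to per-window seeds as `seed + window_index`.

Default desk-scale budgets are 5·10³ equilibration and 5·10⁴ production
sweeps per window with stride 10. These are sized for tractable runs of
the full pipeline on one CPU, not for converged DNA physics; the test
suite uses smaller budgets still (e.g. 10⁴ production sweeps per window
for the two-bead oracle, ~500 sweeps for the condensation comparison),
stated where they are used.

## WHAM

Window histograms share one set of bins (default 0.05 nm over
[1.8, 7.2] nm, half the production window spacing, which resolves
sub-window-scale structure in the profile). The standard self-consistent
equations

    P(x_b) = Σ_i n_i(x_b) / Σ_i N_i exp[(f_i − w_i(x_b))/kT]
    exp(−f_i/kT) = Σ_b P(x_b) exp(−w_i(x_b)/kT)

are iterated with log-sum-exp evaluation (bias energies reach thousands
of kT at k = 5000) until max|Δf_i| < 10⁻⁷ kT, with at most 10⁵
iterations and the gauge fixed by f₁ ≡ 0. Disconnected window sets
(no shared occupied bin) and non-convergence are hard errors; a
non-monotone residual over the final iterations raises a warning.
`V_eff(r) = −kT ln P(r)` is referenced to zero at the bin containing
r = 7.0 nm (half-open bin convention; empty bins are flagged NaN, never
interpolated). **No radial-entropy correction** (2 kT ln r) is applied:
the profile is the standard distance-coordinate WHAM output, so for two
isolated particles it equals U(r) − 2 kT ln(r/r_ref) up to the reference
shift — the two-bead oracle test compares against exactly that
expression rather than subtracting the measure term. Uncertainties come
from a window-wise bootstrap (resample each window's series with
replacement, re-solve, per-bin standard deviation).

The estimation stage is packaged as a model/results pair: `WHAM`
(histograms + temperature) with `fit()` returning `WHAMResults`
(window free energies, unbiased density, `pmf()`, `overlap()`,
`bootstrap()`, `summary()`).

Numerical choices worth noting: the per-adjacent-pair overlap
diagnostic is the summed minimum of the two normalised histograms,
flagged below 0.05. At the production k = 5000 and 0.1 nm spacing, a
*rigid* two-particle toy gives only ~2 % overlap (the biased
distribution is 0.022 nm wide); real molecular systems are broadened by
internal modes. The analytic two-bead oracle therefore runs its ladder
at k = 250 (≈60 % overlap), where the junction-to-junction stitching
noise stays well below the 0.5 kT tolerance of the closed-form
comparison (measured recovery error ≤ ~0.26 kT); the harmonic-toy oracle uses exact Gaussian window sampling
and is independent of the MC sampler altogether.

## Trajectory analyses

* **Gyration tensor** S = (1/N) Σ r_i ⊗ r_i in the COM frame, unweighted
  (no mass factors). Eigenvalues sorted descending; eigenvector signs
  fixed by making the first nonzero component positive.
* **Orientation angle** θ = arccos |p₁ · p₂| ∈ [0°, 90°], where p_k is
  the eigenvector of molecule k's gyration tensor selected by `mode`:
  `largest` (long axis) for linear pairs, `smallest` (plane normal) for
  ring pairs. The mode is explicit because the two conventions describe
  different geometric questions; a circle's two in-plane moments are
  degenerate, so `largest` is flagged for rings. The absolute value
  folds the eigenvector sign ambiguity.
* **2D KDE** of (separation, angle) samples with a product Gaussian
  kernel; bandwidth defaults to Scott's rule per dimension
  (σ_d n^{−1/6}), grid 101 × 91 over [2, 7] nm × [0°, 90°], density
  normalised on the grid. Bandwidth and grid are package choices — the
  KDE is a visualisation aid, not a calibrated estimator.
* **RMSF** after optimal superposition (Kabsch, proper rotation
  enforced) of each frame to a reference on the selected sites; the
  fluctuation is taken about the *time-mean* aligned position, the
  standard convention — the reference only fixes the alignment frame.
* **RDF** g(r) of cation sites around DNA beads: minimum-image pair
  binning normalised by shell volume 4πr²Δr and bulk density
  ρ_B = N_B/V (finite-size convention; self pairs excluded for
  same-group curves, so an ideal gas integrates to N_B − 1).
  Coordination numbers integrate 4πρ_B g r² trapezoidally up to the
  first minimum after the first peak (automatic detection, overridable).
  The CG mapping collapses backbone-oxygen site classes onto the DNA
  bead; groove-specific sites have no CG analogue and are out of scope.

## What the synthetic systems do and do not show

The package's own generated systems are its only inputs. They emulate a
stiff charged pair with the correct topology, net charge and linear
charge density, explicit mono-/divalent counterions, thermal
fluctuations at 300 K, and restrained COM sampling on 2–7 nm. They do
**not** contain solvent structure, grooves, base sequence or atomistic
ion–DNA contact chemistry, so quantities that depend on those (PMF
magnitudes of order 100 kJ/mol at 2 nm, ~0.24 nm contact peaks,
groove-specific occupancies) are not reproduced at this scale, and
passing tests make no claim about them. What the tests do establish:
the builders' geometry and composition arithmetic is exact; the sampler
targets the correct biased Boltzmann distribution (KS test against the
closed-form biased density; per-kernel flux balance); the WHAM layer
recovers known free-energy profiles within stated tolerances end to
end; and the estimator suite (gyration, orientation, Kabsch/RMSF, RDF,
KDE) matches closed forms and independent oracles. The divalent-vs-
monovalent condensation comparison is reported qualitatively (logged by
the test suite, not asserted): at matched anion count the condensed
first-shell cation charge per DNA charge is higher for Ca²⁺ than Na⁺
in the minicircle-pair system.

## Known limitations

* Single-bead-per-bp resolution cannot resolve sub-nanometre ion–DNA
  structure; first-shell radii are set by the CG contact distance
  (~1.15 nm), not by atomistic chemistry.
* Bare Coulomb between explicit ions in a single periodic image (cutoff
  edge/2 with shift) neglects long-range periodic electrostatics; this
  is a deliberate trade against the complexity of Ewald summation and is
  adequate for the qualitative ion-atmosphere observables targeted here.
* The Metropolis chain's relaxation at the production force constant is
  slow for large systems; published-scale window budgets (50 ns MD
  equivalents) are far beyond the default desk-scale budgets, and PMFs
  from the full DNA systems at those budgets should be treated as
  under-converged.
* The WHAM bin width, convergence tolerance and gauge are package
  defaults, documented above, and not inferred from any external
  tooling's settings.
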