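# Methods

`smcsim` models how SMC complexes — extrusive and cohesive cohesin,
condensin I and condensin II — fold interphase chromatin into mitotic
chromosomes, and converts the resulting polymer ensembles into the
observables used to test such models: contact-frequency curves P(s),
binned-matrix feature scores, extrusion-speed estimates, and synthetic
fluorescence cross-sections.

## 1D loop extrusion (`extrusion1d`)

A chromatin fiber is a lattice of sites (1 site = 1 kb by default). A
loop-extruding factor (LEF) is a two-legged walker; extruding species move
both legs outward one site per active epoch, diffusing species (cohesive
cohesin) move each leg ±1 with equal probability. Species differ in:

| parameter | meaning | defaults used in scenarios |
|---|---|---|
| λ (processivity, kb) | mean chromatin extruded before unbinding; ∞ = stays bound | cohesin 100, condensin II ∞, condensin I 800 |
| d (separation, kb) | mean genomic spacing; copy number = ⌊chromosome/d⌋ | cohesin 300, condensin II 700, condensin I 50 |
| step interval (epochs) | encodes speed ratios; cohesin 10 kb/min vs condensin 120 kb/min → 12 : 1 | |
| barrier mode | capturable species are captured with the site's probability (CTCF: 0.9) when stepping onto a barrier; captured legs do not move until unbinding | cohesin capturable, condensins transparent |

One epoch corresponds to 1 s of real time in the prophase scenario (a
condensin leg advances 1 kb per epoch at 120 kb/min).

Unbinding is sampled per active epoch with probability
(kb moved per epoch)/λ per complex, so the mean extruded length in the
absence of obstacles equals λ. Unbound finite-lifetime complexes rebind at
a random free site in the same epoch (pool conserved); a `rebind=False`
switch models net loss instead. Complexes are updated sequentially in a
seeded random order each epoch (avoids directional artifacts; the
scheduling of the original parallel implementation is not reproducible at
the lattice level, and none of the reported observables depend on it).

Collisions are resolved by a policy matrix keyed by (moving, blocking)
species: **stall** (move rejected), **bypass** (the leg steps over the
contiguous run of occupied sites to the first free site), **push** (the
contacted run of legs is displaced one site; a complex with adjacent legs
moves as a unit; a push against a chain end or a captured leg unloads the
contacted complex), **unload** (the blocking complex is removed and, if
its species rebinds, reloads at a random free site). Same-species
collisions stall, as for condensin–condensin and cohesin–cohesin; a
`self_default` override exists for theory checks (below).

**Gap fraction.** The mean-field estimate g = e^(−λ/d) for the uncovered
fraction of chromatin treats extruders as independent (Poisson coverage).
With the stall rule the engine's steady-state gaps exceed the estimate
(≈0.44 vs 0.368 at λ/d = 1) because collisions truncate loop growth; with
non-interacting legs (`self_default="bypass"`) the engine matches the
formula within sampling error at λ/d ∈ {0.5, 1, 2}. The property tests run
the formula check in the regime where its assumption holds; the stall-rule
deviation is expected behavior, not an error.

## Polymer engine (`polymer3d`)

Reduced units: 1 length unit = one bead diameter (10 nm at 200 bp/bead;
coarser beads scale as the cube root of their genomic content, keeping the
volume per bp fixed), energies in k_BT, T = 1. Forces: harmonic bonds
(k = 10, L0 = 1 for chain, loop-anchor and LEF bonds; gap-stretch bonds
with L0 = n_gap + 1), angular stiffness E = k(1 − cos θ) with k = 1.5, a
soft DPD-style repulsion F = A(1 − r/r_c) with A = 3, r_c = 1 (which
permits strand passage, so loop arrays equilibrate topologically),
cylindrical Gaussian-wall confinement with caps, an axial exclusion
("spool") for backbone beads implemented as a quadratic ramp of height
6 k_BT inside radius 2, end-pull forces, constant lateral forces for
cohesion pins, and harmonic azimuthal restraints about the cylinder axis
(the torsional quadruplets through immobile axis ghosts reduce exactly to
azimuthal restraints on the pinned beads).

The reference integrator is overdamped Langevin (Euler–Maruyama) with
dt = 0.02 and γ = 1. The production-scale studies use an inertial DPD
thermostat at dt = 0.05; an overdamped explicit update is only stable
while k_max·dt/γ < 2 and the stiffest chain mode of k = 10 bonds sits at
4k·dt, so the reference engine runs below that boundary. The thermostat
affects kinetics, not the equilibrium ensemble that the in-silico Hi-C
consumes. Neighbor pairs are rebuilt every 5 steps with a 0.5-unit skin;
coordinates beyond 10^6 abort with a diagnostic.

The density quoted for prophase models, 0.224 monomers per cubic
nanometer, is read as 0.224 beads per cubic reduced-length unit, i.e. per
(10 nm)^3 — a literal nm^−3 is impossible for 10 nm beads, and the reduced
reading is consistent with the (16.5 nm)^3-per-nucleosome volume used for
the mitotic models.

## Mitotic chromatid builder (`mitotic_builder`)

Free parameters: mean loop size l_loop (exponentially distributed sizes),
gap L_gap (nm) between consecutive loop anchors, and linear density ρ_L
(Mb/μm) or equivalently pitch P; measured parameters: turn length l_turn
(Mb, from the Hi-C second diagonal) and volume density ρ_V (Mb/μm³, from
electron microscopy); σ_C (nm) enters only at the contact step. Derived
geometry: L_cyl = l_chrom/ρ_L, R_cyl = √(l_chrom/ρ_V/L_cyl/π),
P = l_turn/ρ_L, N_loops = l_chrom/l_loop, L_bb = N_loops(L_gap + L_bond);
cylinder dimensions are inflated so the wall potential equals 0.3 k_BT at
the target surface (compensating the bounding-potential overshoot).

Loop sampling truncates the final loop at the chromosome end (exact length
conservation; bias negligible for ≥100 loops). Gap beads are
n_gap = round(L_gap / nm-per-bead). Anchors are the beads containing the
anchor bp (floor division); coordinates are 0-based half-open. The helix
phase is 0 at the chromosome start.

Initial conformations: helical models place backbone beads (anchors + gap
beads) on a regular helix of the derived pitch at radius R_cyl/2 — the
centerline of a helically wound tube that fills the cylinder cross-
section; a geometric argument fixes the lower bound, since loci one turn
apart (separation = pitch) are only closer in space than loci half a turn
apart when the helix radius exceeds ~0.44 pitch, and below that no second
diagonal can form.  Loop interiors are Brownian bridges between their
anchors, reflected into the cylinder. Stretched models build the backbone as a
random walk of Kuhn segments bridged to the box length along z. The Kuhn
length is set to the bottlebrush main-chain stiffening scale
ℓ_k = R_brush²/b, with R_brush = √(λ_beads/(π ρ)) the corona radius from
the volume density: a dense brush cannot bend below the thickness of its
own corona, and at desk scale this large-scale statistic must be built
into the construction because it cannot emerge within an affordable
relaxation (see "Desk scales" below).

## In-silico Hi-C (`insilico_hic`)

Contacts use the Gaussian-perturbation scheme: every bead is shifted by an
isotropic Gaussian of sd σ_C per axis (σ_C in nm, converted to reduced
units), pairs within 1.1 length units are recorded, and frequencies are
averaged over replicates (default 100; desk scenarios use 30 perturbation
replicates and average P(s) over independently sampled, constructed and
relaxed loop-array replicates — three for the helical model, five for the
stretched one). P(s) uses 128 geometric bins per decade
over 1 kb–1 Gb; the observed-contact numerator and the all-pairs
denominator are smoothed separately with a Gaussian kernel of width 0.03
in log10 s before the ratio. The log-derivative uses central differences
on the smoothed curve.

The loop-size estimator multiplies the derivative-peak position in
[10 kb, 2 Mb] by a left-offset calibration constant 0.48, calibrated once
against builder models with known 100/200/400 kb loops (in a dense array
the derivative peak sits right of the mean loop size; the offset is stated
but not derived in the source analyses). The second diagonal is the first
P(s) local maximum above 2 Mb with a prominence of at least 10^0.5 (~3.2×)
in log10 — helical second diagonals rise an order of magnitude above their
troughs while single-chromosome sampling wiggles stay below ~2–3×, so this
floor separates signal from noise at desk-scale statistics; no qualifying peak
returns a "none" sentinel (e.g. condensin I-only models). The model-fit
metric normalizes both curves to 1.0 at the 3 kb bin and takes the RMS of
log10 differences over 3 kb–40 Mb.

For simulated single-chain chromosomes the experimental "arms > 100 Mb"
guard is dropped, and no matrix balancing is applied (coverage is uniform
by construction). For periodic-box models the box maintains melt density
during relaxation, but cis contacts are computed on unwrapped coordinates:
minimum-image contacts would register image neighbors (different copies of
the chromosome, i.e. trans in reality) as cis.

## Matrix feature scores (`hic_features`)

Observed/expected divides each diagonal by its mean. The compartment
eigenvector is the leading eigenvector of OE − 1 on unmasked bins, sign-
oriented to a reference track. Saddle strength sorts bins into 10 groups
by eigenvector value after trimming the 2.5/97.5 percentiles and returns
(AA + BB)/(AB + BA) using the single extreme group per corner ("corner
pixels" read in the simplest way; configurable). Dots are deduplicated by
connected components within a 30 kb radius; dot strength is the mean of
the central 3×3 pixels of the averaged OE pileup (±50 kb flank).
Insulation is the diamond mean over a 200 kb window in log2 relative to
the chromosome mean; boundary strength is the prominence of the insulation
minimum (the upstream tool's definition is not restated in the source, so
prominence — depth relative to the lower flanking maximum — stands in for
it, with the 0.1 threshold retained), and TAD pileups rescale ±size
snippets of 100–700 kb inter-boundary domains to 100×100 and average.
All scores are invariant to global matrix rescaling.

## Speed and stoichiometry estimators (`kinetics`)

Closed forms: loop/(60·min); (l1 − l0)/(60·min); −d·ln g/t (inverse of
g = e^(−vt/d)); k·l_loop/t for the gap-closing multiplier k ≈ 4–5;
(p1 − p0)/min for helical period growth; loop/residence for the effective
velocity; the Rouse calibration steps-per-minute = rouse_md_steps /
rouse_minutes divided by extrusion events per minute (two legs per event);
cube side (bp_per_nucleosome/ρ_V)^(1/3) with exact unit handling; and the
ChEP stoichiometry ratio × 2·10⁶/180 H4 per Mb. Full-precision values are
returned; display rounding (one decimal for kb/s) is a separate helper.
The 100–200 kb / 2.5 min loop-growth bound evaluates to 0.67–1.33 kb/s,
printed in the source as "0.5–1.3"; the exact value is returned.

## Synthetic fluorescence profiles (`imaging_profiles`)

Each chromatid's spine is the shortest path (edge count; Euclidean weights
optional) through its bond graph plus bridges at condensin positions, so
the path runs along the condensin scaffold. Spine monomers of the two
sisters are paired by mutual nearest neighbors; each pair defines a
section line (origin = midpoint). Monomers are assigned to the section
minimizing their perpendicular rejection and their signed projections are
histogrammed (0.5-unit bins, unweighted counts). Width at half maximum
interpolates the outermost half-max crossings. Scaffold dispersion is the
SD of condensin-bead radial distance about the chromatid axis (0 for a
perfect scaffold; R/√18 for condensins uniform across a disc of radius R).

## Scenarios and desk scales (`scenarios`)

The production-scale systems (100 Mb at 200 bp/bead ≈ 5·10⁵ particles on
GPUs) are reproduced at desk scale with the dimensionless ratios
preserved:

* **prophase_collision** — 20,000-site lattice (scale factor available),
  the verbatim 125-site CTCF list at 90% capture, cohesin λ=100/d=300
  every 12th epoch, condensin d=700 synchronous every epoch; 3,000 epochs
  of G2 equilibration, 1,800 epochs (30 min) of prophase. Output: CTCF–
  CTCF-anchored cohesin counts normalized to G2 — the proxy for dot
  strength.
* **cohesion_sisters** — two 1.2 Mb sisters at 1 kb beads, condensin I
  (λ=800, d=50) and diffusing cohesive cohesins bridging the sisters
  (d=200 at this reduced chain length, preserving several bridges per
  chain); the 1D loop array is pre-equilibrated before coupling, then 1D
  epochs alternate with Brownian dynamics in good solvent; profiles from
  the last 10 conformations.  Within the desk budget the sisters separate
  but do not fully demix, so the diagnostic contrast is the placement
  reversal: under bypass cohesin is displaced off the (well-separated)
  condensin axes toward loop tips at the interface, under stall condensins
  stall at the cohesive links and the pair shares one axis with cohesin on
  it.  The fully formed three-peak cross-section of production-scale runs
  is not reproduced at this size.
* **condensin2_only** — 50 Mb at 4 kb beads: 400 kb loops, 80 nm gaps,
  400 nm pitch, l_turn 17 Mb, ρ_V 44 Mb/μm³, σ_C 48 nm.
* **condensin1_only** — 30 Mb at 1 kb beads: 100 kb loops, 20 nm gaps,
  ρ_L 25 Mb/μm, ρ_V 77 Mb/μm³, σ_C 48 nm, periodic box.
* **nested / overlapping / cohesion_effect** — the two-layer model
  (root 400 kb / nested 100 kb, l_turn 10 Mb, ρ_V 77), the independently
  placed 900 kb loop model (one per 360 kb, azimuthal anchor pins), and
  the helical model with cohesion sites at 1/Mb relocated to loop
  midpoints and pressed sideways at 0.1 k_BT/nm.

**What desk scale does and does not show.** The chromatid models are
relaxed for the shortest budget that equilibrates bead-scale structure —
bond-length statistics plateau within a few hundred Brownian steps, and
the scenarios use 1,000–1,500 steps. This equilibrates local liquid
structure but not whole-chromosome scales; large-scale statistics
(helical winding, brush-axis random walk) are therefore built into the
initial construction and only locally relaxed. Relaxing further at desk
scale progressively replaces the constructed brush-axis statistics with
the finite-size equilibrium of the miniature system (swollen loops, a
flatter P(s)); the production-scale behavior is recovered by construction,
not by equilibration.

A specific thin-corona artifact affects the stretched model's P(s) tail:
at 1 kb beads the loop corona is only ~6 length units thick (vs ~40 at
production scale), so chance close approaches of backbone segments many Mb
apart contribute spurious long-range contacts that flatten the 2–8 Mb
decay.  Replicate averaging damps but does not remove this, and the
measured desk-scale slope sits around −1.25 to −1.35 rather than −1.5;
the shortfall shrinks with finer beads and vanishes at production bead
counts. A fully equilibrated desk-scale brush would
also differ from the production model: with 50–100-bead loops the corona
is only a few beads thick, so the excluded-volume swelling of loops
(unscreened at these short effective chain lengths) inflates short-range
distances relative to the production system, flattening P(s). Passing
desk-scale tests therefore demonstrates that the implemented rules and
converters reproduce the production-scale observables when the
construction supplies the large-scale statistics — not that a 30 Mb
system at 1 kb beads would evolve those statistics on its own.

The synthetic fixtures (planted checkerboards, dots, TAD blocks) contain
no distance-decay noise model beyond optional lognormal jitter and no
mappability artifacts; feature-score tests on them validate arithmetic,
not robustness to experimental noise.

## Numerical choices

* LEF copy numbers round down (⌊total/d⌋); documented and tested.
* Barrier capture is tested for each traversed site on the step that
  would cross it; barriers are bidirectional.
* Zero-size loops (legs on one site) are excluded from 3D LEF bonds.
* P(s) bins with zero possible pairs are NaN and excluded from slopes.
* Peak prominence 2% of local value; fit-metric normalization falls back
  to the nearest valid bin within half a decade of 3 kb.
* Eigenvector sign with zero-variance input returns all-zeros, flagged.
* The acceptance script derives all seeds from `--seed` (kept below 2³¹).

## Known limitations

* The reference integrator targets ≤ ~3·10⁴ beads; no GPU backend.
* Desk-scale P(s) curves are noisier than production ones (single
  chromosome, 30 replicate perturbations vs 100, three snapshots vs three
  independent replicate simulations).
* The unload/push prophase scenarios conserve the cohesin pool by default
  (continuous loading); the no-rebind interpretation is a switch.
* No point-spread-function convolution in synthetic profiles; no
  balancing or mappability filtering of matrices.
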