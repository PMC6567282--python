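# Methods

`cdlattice` models the thermodynamic stability and equilibrium crystallite
shape of cubic-diamond (CD) superlattices assembled from DNA-origami
tetrahedral cages and DNA-grafted nanoparticles (NPs).  This note records
the model, the numerical choices, and the limits of what the desk-scale
computations show.

## Coarse-grained model

All quantities are in reduced Lennard-Jones units (length sigma ~ 0.65 nm,
temperature in eps/kB, every force site has mass 1, so body masses are site
sums: 621 for an NP with its 20 linkers, 175 for a cage with 4).

**Tetrahedral cage.**  A rigid tetrahedral frame: each of the six edges is a
chain of seven 9.9-sigma beads bonded at rest spacing 7.32 by stiff FENE
bonds (kb=240, R0=1.5, eps=8, Delta=6.36), with second-neighbour FENE bonds
(Delta=13.67) enforcing straightness.  Corners are truncated: the outermost
beads of the three edges meeting at a corner are tied together, three small
truncated-vertex beads sit beyond the corner, and a single anchor bead (the
first nucleotide of the vertex linker) lies on the corner axis, tethered to
the 40-sigma central sphere (Delta=36.52) that represents the caged NP.
The corner placement is fixed by requiring every corner bond to sit exactly
at its FENE rest length; this has a unique solution with the vertex
triangle rotated ~66 degrees off the edge tangents (the cage is therefore
chiral, which has no dynamical consequence).  The truncated-vertex beads
are linker-scale (diameter 1): large beads there would close the channel
the DNA strand threads.  The frame beads and the central sphere of the same
cage overlap by construction and carry no mutual non-bonded term.

**Nanoparticle.**  Twenty 1-sigma vertex sites at the corners of a regular
dodecahedron of circumscribed diameter d (40-120), plus a central site, all
FENE-bonded (center-vertex Delta = d/2 - 0.96, vertex-vertex Delta =
d/2.8 - 0.96).  The central site's excluded volume is the inscribed sphere
(diameter 0.7946 d).  One linker per vertex; the first four vertices form
the cube-diagonal tetrad that faces the four cage neighbours in the lattice.

**DNA.**  Two sites per nucleotide (backbone + base), standard FENE bonds
(kb=30, R0=1.5, eps=1).  Each linker has seven inert spacer nucleotides and
an eight-base sticky end; the cage sequence 5'-GCGCAGTC and its reverse
complement GACTGCGC on NPs make cage-NP the only hybridizable pair, with
neither 8-mer self-complementary.  Non-bonded repulsion is the expanded WCA
potential with core shift Delta_ij = (d_i+d_j)/2 - 2^(1/6), truncated and
shifted to zero at surface contact + 2^(1/6).  The only attraction is a
cut-shifted Lennard-Jones well between complementary bases of distinct
strands (cutoff 2.5).  Its depth eps_bp is the one free parameter of the
force field: the reference two-site DNA parameterizations fix it only
implicitly, so it is calibrated by a two-strand melting scan - an isolated
8-mer duplex must stay bound at the lattice working temperature T=0.09 and
melt by T=0.30.  Any depth in [0.6, 1.0] satisfies this; eps_bp = 0.8 is
the default and the calibration is part of the test suite.  A single angle
potential ka(1+cos theta) orients each linker radially outward at its
graft and stiffens consecutive backbone triplets, making ka (0.5-2.0, the
experimental salt-concentration proxy) the single flexibility knob shared
by cage and NP linkers.

**Lattice.**  The CD lattice is two interpenetrating FCC lattices (NPs at
cell origins, cages at b/4*(1,1,1)) in a triclinic box with equal edges and
60-degree angles.  All cages share one orientation and NPs the opposite, so
every cage linker points at a nearest-neighbour NP.  Every
nearest-neighbour link is built pre-hybridized: the two facing strands run
antiparallel on lines +-1.5 sigma off the link axis (ramped over the spacer
region), sticky bases in registry at the pair-well minimum.  The lattice
constant b is set so these links are at rest
(b = 4/sqrt(3) * (anchor radius + d/2 + 22*0.96) ~ 181.6 sigma at d=40),
rather than under-sizing by 10% and relying on the barostat; the P=0 runs
then start stress-free.  Slabs reuse the same construction with in-plane
periodicity only; the (111)/(110) termination is chosen to sever one bond
per surface body (the alternative (111) cut severs three), and (100) slabs
are cage-terminated on both faces, which for strict layer alternation means
an odd layer count.

## Simulation

Velocity-Verlet with timestep 0.003; Langevin (BAOAB) thermostat by
default or a single Nose-Hoover chain, damping 1.0; zero-pressure runs use
a weak-coupling isotropic barostat (damping 3.0, per-step strain capped at
2e-4) that preserves the triclinic angles.  Neighbour lists are Verlet
lists with per-pair shifted cutoffs (mandatory given the 1-40 sigma size
disparity) and 0.3-sigma skin, rebuilt on a half-skin displacement
trigger; non-bonded terms are excluded for site pairs within three bonds
and for cage frame-core pairs.  Lattice preparation follows the two-step
protocol: a single tethered primitive cell is equilibrated until all four
links are hybridized, then replicated unwrapped and relaxed at P=0.
Hybridization bookkeeping (>= 4 of 8 complementary base pairs within 1.5
sigma) is diagnostic only.  Desk-scale runs are 10^4-10^5 steps on 1-16
bodies; the published protocol (4x10^8 steps, 64+64 bodies, d up to 120)
is accepted by the same code paths but is cluster-scale.

## Analyses

**Surface energy and shape.**  The broken-bond model counts severed
nearest-neighbour links per unit area on an in-plane-periodic supercell;
minimal terminations give per-area ratios
gamma_100 : gamma_110 : gamma_111 = sqrt(3) : sqrt(6)/2 : 1 (1.7321 and
1.2247).  The slab estimator gamma = (<E_slab> - <E_bulk,matched>)/(2A)
rescales the bulk reference to the slab composition and block-averages the
uncertainty.  The Wulff construction intersects half-spaces at distances
gamma_hkl over the full 48-element cubic point group
(scipy HalfspaceIntersection), reports per-family area fractions (facets
below 1e-6 of the area are dropped), and scans gamma_100/gamma_111 by
bisection (tolerance 1e-4) for the cube-only and octahedron-only
thresholds.  With gamma_110/gamma_111 held at the printed 1.22, the
cube-only threshold is 1/sqrt(3) = 0.5774 while the {100}-vanishing
threshold is sqrt(2)*1.22 = 1.7253 rather than sqrt(3): 1.22 lies below
the octahedron corner support sqrt(3/2) = 1.2247, so the (110) planes
already shave the corners (and edges) slightly.  At the exact broken-bond
ratio the threshold is sqrt(3).

**Structure factor.**  S(q) = (1/N) sum_{j!=k} exp(-iq.(r_j-r_k)) over
both species' body centers (the partial per-species S(q) is available),
evaluated only at box-commensurate wavevectors and shell-binned with width
= smallest reciprocal spacing / 4, which resolves the (711)/(642) doublet
near q/q0 = 4.2 at 4^3 cells.  Ideal CD frames show peaks exactly at the
diamond-allowed reflections (h,k,l all odd, or all even with h+k+l = 0 mod
4); i.i.d. Gaussian disorder damps the coherent peak weight by
exp(-q^2 <u^2>/3), which is how stiffness (through <u^2>) limits the
largest indexable q/q0.

**Lattice dynamics.**  Body-center displacements are mass-weighted,
Fourier-transformed over cells, and the 6x6 equal-time covariance per
wavevector is pseudo-inverted to D(q) = kBT <w w^+>^-1 (acoustic nulls at
the zone center map to zero frequencies); mass-weighting is required for
the eigenvalues to be omega^2.  The analytic reference is the minimal
spring model - radial kr on the four nearest-neighbour links and angular
ktheta (energy (1/2) r0 ktheta dtheta^2, so ktheta carries a 1/r0 unit
factor) on bond-angle triplets - whose dynamical matrix is built from
internal-coordinate Jacobians on a supercell (exact Gauss-Newton Hessian
at equilibrium, verified against finite differences).  A 4^3 lattice gives
four commensurate wavevectors along each of (100) and (111); with the
transverse pair degenerate and the zone-center shared, 13 unique points
constrain the (kr, ktheta) least-squares fit.  The classical harmonic free
energy per cell is kBT <sum_l ln omega_l(q)> on a half-step-offset 16^3
Brillouin-zone grid (converged to <0.1% against 32^3); only differences
between systems at equal T are reported, so the hbar-dependent constant
cancels.

**Vibration amplitudes and entropy.**  <u^2> is site-referenced (variance
about the mean position); the multi-origin time-lag curve saturates at
twice that value and is halved when read off.  The rotational observable
is the per-vertex angle between time-lagged center-to-vertex vectors,
averaged over all vertices (the published "chosen vertex" is averaged
here); for isotropic small rotations its lag plateau is 4/3 of the body
rotation-vector variance <phi^2>, and the reported <phi^2> applies that
factor, so krot = 3kBT/<phi^2> round-trips exactly on surrogates.  Plateau
windows are auto-detected (last half of the curve with log-log slope
< 0.05) and overridable; drifting trajectories yield a warning and no
plateau.  The independent-oscillator decomposition uses
dS_trans = (3/2) kB [ln(u^2/u^2_ref)_NP + ln(.)_cage] and the same form
for rotations per species; the T d<u^2>/dT correction term is dropped on
the strength of the linear-in-T amplitude check, which is exposed as the
`temperature_linearity` diagnostic.  dE is the difference of mean
potential energy per primitive cell; dF = dE - T dS.

## Synthetic-data generators

The surrogates emit exactly the statistical structure the estimators
assume and nothing more: Gaussian lattice vibrations with equipartition
mode amplitudes (frames i.i.d. by default - the dynamical-matrix estimator
uses equal-time covariances only - with an OU-correlated mode for plateau
detection), independent rigid-body rotations with per-species stiffness or
a shared hybridization-arc constraint <phi^2> = (2s/d)^2, and
perturbed-ideal frames for S(q).  They contain no anharmonicity, no
diffusion, no defect formation and no melting, so surrogate-based tests
validate the estimators and the entropy bookkeeping, not the realism of
the force field; the reduced-scale MD runs close that gap qualitatively.

For study sweeps the generator defaults emulate the reported qualitative
amplitude trends with smooth one-parameter laws:
u^2 = u2_ref (d/40)^(1/4) (0.5/ka) with u2_ref = 10 sigma^2 (rms ~ 1.8% of
the lattice constant, comfortably below melting), and a shared arc
s = 5 sigma (d/40)^(1/4) sqrt(0.5/ka), so NP rotations tighten and cage
rotations loosen as d grows, translations stabilize (dS_trans > 0) while
NP rotations dominate and destabilize, and stiffness enters as a pure
multiplicative shift - re-referencing each ka to its smallest-NP system
collapses the size dependence exactly.  kr = ka and ktheta = 0.1 ka map
stiffness onto the spring model.  The quarter-power exponents are a
deliberate minimal choice satisfying the observed inequalities (any
exponents alpha, beta with alpha < 1/2, 3 beta + 6 alpha < 3 would do);
they are conditions of the study, not fitted quantities.

## Reorientation bonding at desk scale

Surface bodies on (100) facets can rotate and hybridize their dangling
linkers with unused strands of interior NPs, lowering gamma_100 below the
broken-bond value when linkers are flexible.  This is an activated,
collective process: a surface cage must reorient against two intact
links.  The short slab runs used here (10^4-10^5 steps versus 4x10^8 in
the full protocol) essentially never nucleate it, so the stiffness trend
in reorientation-bond counts is asserted non-strictly, and the
reduced-scale gamma_100/gamma_111 estimate - scored through the counting
relation sqrt(3)(2 - r)/2 with r the reorientation bonds per surface
cage - sits at the broken-bond limit for all ka.  Demonstrating the
quantitative gamma_100(ka) curve requires the full-scale protocol.

## Known limitations

* The base-pair well reproduces the functional role of hybridization
  (specific, thermally reversible), not any sequence thermodynamics; at
  most one partner per base is enforced by excluded volume, not
  bookkeeping.
* The weak-coupling barostat samples a slightly distorted isobaric
  ensemble; for the quasi-harmonic lattices studied here only the mean
  cell matters, and the toy-crystal test pins it to within 1% of the
  stress-free constant.
* The dynamical-matrix free energy is classical and harmonic; approaching
  the melting temperature invalidates it.
* DNA length, cage-size variation, explicit salt, and optical properties
  are outside the model's scope.
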