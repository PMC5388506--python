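# Methods

## System and geometry

The system is an idealized stack of two (GAGAGAGQ)₁₀ β-roll molecules,
one bead per residue at the Cα position, 160 beads total. Each molecule
winds ten 8-residue repeats through two parallel β sheets: the six
G/A-alternating residues of a repeat form a strand, and the trailing
G–Q pair forms the turn that carries the chain to the other sheet.
Odd-numbered strands run +x in the bottom sheet, even-numbered strands
run −x in the top sheet. Residue indices are 1-based and global
(1–80 bottom molecule, 81–160 top).

Geometry defaults (Å): 4.85 between adjacent strands of a sheet, 5.0
between the two sheets of a roll, 5.0 between the stacked molecules,
3.4 per-residue rise along a strand. Two deliberate regularities make
the build exactly commensurate with a per-class contact model:

* top-sheet strands carry a uniform lateral slant of one strand spacing
  per strand, so the turn bridges on the +x and −x sides span identical
  3D gaps and every turn-flanking vertical pair has the same native
  distance (5.0 Å);
* each turn is a symmetric two-bead bulge placed so its two bonds have
  exactly the strand bond length, putting one turn bead near each sheet
  plane ((sheet gap − bond)/2 = 0.8 Å away); the inter-molecule
  turn-to-turn pairs then all share one native distance (6.6 Å).

As a result every omega/lateral pair sits at 4.85 Å, every vertical
intra pair at 5.0 Å and every vertical inter pair at 6.6 Å in the
build, all native bond/angle/torsion references are taken from the
build, and the ideal stack is an exact stationary point of the energy
(zero force to machine precision). The build validates at construction
time that all Ω pairs lie inside the 4.0–6.0 Å window and rejects
geometries that violate it, listing the offending pairs.

The restraint selection ("partial template") anchors, for each
bottom-sheet strand of the bottom molecule, the base glycine at each of
its two turn ends: the in-turn glycine on the +x side (z = 0.8 Å) and
the strand-start glycine on the −x side (z = 0). That gives 10 glycine
beads at the bottom of the turns on both sides of the roll. With a
two-residue G–Q turn the chain enters +x turns from the bottom and −x
turns from the top, so the bead at the bottom of a turn alternates G/Q
between the two sides; one of the ten anchors per side is therefore a
strand-base rather than in-turn glycine. 

## Energy model

Gō-like: attractive interactions exist only for the native contact
classes of the build.

| term | form | default |
|---|---|---|
| bond | k_b (r − r₀)², native r₀ per bond | k_b = 20 kcal·mol⁻¹·Å⁻² |
| angle | k_a (θ − θ₀)², native θ₀ per angle | 20 (strand) / 10 (turn) kcal·mol⁻¹·rad⁻² |
| torsion | k_d (1 − cos(φ − φ₀)) | k_d = 1 kcal·mol⁻¹ |
| contact | ε[5(r₀/r)¹² − 6(r₀/r)¹⁰] | ε = 1.5 / 0.75 / 1.2 kcal·mol⁻¹ (lateral / vert-intra / vert-inter) |
| excluded volume | ε_ev[(σ/r)¹² − 2(σ/r)⁶ + 1] for r < σ | σ = 3.0 Å, ε_ev = 1 kcal·mol⁻¹ |
| restraint | k Σ|r − r_ref|² | k = 10 kcal·mol⁻¹·Å⁻² |

Notes on the less obvious choices:

* The well-depth hierarchy (lateral strongest, inter-molecule close
  behind, intra-turn weakest) is a model *input* encoding the measured
  hydrogen-bond ordering; recovering it from trajectories is then a
  pipeline test, not a discovery.
* k_b = 20 pairs with the 10 fs timestep: the lightest bead (glycine,
  57 amu) gives a bond period of ≈37 fs, and the zero-friction
  integrator conserves energy to ~10⁻³ relative over 10⁴ steps. A
  stiffer 100 kcal·mol⁻¹·Å⁻² bond has a ~17 fs period and is unstable
  at this timestep.
* Angles are harmonic in θ even though strand references are collinear
  (θ₀ = π): the gradient's 1/sin θ is guarded, which is benign because
  the force magnitude 2k(θ−θ₀) vanishes together with sin θ there. A
  cosine-harmonic form was tried first and rejected: it is quartically
  soft around collinearity, and the under-braced lattice swelled until
  the baseline Ω band was lost.
* Turn angles are softer than strand angles (turns are the flexible
  element of the fold). 10 kcal·mol⁻¹·rad⁻² keeps the unboosted
  baseline inside the stable band across seeds over 10⁵-step runs;
  5 kcal·mol⁻¹·rad⁻² occasionally let a terminal strand peel at 300 K.
* Proper torsions are defined only over quadruples whose reference bond
  pairs are non-collinear — the turn regions (56 torsions in the
  stack). Strand-interior quadruples are exactly collinear in the ideal
  geometry, where a torsion angle does not exist. These turn torsions
  supply the nonzero dihedral energy channel the dual boost requires.
* Excluded volume skips 1-2 and 1-3 neighbours and native contact
  pairs; the closest non-excluded pair in the build sits at 5.0 Å,
  safely outside σ = 3.

Masses are per-residue (G 57.05, A 71.08, Q 128.13 amu);
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹; force-to-acceleration conversion
418.4 Å·ps⁻² per (kcal·mol⁻¹·Å⁻¹)/amu.

## Dynamics

BAOAB splitting of Langevin dynamics (velocity Verlet in the
zero-friction limit), dt = 10 fs, friction 1 ps⁻¹, 300 K,
Maxwell-Boltzmann initial velocities. One seeded generator drives
initialization and noise; identical seeds reproduce trajectories
bitwise. Conventional runs log per-frame energy decompositions and
report post-equilibration time averages of V_total and V_dihedral with
naive standard errors over logged frames (no block averaging; the
averages feed the boost prescription, where their few-tenths
kcal·mol⁻¹ uncertainty is immaterial against α values of 32–112).

## Dual boost

Boost energy ΔV = (E − V)²/(α + E − V) below threshold E, zero at and
above it; the boosted force is the unboosted force times
α²/(α + E − V)². Both are continuous at V = E, keep V ≤ V* ≤ E, and
preserve the ordering (hence positions) of minima. Prescription from
cMD averages: E_dih = V̄_dih + 3.5·N_res, α_dih = 3.5·N_res/5,
α_tot = 0.2·N_atoms, E_tot = V̄_tot + n·α_tot. N_res and N_atoms both
count the 160 beads of the CG stack and are logged with every run.

Composition: the dihedral boost is applied first and folded into the
boosted total; the magnitude and threshold test of the total boost use
the raw total energy (its defining formula is a function of V_total).
The chain rule then scales non-dihedral forces by f_t and dihedral
forces by f_d + f_t − 1. The alternative convention — thresholding the
dihedral-boosted total, with dihedral forces scaled by f_t·f_d — is
implemented behind `threshold_on="dihedral_boosted"`. The raw-total
reading is the default for a desk-scale reason that is easy to verify:
the CG dihedral energy is bounded above by 2·k_d per torsion
(112 kcal·mol⁻¹ total) while E_dih sits ≈560 above the average, so
ΔV_dih never falls below ≈380; under the alternative convention the
dihedral-boosted total therefore sits permanently above
E_tot = V̄ + n·α_tot (n·α ≈ 64–80), the total channel never engages,
and the threshold multiplier n — the experimental design variable of
the three regimes — has no effect at all. Under the default the three
regimes separate as designed (mean ΔV_total grows with n).

A note on scale: in the atomistic original, both prescription constants
act on systems with solvent-scale atom counts and per-residue dihedral
content ~3.5 kcal·mol⁻¹; on 160 beads the dihedral channel is
essentially fully flattened (f_d ≈ 0.03) and the total channel
fluctuates around its threshold. The qualitative design — boosted runs
unfold, unboosted runs do not — carries over; the quantitative plateau
timings of the atomistic study do not, and are out of scope.

## Scripted unfolding generator

The generator emulates staged, mainly-C-terminal unfolding without an
engine: each plateau level L is realized exactly by peeling 64 − L
residues of the top molecule into straight extended tails (3.8 Å per
residue) anchored at the first unpeeled residue — the default peel
order takes the first 8 from the N terminus and the rest from the C
terminus — plus Gaussian positional noise (0.1 Å) on every bead each
frame. The default schedule holds plateaus at Ω = 52, 38, 30, 24, 2
with durations proportioned like the staged trace it emulates. Peeled
geometry guarantees broken pairs sit > 6 Å and kept pairs stay in
window with ≥ 6σ noise margin, so the Ω trace matches the schedule to
±1 per frame. What it deliberately does not emulate: transition-path
shapes between plateaus (levels switch in one frame), refolding
excursions, and any energetics — it is an analysis target, not a
simulation.

## Analysis conventions

* Ω window inclusive on both ends (4.0 ≤ d ≤ 6.0 Å).
* H-bond indicator: inclusive distance cutoff; for CG bead pairs the
  class rest length + 1.0 Å is the default cutoff. Lifetime events are
  maximal runs of 1s; boundary-touching runs count; event_count ×
  mean_lifetime ≡ occupancy × total time exactly.
* PMF: histogram on edges aligned to multiples of the bin size (so
  different bin sizes share an axis), F = −k_B T ln p, shifted so the
  lowest finite value is 0; empty bins are NaN, never interpolated.
  Reweighting multiplies per-frame weights exp(ΔV/k_B T) (max-shifted
  for overflow safety) into the histogram.
* Bond strength: F at the first discrete local maximum past the global
  minimum (plateau ties break toward smaller distance); profiles that
  rise monotonically raise a named no-peak error rather than returning
  an edge value.
* Backbone relaxation: unit normals of consecutive-Cα triples
  (collinear triples flagged NaN), C(t) averaged over triples and time
  origins, normalized to C(0) = 1; relaxation time is the first zero
  crossing with linear interpolation, or the max lag flagged as a lower
  bound.
* Plateau segmentation: greedy maximal segments within ± tolerance
  (default 2 Ω units, matching the stable band's width) of the running
  segment median, minimum duration 10% of the trace by default; levels
  are segment medians.
* Clustering: leader algorithm on best-fit RMSD (Kabsch superposition
  via scipy's rotational alignment), 2.0 Å default cutoff, medoid
  (minimum summed RMSD) as representative. The leader pass is
  order-dependent by construction; the medoid step is not.

## Reading the well-depth hierarchy back out

On stack trajectories the first-peak strength of a class mixes its well
depth with the conformational background of its pairs. The turn-flank
(vertical-intra) pairs are (i, i+3) backbone-tethered: their open state
has almost no volume, so their apparent strength is either undefined
(the profile never turns over on desk timescales) or inflated above the
lateral class — even though their well is the shallowest. This is a
property of any Cα-bead mapping: the atomistic donor–acceptor pairs
flicker through local side-group freedom that beads do not have. The
package therefore separates two statements:

* on the stack runs, PMF minima recover the class rest lengths (all
  three classes, within about a bin width) and the lateral > inter
  strength ordering is resolved;
* the full depth hierarchy (lateral > inter > intra) is recovered by
  matched-background probes (`betaroll.probe`): each class's 12-10 well
  sampled as a radial coordinate with one common weak tether
  (0.003 kcal·mol⁻¹·Å⁻² chosen so every class keeps a bound global
  minimum and a defined first peak) and the 3D r² Jacobian folded into
  the effective potential. The quadrature profile is the analytic
  oracle; the Langevin-sampled route must match it, and both order the
  classes exactly as the input depths (0.996 / 0.796 / 0.325
  kcal·mol⁻¹ by quadrature at 300 K).

## Problem sizes and tolerances

Default desk-scale runs: 2·10⁴-step cMD for prescription averages,
5·10⁴-step aMD per regime, 1.2·10⁵-step (2·10⁴ equilibration) cMD for
the baseline-band measurement — minutes each on one CPU. Finite
difference force checks at 10⁻⁴ relative; NVE drift budget 10⁻³ of the
initial energy over 10⁴ steps; equipartition within 5%; 1D reweighting
within Monte-Carlo tolerance 0.05 on populations of 4·10⁵-step
samplers; PMF bin-robustness within 0.05 kcal·mol⁻¹ across bin sizes
0.1–0.4 Å on 3–4·10⁵-sample series.

## Known limitations

* One bead per residue: no side chains, no angle-dependent hydrogen
  bonds, no hydrophobic-core packing; "hydrogen bonds" are bead-pair
  contacts.
* The baseline band (Ω̄ ≈ 61.2–61.5) sits in the lower half of the
  62 ± 2 target band: the 12-10 wells are anharmonically soft outward,
  so a few pairs always breathe past 6 Å.
* The boosted desk-scale runs reach partial unfolding (Ω into the
  40s–50s over 5·10⁴ steps); complete staged unfolding to Ω = 0 as in
  the atomistic study needs either far longer runs or thresholds beyond
  the studied n, where the flattened excluded volume eventually makes
  the 10 fs timestep unstable.
* Unweighted PMFs from boosted ensembles are, as in the original
  workflow, comparative tools; only the toy-model reweighting is held
  to an exact Boltzmann standard.
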