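# Methods

## Crosslinking yields and the significance filter

A yield is the densitometry intensity of the crosslinked band divided by
the total arrestin signal (crosslinked + free), a fraction in [0, 1];
values above 1 from quantification noise are clipped with a warning. A
pair is called significant when its replicate yields (n ≥ 3) exceed a
pooled background-noise control under BOTH a one-sided equal-variance
t-test at p < 0.02 and a one-sided Welch test at p < 0.05.

Choices the data do not dictate, made once and exposed as configuration:

* **One-sided tests.** The scientific question is whether signal exceeds
  background; a two-sided test would spend power on the impossible
  direction.
* **Conjunction of the two tests.** Requiring both thresholds is the
  conservative combination; the type-I error of the conjunction is
  bounded by the stricter threshold (0.02), which the acceptance suite
  verifies empirically on 10,000 null pairs.
* **No multiple-testing correction** — thresholds are applied raw, and
  the counts reported are descriptive, not inferential.
* **Degenerate variance.** If both samples have zero variance the t
  statistic is undefined; the verdict falls back to an exact comparison
  of means (p = 0 or 1).
* **Detection floor.** "Detectable" means any nonzero quantified band by
  default; the floor is configurable because band visibility is a
  judgement call upstream of this package.

## Crosslinker geometry

The BrEtY–Cys thioether adduct is modelled as a polyline
Cβ–Cγ··(ring)··Cζ–O–CH₂–CH₂–S–Cβ with an embedded ideal-geometry table:
bond lengths 1.51 (Cβ–Cγ), 2.79 (rigid para-ring span), 1.37 (Cζ–O),
1.43 (O–CH₂), 1.53 (CH₂–CH₂), 1.81 (CH₂–S), 1.81 Å (S–Cβ); angles 117°
at the aryl ether oxygen, 109.47° at the sp³ carbons, and 98.9° at the
thioether sulfur (the dimethyl-sulfide value). The para-substituted ring
is rigid with both exocyclic bonds on its 1,4 axis, so the stem
Cβ–Cγ–Cζ–O is straight. Torsions of the three geometry-changing
rotatable bonds are enumerated on a 15° grid (13,824 conformers);
conformers with any non-bonded atom pair closer than 2.0 Å are
discarded; the maximum anchor–anchor distance over the survivors is the
span. The maximum is attained at the all-anti conformer, so the result
is stable under grid refinement (a property the tests check, along with
the contour-length upper bound).

**Known discrepancy.** This enumeration gives 10.59 Å, and an
independent cross-check — MMFF-optimized conformer sampling of the real
adduct fragment with RDKit — gives a maximum of 10.68 Å, both a few
tenths above the 10.2 Å figure commonly quoted for this crosslinker.
Under any reasonable ideal covalent geometry the fully extended adduct
exceeds 10.4 Å; 10.2 Å appears to reflect sampling that did not reach
the fully extended conformer. The package reports what its documented
geometry computes and keeps 10.2 Å as the default restraint wall, since
the wall is the field's operating convention for this probe, not a
quantity this package re-derives.

Monoisotopic masses use lightest-isotope atomic masses; for ions the
electron mass is subtracted per positive charge and the total divided by
|charge| (the protonated BrEtY cation C11H15BrNO3⁺ evaluates to
288.0230 at four decimals).

## Flat-bottom restraints and scoring

E = √B · [max(d − hi, 0)² + max(lo − d, 0)²], with lo = 4.0 Å,
hi = 10.2 Å, and B the mean yield as a fraction in [0, 1]. The penalty
is continuous and once-differentiable at the walls, exactly zero inside
them, and scales as √B (quadrupling the yield doubles the energy —
asserted to 1e-12 in tests). Energies are in weighted Å²; no force
constant is applied. Whether √B uses fractions or percentages changes
absolute energies but not rankings; the fraction convention is the
package default and is configurable at restraint construction.

Anchors are Cβ, or Cα for glycine; a non-glycine residue lacking its Cβ
is a hard error by default (scoring a residue without its anchor is
never meaningful), with an opt-in logged Cα fallback. Satisfaction is
reported at 10.2 Å (strict adduct reach) and 15.0 Å (reach plus a
flexibility margin of a few Å, the field's accepted slack for chemical
crosslinks on mobile complexes). Model ranking is by ascending total
energy, ties broken by satisfaction count at the first cutoff, then
input order.

The inter-body clash term is a soft-sphere penalty on Cα pairs,
weight · max(4.0 − d, 0)², standing in for repulsive non-bonded
energetics at the resolution the rigid-body sampler works at.

## Rigid-body Metropolis Monte Carlo

One partner is fixed; the other moves in the 6-DOF space of proper
rotations and translations. A proposal is a compound move: rotation
about the mobile body's current centroid around a uniformly random axis
by a N(0, σ_rot) angle plus a N(0, σ_trans) translation per axis.
Defaults: σ_rot = 6°, σ_trans = 1 Å, adapted every 200 steps toward a
30–50% acceptance rate (bounded scaling). kT defaults to 1.0 in
weighted-Å² units, chosen so a unit-yield restraint violated by 1 Å
beyond its wall (E = 1) is accepted with probability e⁻¹ ≈ 37%. Every
trial draws from `numpy.random.default_rng(seed + trial)`; there is no
hidden global RNG state and identical configurations reproduce
bit-identical traces.

**Plateau-centroid estimate.** A flat-bottom restraint landscape has a
*plateau* of minimal-energy poses rather than a point minimum, and the
first minimal pose a walk happens to touch lies on the plateau's
boundary — the worst representative. The reported best pose is
therefore the centroid (chordal-mean rotation and mean translation) of
all visited poses tied with the best energy, provided the centroid's
own energy is tied; otherwise the raw best pose is kept. Convergence
can be monitored via the thinned energy trace; a plateau criterion (no
improvement over a window) is available but makes no claim to match any
particular production sampler's stopping rule.

## Principal-axes orientation analytics

Each body's frame is built per frame from the principal components of
its Cα coordinates, eigenvalues sorted descending: PC1 = longitudinal,
PC2 = vertical, PC3 completing the frame. Signs: longitudinal points
toward the centroid of configurable "nose" residues; vertical toward a
reference direction (membrane normal convention; for synthetic bodies
the tests use each body's own base-frame PC2, which is the stable choice
when no membrane exists). The axes are used as aircraft north/east/down
axes — roll about longitudinal, pitch about transverse, yaw about
vertical, with north × east = down.

The relative rotation is R = X_receptorᵀ · X_arrestin, the arrestin axes
expressed in receptor-frame components. This is invariant under any
global rigid motion of the complex (both frames transform as X → GX, so
Gᵀ cancels), which is the property that makes the angles physically
meaningful; tests assert it exactly. Angles follow the ZYX
factorization: β = atan2(−R₃₁, √(R₁₁² + R₂₁²)),
γ = atan2(R₃₂/cos β, R₃₃/cos β), α = atan2(R₂₁/cos β, R₁₁/cos β),
reported in degrees. At gimbal lock (|cos β| < 1e-8) roll is set to 0,
the residual rotation folded into yaw, and the row flagged.

Numerical degeneracies: collinear point sets raise; adjacent
eigenvalues within 1% of each other only warn, since PC ordering (not
the analysis) becomes unstable there. RMSD traces are computed on
arrestin Cα after least-squares (Kabsch) superposition of the receptor
Cα onto frame 0, so global drift cancels. Distance statistics
(min/quartiles/max, fraction-within and ever-within at 10.2/15.0 Å) are
brute-force per-frame computations, vectorized; contact persistence is
the fraction of frames with minimum inter-residue heavy-atom distance
below a 4.0 Å cutoff, with an any-of-group variant for interactions
that switch partners.

## Synthetic data: what it emulates, and what it does not

Pseudo-proteins are self-avoiding random walks with 3.8 Å Cα spacing,
4.0 Å self-avoidance, and pseudo-Cβ atoms 1.53 Å off the local backbone
— enough realism for anchor geometry, none for folds, sequences or side
chains.

* **Blot tables**: per-replicate measured yield = clip(true + N(0, sd),
  0, 1), band = yield × total with totals uniform in [800, 1200]
  arbitrary units; controls drawn from a background distribution
  (default mean 0.02, sd 0.01, n = 20 — a low, tight noise floor). The
  ground-truth label is "true yield exceeds control mean by 0.05".
* **Toy complexes**: the receptor coil is confined to a bowl-shaped
  shell cradling a compact mobile coil, so contact directions span a
  wide solid angle — as in the real complex, where the receptor core
  and C-tail wrap around the arrestin crest and N-domain. This matters:
  crosslinks on a single flat patch leave the docked pose
  underdetermined no matter how good the sampler is, because a pair at
  distance d only resists transverse sliding beyond
  √(10.2² − d²) − no pose information below that. Planted pair
  distances are drawn across the whole flat bottom [4.0, 10.2] Å
  (near-wall pairs are what pin the pose), stratified by azimuth around
  the interface so pairs tile it rather than cluster. Yields follow
  B = clip(0.6 − 0.04·(d − 4), 0.05, 0.6) + N(0, 0.02), a modelling
  choice loosely mimicking that tighter contacts crosslink more
  efficiently, not a measured relation.
* **Trajectories**: per frame the mobile body is rotated rigidly about
  its centroid so the relative-orientation angles equal base + N(0, sd)
  exactly, plus translational jitter; the planted angle table is emitted
  for recovery tests. Default angular spreads (5°, 5°, 10°) for
  (pitch, roll, yaw) echo that pitch is the most membrane-limited motion
  and yaw the freest.

Passing tests on these generators shows the analysis machinery is
correct and calibrated; it does not show that real blots are normal, n
of 3 is sufficient power for weak signals, or that a rigid-body search
can fold flexible loops — all outside this package's scope.

## Problem sizes

Defaults are desk-scale: toy bodies of 40 + 40 residues, 12 planted
restraints, pose recovery at 10 trials × 50,000 steps, filter
calibration at 10,000 simulated pairs, ensembles of 60–2,000 frames.
The adduct enumeration visits 13,824 conformers at the 15° default
grid. All are package choices to keep the full validation suite
runnable on a single CPU in minutes; every size is a parameter.

## Known limitations

* Rigid-body sampling only: flexible loops and termini are accepted as
  alternative input conformers, not sampled.
* The enumerated adduct span exceeds the conventional 10.2 Å wall (see
  above); both numbers are reported rather than reconciled.
* The clash term is Cα-resolution and pairwise-quadratic; it prevents
  interpenetration but carries no attraction, so poses float freely
  wherever restraints are satisfied.
* Binary trajectory formats are out of scope; ensembles are multi-model
  PDB behind a small reader interface.
* The salt-bridge-style contact criterion (4.0 Å heavy-atom minimum) is
  a documented default, not a fitted one.
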