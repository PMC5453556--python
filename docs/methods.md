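# Methods

This note documents the models and procedures implemented in
`crypticscreen`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## Pocket detection by protein–solvent–protein scanning

A structure's heavy atoms (hydrogens and waters are excluded by default,
so detection does not depend on whether an ensemble was saved with
protons) are assigned van der Waals radii — Bondi values by default, with
a 1.8 Å fallback for unrecognized elements — and embedded in a cubic
lattice of step `grid_step` (default 1.0 Å) spanning the atom bounding
box plus `padding` (default 4.0 Å, enough to guarantee genuine solvent on
every side so box edges cannot masquerade as burial). A voxel is
*occupied* when its center lies within `radius + probe_radius` of an atom
center; `probe_radius` defaults to 0 (pure van der Waals occupancy) and
is exposed because the choice is a convention, not a law.

Each solvent voxel is scanned along seven lines: the three lattice axes
and the four cube diagonals, the diagonals stepping voxel-by-voxel along
(±1, ±1, ±1) index increments. A direction counts as one
protein–solvent–protein (PSP) event when occupancy is found on **both**
sides of the voxel along that line, anywhere within the grid; the
per-voxel count is therefore an integer in [0, 7]. PSP per direction is
binary — enclosed or not — rather than a count of crossings along the
line; this is the reading consistent with a [0, 7] scale and a threshold
of 6. Voxels with at least `min_psp` (default 6) enclosed directions are
pocket elements. Contiguous elements (26-connectivity by default;
cryptic pockets are irregular and stricter connectivity fragments them)
are grouped into pockets, and pockets under `min_elements` voxels
(default 30, ≈30 Å³ at a 1 Å step) are discarded as noise. Pockets are
ordered by descending size with ties broken by smallest voxel index, so
runs are bit-reproducible.

The production scan computes per-direction enclosure with
logarithmically doubled boolean shifts (O(log n) array passes per
direction). Its correctness oracle — a per-voxel, per-direction ray walk
sharing none of that machinery — lives in `synthetic.brute_force_psp_counts`
and the two are compared exhaustively on randomized grids in the test
suite.

## Pocket clustering and target-state selection

Pockets detected independently across an ensemble are grouped by
center-of-mass proximity with a greedy largest-first algorithm: the
largest unclustered pocket founds a new center, all pockets are assigned
to their closest center within `distance_cutoff`, and the two steps
repeat until every pocket is assigned. "All pockets are assigned" is
read as *global* re-assignment after each founding, so a pocket always
ends up with its closest center; a strict no-reassignment variant is
available behind a flag because the wording of the procedure admits both
readings. Ties in "largest" are broken by size and then lexicographic
center of mass, making the partition independent of input order. The
default cutoff is 5.0 Å — about half the diameter of a small-molecule
site — and is prominently configurable because no published value exists
to anchor it; the algorithm, not the cutoff, is the reproducible part.

Docking targets are the states whose structures contain the chosen
pocket cluster, filtered to equilibrium population ≥ 0.004% (inclusive)
and capped at the 15 most populated, with population ties at the cap
broken by state id. Populations are *not* renormalized after selection:
Boltzmann weights are scale-invariant, so renormalization would change
no downstream ranking.

## Boltzmann-weighted docking score aggregation

Docking engines are external; their output enters as a per-compound,
per-state score matrix with a declared polarity (higher-better by
default). The ensemble score of a compound is the equilibrium-weighted
average

  S = Σᵢ πᵢ·sᵢ / Σᵢ πᵢ

over the states where the compound was actually scored: missing entries
drop out and the weights renormalize over the rest, with a coverage
column and a configurable exclusion threshold so thinly docked compounds
are logged rather than silently ranked. The score is always bracketed by
the per-state extremes, is invariant to rescaling all populations by a
constant, reduces to the plain mean under equal weights and to the raw
score with a single state — the crystal-structure screening limit.

## Compound triage

Drug-likeness uses the rule-of-5 thresholds with the molecular-weight
cutoff tightened to 400 g/mol: pass requires mw ≤ 400, logP ≤ 5,
HBD ≤ 5 and HBA ≤ 10, all inclusive (the standard convention) and all
simultaneously (no one-violation allowance). Descriptors are computed
from SMILES with RDKit when not supplied. Structural alerts are SMARTS
lists; matching any pattern of a list flags the compound with that
list's name, and the purge decision is "any flag set". The shipped
`reactive` and `aggregators` lists are small illustrative sets — the
full published alert collections are distributed elsewhere and can be
loaded from `name<TAB>SMARTS` files. Records lacking both descriptors
and a parseable SMILES are reported *unevaluable*, a distinct category
from *fail*, and input/output counts are conserved across the pipeline.
Stereochemistry is passed through untouched; conformer generation and
energy minimization are out of scope.

## Kinetics

Initial velocities are free-intercept least-squares slopes of signal vs
time over the first 10 s of a trace (≥3 points required). Velocities in
absorbance units per second are accepted throughout, since every
reported quantity except kcat itself is a ratio; conversion to μM/s
requires a user-supplied extinction-coefficient factor.

Substrate series fit the Michaelis–Menten model
v = kcat·[E]·[S]/(Km+[S]) by nonlinear least squares (scipy's
trust-region reflective solver, three data-driven starts, best SSR
kept). Standard errors come from the fit covariance; kcat/Km carries an
independently-propagated error. A fit is flagged ill-determined when Km
lands more than 10× outside the probed substrate range or its standard
error exceeds its value — a flat or saturated design cannot pin Km,
whatever the covariance claims.

Modulator dose series fit the two-parameter mixed-activation model

  v = kcat·[E]·[S]·(1 + β·[A]/K_act) / (Km + [S]·(1 + [A]/K_act))

with Km fixed to the compound-free fit and kcat anchored from the
[A] = 0 points by default (a fully free three-parameter fit is
available). β rescales the catalytic output of the modulator-bound
complex and K_act is the modulator's dissociation constant from it. At
[A] = 0 the model reduces exactly to Michaelis–Menten; as [A] → ∞ the
velocity tends to β·kcat·[E]; and the apparent efficiency kcat/Km scales
as (1 + β·[A]/K_act), so a compound with β ≤ 1 can still activate at
sub-saturating substrate through the apparent-Km shift. **Identifiability
caveat:** β and K_act are strongly correlated whenever the tested doses
do not substantially exceed K_act — in the limit K_act → ∞ at fixed
β/K_act the model becomes linear in [A] and the two parameters collapse
onto a ridge. With doses reaching only ~1.2×K_act and 5% proportional
noise, the Fisher standard error of K_act is comparable to its value, and
a nontrivial fraction of replicate fits run onto the ridge. Fits whose
K_act exceeds 10× the highest tested dose are therefore flagged
non-identifiable; single-dataset K_act values from such designs should be
read as order-of-magnitude estimates.

Dose-response data fit a one-site hyperbola with the baseline fixed
at 1, v_rel = 1 + a·[A]/(EC50+[A]): Hill coefficient 1 by default (a
free-Hill variant exists), the sign of the amplitude distinguishing
activators from inhibitors, and an extrapolation flag raised when the
fitted EC50 falls more than 10× outside the tested dose range. The
hyperbolic form is a choice — the underlying assays report EC50s without
naming a model — and is the simplest curve consistent with one-site
binding.

All fits are plain **unweighted** least squares. Likelihood-exact
weighting for proportional noise (σ ∝ signal) was evaluated and
rejected: it systematically downweights the high-dose points that carry
the saturation information and measurably degrades EC50 and K_act
recovery, while unweighted regression of initial velocities is also the
field's standard practice.

Plate screens call hits with two rules: the effect at each concentration
is the relative change of the mean velocity against the same-plate
no-compound control; a compound is *dose-dependent* when all effects
share one sign and |effect| is non-decreasing with concentration within
one pooled standard error (the tolerance absorbs replicate noise); and a
*hit* additionally needs max |effect| ≥ 20%. The "impact ≥ 20%" rule is
applied to relative velocity changes — the ratio reading — which also
makes hit calls invariant to rescaling every velocity on a plate.
Efficiency changes between conditions are reported as
100·((kcat/Km)₁/(kcat/Km)₀ − 1) with errors propagated from both fits.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth known by construction; all are bit-reproducible under a fixed
seed.

*Structures.* Pocket-open states are hollow shells of carbon-like
pseudo-atoms (radius 1.7 Å) on a golden-spiral lattice at radius 8 Å
with ~1 Å spacing; an optional angular mouth turns the closed cavity
into an open pocket. Pocket-closed states are solid balls of atoms. The
cavity's qualifying voxel set is enumerated entirely by brute force
(exhaustive occupancy check, naive ray walk, hand-rolled BFS from the
cavity center) and a shell that leaks to the box edge at the requested
grid step is rejected rather than returned with a bad oracle. These
decoys test the geometry of detection exactly; they do not resemble real
protein surfaces, so passing says nothing about chemical druggability.

*Ensembles.* n states mixing open and closed structures, with uniform or
geometric populations; the geometric ratio 0.85 spans roughly an order
of magnitude across 15 states, matching the spread described for the
real target set.

*Score matrices.* I.i.d. Gaussian baseline scores (sd 1, mean 5) with
planted binders receiving a fixed bonus in every state; bonuses must
exceed 3× the noise sd so rank-1 recovery is guaranteed in tests.

*Assays.* Velocities are drawn as model(θ)·(1 + ε), ε ~ N(0, cv²) —
proportional noise, the typical error structure of absorbance assays —
at the study's designs: substrate 10–200 μM, screen doses 0.5/50/100 μM,
dose-response 0–400 μM at 50 μM substrate, enzyme 1 nM, triplicate,
cv = 5%. Linear traces with slope equal to the velocity are available
for testing the initial-velocity extraction. What the simulations do not
model: substrate depletion, instrument drift, detergent or
enzyme-concentration dependence, and compound aggregation — so parameter
recovery here demonstrates estimator correctness, not robustness to
those real-world effects.

The compound-1 simulations use β = 0.8424, derived by inverting the
efficiency relation 1 + β·[A]/K_act = 1.52 at [A] = 100 μM with
K_act = 162 μM.

## Problem sizes

Default test and reproduction runs use 100 simulated datasets per
recovery experiment, triplicate observations, ≤16³ lattices for
scan-vs-oracle comparisons and ~800-atom decoy shells — sizes chosen so
the whole suite completes in well under a minute on one core while
keeping Monte Carlo standard errors a few percent.

## Known limitations

- The clustering cutoff and any probe radius are conventions; different
  choices change pocket membership on real ensembles.
- K_act from single saturating-limited dose series is weakly identified
  (see above); report it with its flag and standard error, never alone.
- EC50 estimates from 3-replicate, 5%-noise series scatter with ~25–40%
  sampling sd; averages over many replicates retain a small (~5%)
  right-skew bias intrinsic to nonlinear least squares.
- The shipped alert lists are illustrative, not the published
  collections; library-scale purge counts will differ from any published
  screen.
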