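# Methods

## Model

The scoring function is a distance-dependent atomic pair potential between
protein and RNA heavy atoms.  Protein atoms are grouped into 20 chemical
types and RNA atoms into 12 (carbonyl-like carbons, aromatic carbons, sp3
carbons, amide/charged/aromatic nitrogens, carbonyl/hydroxyl/ester and
charged oxygens, sulfurs, phosphorus), giving 240 possible type pairs.  For
each retained pair the potential is a table of energies on 0.2 Å bins; the
binding score of a pose is the sum of table lookups over all
inter-molecular pairs closer than 10 Å.

Energies are inferred from structures by iteration rather than from a
reference state.  The observed pair distribution `g_obs` is the
shell-volume-normalized radial histogram of the native training complexes
(12 Å reference sphere, each complex weighted equally).  A pre-generated
rigid decoy ensemble per complex stands in for the thermodynamic ensemble
of binding modes: under trial potentials `u^(n)` every pose gets a
Boltzmann probability `w_l ∝ exp(-E_l/kT)` and the probability-weighted
pose distribution `g^(n)` is compared with `g_obs`:

    u^(n+1) = u^(n) + (λ/2) kT (g^(n) - g_obs).

Iteration stops when the native pose of every training complex scores
strictly below all of its decoys (ties count as failures).  If the cycle
budget is exhausted the best table seen (fewest discrimination failures) is
returned, flagged unconverged.  Because poses are rigid, per-pose
histograms and score decompositions are cached once; every cycle is then a
tensor contraction, which is what makes the loop cheap.

### Assumptions

- Only heavy atoms carry statistics; hydrogen effects are implicit.
- The decoy ensembles bracket the binding modes that matter: the update can
  only penalize geometries the ensemble actually visits.
- A single `kT = 1` (reduced units) applies everywhere; the 100 and 10
  short-range penalty caps are treated as dimensionless values on the same
  scale.  Absolute score magnitudes are therefore not calibrated
  free energies; only differences and rankings are meaningful.

## Parameters

| parameter | default | meaning |
|---|---|---|
| bin width | 0.2 Å | radial resolution of histograms and tables |
| reference sphere | 12 Å | pair-counting radius for distributions |
| scoring cutoff | 10 Å | pairs beyond this contribute nothing; tables are 0 there |
| penalty cap | 100 (soft: 10) | short-range clash penalty ceiling, reduced units |
| kT | 1 | Boltzmann factor scale in the iteration |
| λ | 1 | update step size |
| occurrence threshold | 1000 (50 at toy scale) | minimum within-sphere pair count for a pair type to receive a potential |
| cluster radius | 5 Å | RNA heavy-atom RMSD radius for greedy pose clustering |
| CAPRI tiers | standard | high/medium/acceptable thresholds on (fnat, L_RMSD, I_RMSD) |

The 6-12 parameters used for the initial potentials and the VDW prefilter
ship as an Amber-style per-type file (radius, well depth; `R_ij = R_i +
R_j`, `ε_ij = √(ε_i ε_j)`) and can be overridden by the user.

### Numerical choices

- **Normalization of g.**  Bin counts are divided by exact shell volumes
  and by the mean pair density in the sphere, so a uniform random
  arrangement gives g = 1.  The iteration is invariant to any common
  normalization of `g_obs` and `g^(n)`; this contract fixes the gauge.
- **Lookup.**  Piecewise-linear interpolation between bin centers, the
  penalty cap below the first bin center, a linear ramp to exactly zero at
  the cutoff, zero beyond.  Scores are continuous in the coordinates.
- **Forbidden core.**  Bins below the first natively populated bin of a
  pair are pinned exactly at the penalty cap: the wall is an assigned
  penalty, not a statistical estimate, and the VDW term does not perturb
  it.  During iteration the update re-caps after every cycle, so walls
  stay walls.
- **Smoothing.**  The final potentials are smoothed once with the
  1:2:4:2:1 kernel to damp statistical fluctuation.  The kernel runs over
  the statistically estimated window only: the capped forbidden core and
  the zero tail beyond the cutoff act as hard window boundaries, and at
  the window edges the kernel is truncated and renormalized.  Smearing the
  artificial 100-unit wall into the first contact bins would corrupt
  exactly the bins that carry the discrimination signal.
- **Boltzmann weights** are computed max-shifted, so arbitrarily large
  score gaps cannot overflow.
- **Ties.**  A native tied with a decoy counts as a discrimination
  failure; clustering keeps the earlier (better-scored) pose; stable
  argsorts make every ranking deterministic.
- **Refinement.**  Rigid-body Nelder–Mead over 6 parameters (3
  translations in Å, 3 axis-angle components about the moving partner's
  centroid), initial steps 1 Å / 5°, energy tolerance 1e-4, at most 2000
  evaluations.  The starting pose is a simplex vertex, so the returned
  energy never exceeds the starting energy.  Severely clashed starts sit
  on the flat capped-energy plateau; the initial simplex is then
  deterministically re-widened (×2, ×4) until it straddles the plateau
  edge.
- **Degenerate inputs.**  Empty structures, empty score vectors, mismatched
  grids and non-orthonormal rotations raise immediately; superposition
  requires ≥ 3 non-degenerate points and always returns a proper rotation
  (no reflections, chiral sets stay chiral).

## Synthetic study conditions

The fixture generator emulates the shapes of the real problem while staying
minutes-cheap and download-free.  Toy proteins are repeating Arg–Phe–Asp
triplets and toy RNAs repeating A-U-G-C, rendered as deterministic spherical
heavy-atom clusters (all atom names drawn from the standard typing
alphabet) whose residue centers follow zigzag rods packed into a bound
interface with at least 20 residue–residue contacts.  Sizes follow the real
training-set floors: 21–28 protein residues, 10–14 nucleotides.  Decoy
ensembles mix uniform rigid placements on the surface shell with
small near-native jitters, rejecting poses with any inter-partner atom
closer than 1.5 Å, and span near-native (< 5 Å) to far (> 20 Å) RMSD.

For recovery experiments a known generating potential (per-pair Morse
wells with seeded depth 0.3–2.5, location 3–5 Å, and width; compact, like
real contact potentials that vanish well before the cutoff) defines the
ground truth.  Each training native is the lowest-scoring decoy under the
generating potential after local refinement, so ground truth discriminates
every native by construction — the property the derivation must recover.
At the default study scale (8 complexes × 100 decoys + native, retention
threshold 50 — the >1000 rule scaled to the toy set's roughly tenfold
smaller pair volume) the derivation converges in 2 cycles, well inside the
10-cycle budget the method is expected to need.  On the larger recovery
conditions (10 complexes × 200 decoys) the derived table ranks held-out
decoys consistently with the generating table (mean Spearman ρ ≈ 0.86–0.93
across seeds tried).

What passing these conditions does **not** show: the toy geometry has no
real secondary structure, electrostatics, or induced fit; the training set
is orders of magnitude smaller than a curated crystal-structure corpus, so
per-bin statistics are far noisier than in production use; and decoys come
from a simple rigid sampler rather than a shape-complementarity docking
engine.  Benchmark success rates on real docking sets cannot be inferred
from these tests.

## Design choices that were genuinely open

- The printed form of the iterative update was not recoverable from the
  source text; the implemented `(λ/2)·kT·(g^(n) − g_obs)` correction follows
  the described mechanism, with λ exposed in configuration.
- Whether caps apply during iteration or only at the end is unstated; this
  implementation re-caps every cycle (walls cannot erode).
- The exact normalization of g is unstated; the uniform-density ⇒ g = 1
  gauge is enforced (the iteration is invariant to the choice).
- C-terminal OXT is not in the published typing table; it is mapped to the
  carboxylate-oxygen type by chemistry.  Modified residues are dropped with
  a warning rather than guessed.
- altLoc conformers resolve to highest occupancy (ties: first in file);
  each MODEL of a multi-model file is a separate pose.
- CAPRI thresholds follow the standard protein–protein assessment tiers;
  they are exposed in configuration since the original CAPRI rounds
  predate RNA targets.

## Known limitations

- Energy units are reduced; mixing the derived tables with physical
  force-field terms requires an external calibration.
- The derivation can stop at thin discrimination margins (it stops as soon
  as every native ranks first), so the unsmoothed converged table carries
  the formal rank-1 guarantee; the smoothed artifact is the recommended
  scorer and retained rank 1 in all conditions tested here.
- No DNA typing, no modified nucleotides, no mmCIF input, no global FFT
  sampling — decoy generation beyond the synthetic sampler is out of scope.
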