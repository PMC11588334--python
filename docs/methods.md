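# Methods

This note records the models, numerical choices and known limitations of
`osmokit`, in the order a user meets them.

## Structure handling

Structures are read with gemmi and reduced to a small domain model: ordered
polymer chains and a separate water list. Author residue numbering is
authoritative throughout, because that is how kinase residues are named in
practice (WNK1/E388, WNK3/E314). Only the blank/'A' alternate-location
conformer and the first model are kept; hydrogens are dropped and all water
geometry uses the oxygen. These conventions are configurable only where a
analysis needs it (altloc policy in `read_structure`).

## Superposition and displacement profiles

All r.m.s.d. values are computed over C-alpha atoms of mapped residue
pairs. Backbone-level comparison is the field's reporting convention and
makes cross-isoform comparisons well defined; an all-common-atom option was
deliberately not made the default because isoform side chains differ.

The Kabsch algorithm is implemented directly (SVD of the covariance,
reflection corrected by sign-flipping the smallest singular vector);
degenerate geometry (fewer than 3 pairs, collinear sets) is rejected.
`rmsd_selection` separates the residue set used to *fit* from the set the
r.m.s.d. is *reported* over, which is how "N-terminal domains superimposed"
local comparisons and "Activation Loops excluded" statistics are formed.
Displacement profiles are Euclidean C-alpha distances after an anchored
fit; the hinge finder is a two-segment piecewise-constant changepoint and
is meaningful for block-like (shift) motions — for a rotation about a
pivot, displacement grows continuously from the hinge and the changepoint
lands mid-ramp, so only the peak location is interpreted in that case.

Cross-isoform residue mapping uses global pairwise alignment
(BLOSUM62, affine gaps −11/−1, Biopython's `PairwiseAligner`); all
residue-to-residue aligned columns become pairs, including substituted
positions — mutated sites must remain mapped or mutant-vs-wild-type
comparisons would silently drop the residues of interest.

Crystal-symmetry mates are generated through gemmi's space-group operators
in fractional coordinates. For dimer-on-dimer comparisons the chain pairing
(A↔A/B↔B vs A↔B/B↔A) and a small set of lattice shifts are searched and the
lowest r.m.s.d. kept, since a deposited origin choice is not recoverable
from a paper's text.

Default residue windows (author numbering, configurable): WNK1 Activation
Loop 371–400, WNK3 Activation Loop 297–326, WNK1 N-terminal-domain anchor
194–310. The literature states the exclusions but not exact bounds; these
windows span the phosphoacceptor serines and the mutated glutamate with
symmetric margins.

## Conserved-water mapping

Waters are projected into a common reference frame using the anchor
superposition of their parent structure, filtered at occupancy ≥ 0.5 and
B ≤ 80 Å² (crystallographic practice; both exposed). Clustering is greedy
agglomerative on centroid distances with three constraints: merge distance
≤ `match_cutoff` (default 2.2 Å), at most one water per structure per
cluster, and every member within the cutoff of the merged centroid. Ties
break by distance then lexicographic member identity, making the result
independent of input order (tested by permutation). 2.2 Å separates
adjacent hydration sites (~2.8 Å O–O) while tolerating lattice-to-lattice
drift after superposition.

Retention between two structures uses optimal one-to-one assignment
(Hungarian algorithm on the distance matrix, pairs beyond the cutoff
forbidden) rather than greedy matching, so counts are reproducible and
symmetric; greedy is available behind a flag. Networks are connected
components of the centroid graph with edges at O–O ≤ 3.4 Å, the upper bound
of water–water hydrogen bonds. CWN1/CWN2 are identified by region, not by
label: the largest component contacting both Catalytic-Loop and
Activation-Loop residues, and the largest component touching both subunits
of the dimer, respectively.

## Autocatalytic kinetics

The model is the two-species autocatalytic scheme with rapid-equilibrium
chloride scaling `k_app = k/(1+[Cl]/K_Cl)`. An alternative in which
chloride sequesters the unphosphorylated species gives algebraically
identical progress curves, so the two cannot be distinguished by this data;
the scaling form is used. p0 (the phosphorylated seed) is fitted, not fixed
at zero: autocatalysis cannot start from p = 0, and dephosphorylated enzyme
preparations retain residual phosphorylation.

Fitting is unweighted least squares on fractions. Global search is seeded
differential evolution over log-scaled parameters (bounds: k ∈ [1e−5, 10]
μM⁻¹min⁻¹, K_Cl ∈ [1, 5000] mM, p0 ∈ [1e−5, 0.5]·T), followed by bounded
least-squares refinement of the best candidates; the log parameterization
keeps the search well scaled across orders of magnitude. Standard errors
are asymptotic, from the Jacobian at the optimum. Saturated or flat series
are reported as non-identifiable rather than fitted.

The closed form and an adaptive ODE integration (LSODA, rtol 1e−10) agree
to better than 1e−8 relative over the tested regime; the ODE route exists
purely as a cross-check.

## Equilibria

SLS apparent mass is treated as the weight average, the quantity a
90° instrument reports for small proteins: a 60 kD reading for a
40 kD monomer then means a 50/50 mixture *by mass* (number-average would
give 53.3 kD, inconsistent with that reading). The mass-action solver uses
the closed form [M] = (−Kd + √(Kd² + 8·Kd·c))/4 and conserves
[M] + 2[D] = c to ~1e−10 relative; Kd is fit on log scale by least squares
on apparent masses. With Kd = 20 μM (the value that makes 0.8 mg/ml of a
40 kD monomer exactly 50/50) the model predicts 65.1 kD (dimer mass
fraction 0.63) at 1.8 mg/ml — "predominantly dimeric", though still short
of pure dimer.

DSF melts are fit to the symmetric logistic with the inflection point as
Tm, initialized from the steepest finite-difference slope (which makes the
fit exactly equivariant under temperature shifts). Fluorescence beyond the
global maximum is trimmed before fitting — the post-transition aggregation
roll-off of dye-based melts is not part of the unfolding isotherm.

## Synthetic data

Generators are pure functions of (design, seed) and always return their
ground truth alongside the data; tests never re-derive truth from data.

* **Ensembles**: an ideal helix-turn-helix C-alpha scaffold (44 residues,
  helix radius 2.3 Å, rise 1.5 Å, 100°/residue), 10 planted water sites
  (≥ 3 Å apart, per-structure Gaussian jitter σ = 0.25 Å), 30 background
  waters per structure uniform in the scaffold box (density ≈ 0.002 Å⁻³),
  each copy under its own random rigid motion. Background waters are
  rejection-sampled to stay ≥ 2.5 Å from planted centers *and* from
  background waters of other structures: without the cross-structure
  exclusion the background occasionally forms genuine conserved sites and
  the recorded truth would be wrong. What this generator does **not**
  emulate: partial occupancy, anisotropic B, lattice-specific waters,
  non-rigid conformational change — recovery rates on it bound detector
  performance under ideal rigid-body conditions only.
* **Progress curves**: the experimental design itself — 4 μM enzyme,
  chloride at 50/150/250 mM, samples at 0/4/10/15/20 min — with additive
  Gaussian noise (σ = 0.03 fraction units) clipped to [0, 1]. The
  wild-type-like preset (k = 0.10 μM⁻¹min⁻¹, K_Cl = 120 mM, p0 = 0.15 μM)
  is calibrated so the 50 mM curve approaches completion within the sampled
  window, which is what the stated time-point design implies; the
  activating-mutant-like preset (k = 0.25, K_Cl = 400) encodes the
  faster-and-less-chloride-sensitive ordering. Both are illustrative, not
  measured constants.
* **SLS / DSF**: mass-action weight-average masses at 0.8/1.2/1.8/2.4
  mg/ml with multiplicative noise; logistic melts on the 4–80 °C, 0.5 °C
  instrument grid (153 points) with multiplicative noise.

## Problem sizes and determinism

The replicate studies use 100 kinetic replicates, 50 SLS replicates and 10
DSF replicates; the standard ensemble is 5 structures × (10 + 30) waters.
These sizes give stable medians while keeping the whole suite and the
acceptance script around a minute each. All stochastic steps take explicit
seeds; the pipeline reports embed the config hash and input checksums and
are byte-reproducible apart from the timestamp field.

## Known limitations

* Comparisons against the deposited WNK structures run only when local
  coordinate files are supplied; conserved-network counts on real data
  additionally depend on curation choices (cutoffs are exposed for this).
* The kinetic model is the minimal two-species scheme: no explicit
  monomer–dimer species, no ATP depletion, no multi-site coupling
  (phosphosites are fit independently).
* The Kd fit assumes a clean two-state 2M ⇌ D system and errors only on
  apparent mass, not concentration.
* `find_hinge` assumes a single dominant block motion.
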