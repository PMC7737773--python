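# Methods

This note documents the models implemented in `ddgdyn`, the defaults and the
reasoning behind them, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Problem setting and sign convention

The quantity predicted is ΔΔG, the change in Gibbs free energy of folding
upon a missense mutation, in kcal/mol. Throughout the package **ΔΔG < 0 is
destabilizing and ΔΔG > 0 stabilizing**; exactly 0 is assigned to the
destabilizing class (the boundary must live somewhere, and experimental
"no effect" entries are conventionally grouped with destabilizing in
sign-classification summaries). External files in the opposite convention
are negated on read via `sign_convention="pos-destab"` (CLI:
`--sign-convention`).

## Structure handling

PDB input is parsed with Biopython. Author residue numbering with insertion
codes is the one and only coordinate system for mutation positions — no
renumbering, ever, because mutation strings ("W43F") are written against the
deposited numbering. Waters are dropped, hydrogens and non-water HETATM
groups kept. Alternate locations collapse to one atom per (chain, residue,
name): highest occupancy wins, ties go to the first-listed conformer. Only
one MODEL is read (the first unless requested otherwise). No structures are
ever fetched from the network; an identifier is resolved only against a
user-supplied local directory.

Relative solvent accessibility (RSA) is Shrake–Rupley ASA (probe 1.4 Å, 960
sphere points per atom) over the residue's heavy atoms, divided by the
theoretical Gly-X-Gly maxima of Tien et al. (2013); values may slightly
exceed 1 for extended conformations. SASA is evaluated in a canonical
principal-axes frame of the structure so that the fixed sphere grid cannot
make the result depend on the input's orientation; without this, rotating a
structure changes ASA by ~1%. Residues with RSA ≤ 0.30 are classified
buried (boundary inclusive on the buried side).

## Pharmacophore signatures

Each heavy atom of the 20 standard residues carries one or more of eight
categories — Hydrophobic, Positive, Negative, HBondAcceptor, HBondDonor,
Aromatic, Sulfur, Neutral — from the bundled table
`data/pharmacophores.tsv` (one auditable row per residue/atom; unknown
combinations fall back to Neutral with a logged warning). Backbone amide N
is a donor (except proline), carbonyl O an acceptor, terminal OXT a charged
acceptor.

The signature of a site is computed over its *environment*: all heavy atoms
within a closed ball of radius 10 Å around the site's Cα, excluding the
site's own side chain (backbone retained). The exclusion makes the vector a
description of what surrounds the residue being replaced rather than of the
residue itself, and — deliberately — makes the environment identical for a
forward mutation and its hypothetical reverse, for which no mutant structure
exists. For every unordered category pair and every threshold in
(3.0, 4.5, 6.0, 7.5, 9.0, 10.0) Å, the signature counts atom pairs at or
below the threshold; an atom with k categories contributes k ways. Counts
are cumulative (non-decreasing in the threshold), translation- and
rotation-invariant, and flatten to 216 features in a fixed order (pairs
lexicographic in the category order, thresholds ascending). Radius and
threshold grid are configurable; the defaults follow the cutoff-scanning
lineage of such signatures (a sub-contact minimum, even spacing, outer
threshold equal to the environment radius).

## Elastic-network normal modes

The dynamics model is a Cα-only elastic network with uniform masses. Two
force fields are registered:

* `anm` — unit springs between all Cα pairs within a cutoff (default 15 Å);
* `calpha` — Hinsen-style distance-dependent constants,
  k(r) = 8.6·10²·r − 2.39·10³ for r < 4 Å and 1.28·10⁸·r⁻⁶ beyond (r in Å),
  springs between all pairs. k ≤ 0 (Cα pairs closer than ~2.8 Å) raises —
  that is a physically broken structure.

The registry is extensible; these are the two canonical Cα force fields and
are documented as a subset of what a full NMA toolbox offers. The absolute
spring-constant scale is arbitrary and cancels in every normalized feature.

The Hessian is assembled from standard pairwise super-elements
(−k/r²·ΔrΔrᵀ off-diagonal, row-sum negation on the diagonal) and
diagonalized exactly (`scipy.linalg.eigh`; O(N³), fine at desk scale — a few
hundred residues). A connected, non-collinear network has exactly six
near-zero eigenvalues (rigid translations/rotations), detected with
tolerance λ < 10⁻⁸·λ_max; more than six raises "ill-conditioned", a
disconnected network is rejected up front naming its smallest component.
Mean-square fluctuations are the non-trivial mode sum Σ λ_m⁻¹|v_m,i|², which
equals the diagonal 3×3 block traces of the Hessian pseudo-inverse (the test
oracle). Cross-correlations are the normalized covariances of the same mode
sum; porcupine vectors are one eigenvector reshaped to N×3 and scaled to
maximum norm 1.

Four per-site scalars enter the feature vector: fluctuation, fluctuation
rank percentile (site with the largest fluctuation → 1.0), mean absolute
correlation of the site's row (diagonal included), and the site's
displacement norm in the first non-trivial mode. Which NMA-derived scalars
a ΔΔG predictor should use is genuinely open; these four were chosen to
capture local mobility, its rank in the protein, dynamic coupling, and
participation in the softest mode, and they are exactly rigid-motion
invariant.

## Interaction and substitution features

* Hydrophobic contacts: heavy-atom pairs (one atom in the site residue, one
  outside) with both atoms carrying the Hydrophobic category and distance
  ≤ 4.5 Å (closed). Hydrogens are never added; the threshold is a
  heavy-atom value.
* Contact potential: Σ over residues whose Cβ (Cα for glycine) is within
  8 Å of the site's, of a symmetric 20×20 pair-energy matrix. The bundled
  default is a clearly-labelled **synthetic** hydrophobicity-derived
  quasi-chemical-style matrix (`data/contact_potential_synthetic.csv`,
  e_ij = −kd_i·kd_j/8); readers for plain 20×20 CSV and AAINDEX3
  lower-triangular format let users substitute any published statistical
  potential without code changes.
* Substitution block: BLOSUM62 log-odds (via Biopython), Δvolume
  (Zamyatnin), Δhydrophobicity (Kyte–Doolittle). The two difference terms
  are antisymmetric under wt/mut swap, which is what makes reverse-record
  features coherent. Volume classes use |ΔV| ≤ 25 Å³ as "similar"
  (inclusive).

## Dataset curation

Hypothetical reverse mutations (mut→wt, −ΔΔG, computed on the wild-type
structure) counter the natural excess of destabilizing measurements.
Reverses with ΔΔG < −2.0 or > 2.0 kcal/mol are left out — the modeled
mutant is too uncertain for drastic changes; the window is exclusive, so a
reverse of exactly ±2.0 is kept. Double augmentation is refused. Multi-site
curation keeps doubles and triples only. Splits are either uniform random
or grouped by protein identifier, in which case no group straddles the
train/test boundary; by-protein grouping is a conservative stand-in for
sequence-identity clustering, which would need an external redundancy
pipeline.

## Learning

The regressor is scikit-learn's RandomForestRegressor (500 trees, minimum
leaf 3, seed 42 by default; predictions of averaging trees always stay
within the training target range). Feature selection is incremental forward
greedy: starting empty, each step adds the feature maximizing mean k-fold CV
Pearson r, stopping when the improvement stays below 10⁻³ for three
consecutive steps or at the feature cap. Candidate evaluation uses a lighter
forest (30 trees) — the selection signal is a ranking, not a final fit — and
constant columns are skipped; the final model and the reported
cross-validation always use the full forest. Cross-validation is stratified
by sign class (plain k-fold when a class is too small to stratify) and
reports per-fold, mean-over-fold and pooled metrics, since pooled and
averaged summaries can legitimately differ.

Single and multiple mutations are intended as two separate models. A
multi-site vector sums count-type blocks (signature, hydrophobic contacts,
substitution) over sites, averages intensity-type blocks (dynamics, contact
potential, RSA), and appends the site count; sites are processed in a
canonical order so the vector is exactly independent of how the mutation
list was written. Persisted models carry their selected features and a
configuration hash; predicting with a vector from a different feature
configuration is an error, not a silent misalignment.

## Evaluation

Metrics: Pearson r, Spearman ρ, Kendall τ, RMSE, MAE, and a sign-AUC
defined as the probability that a random stabilizing record outranks a
random destabilizing one by predicted ΔΔG (midrank ties; labels from the
observed values). Correlations on constant vectors raise rather than return
a placeholder. "Removing 10% of outliers" is implemented as dropping the
⌈0.1·n⌉ records with the largest absolute residuals (ties resolved by input
order) — the only computable reading of residual-based outlier marking; it
can only lower RMSE. Stratified reports cover sign class, burial
(RSA ≤ 0.30), protein size (≤ 150 residues = small; exactly 150 is assigned
to small since the strict inequalities leave it unassigned) and volume
class; strata under 5 records are flagged insufficient rather than scored.

## Synthetic data

The fixtures module generates everything the tests need:

* **Ideal α-helices** built by NeRF chain extension with ideal bond
  lengths/angles and (φ, ψ) = (−57°, −47°): backbone N, CA, C, O plus CB
  for non-glycines. Consecutive Cα are ~3.8 Å apart with a ~1.5 Å rise.
  Geometry is ideal, not energy-minimized, and side chains stop at Cβ.
* **Packed clusters**: a central alanine progressively buried by carbon
  occluders at 4.2 Å (8 per "shell", up to 64), driving RSA strictly and
  monotonically to zero — the burial fixture for accessibility tests.
* **Planted-signal training sets**: single mutations sampled (with
  replacement) over the interior sites of a 40-residue helix, featurized
  through the real pipeline; ΔΔG = intercept + Σ w_f·feature_f + N(0, σ)
  with σ = 0.1 kcal/mol and n = 500 by default. Five planted features (RSA,
  contact potential, Δvolume, Δhydrophobicity, site fluctuation) span the
  feature blocks; weights are scaled once so each contributes 0.5 kcal/mol
  of spread, giving a realistic ±2 kcal/mol ΔΔG span, and contributions are
  mean-centred so both sign classes are populated. Non-planted columns are
  row-permuted (seeded), so "informative feature recovery" is well defined
  despite the strong structural collinearity of signature counts.

What passing these tests shows: the feature pipeline is deterministic,
rigid-motion invariant and correctly wired end to end, and the selection +
regression stack can find and exploit genuine signal at realistic noise.
What it does not show: predictive accuracy on real proteins. The helices
have no tertiary packing, no full side chains, no crystallographic noise,
and the planted linear target is far simpler than real stability
thermodynamics; numbers obtained on these fixtures are pipeline
diagnostics, not benchmark claims.

## Numerical choices

* Trivial-mode tolerance 10⁻⁸·λ_max; eigenvalues within it are clamped to 0.
* Closed balls everywhere a threshold is compared (≤, never <).
* Signature thresholds must be strictly ascending; violation raises.
* Degenerate inputs raise early with specific errors: empty environment, no
  CA at a site, disconnected network, > 6 zero modes, non-finite features
  (naming the offending columns), zero-variance metric inputs.
* Greedy selection ties break toward the first candidate in column order;
  multi-site aggregation orders sites by (chain, position, insertion code).

## Known limitations

* The bundled contact potential is synthetic; for production use load a
  published AAINDEX contact-energy matrix via the provided readers.
* Only hydrophobic contacts are computed from the interaction taxonomy; no
  hydrogen-bond geometry, aromatic stacking or electrostatics, and
  hydrogens are never added.
* Cα-only NMA with two force fields; no all-atom modes, deformation
  energies or solvent models.
* No mmCIF parsing, no automatic structure download, no symmetry expansion;
  the user supplies the assembly they want analyzed.
* Redundancy control in splits is by protein identifier, not sequence
  identity.
* Published model weights are not reproduced; models are retrained from
  user-supplied or synthetic data.
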