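# Methods

## Overview

`piscore` assesses the quality of protein–protein interfaces in multi-chain
atomic models, independently of any density map, and optionally blends that
assessment with a fit-to-map term for models derived from cryo-EM. The core
quantity is the **PI-score**: the signed decision value of a support vector
machine trained to separate native-like interfaces from non-native
(decoy-like) ones in a twelve-dimensional feature space. Positive scores
call an interface native-like; the magnitude is the confidence of the call.

## Interface definition

A residue of chain A is an *interface residue* iff its Cα lies within 7 Å of
any Cα of chain B (and symmetrically). An interface enters scoring only when
both chains contribute at least 10 residues; smaller contacts are reported
as "below minimum size" and never scored. Residues lacking a Cα (terminal
artifacts) are ignored with a warning. Structurally redundant interfaces
within one assembly (e.g. the three equivalent contacts of a C3 homotrimer)
can be removed by a greedy pass that drops any interface whose structural
similarity to a retained one is ≥ 0.7. The similarity measure is a
superposition overlap: after the best sequence-order-preserving Cα pairing
and least-squares superposition (both side orders are tried, since a
symmetry operation may swap the two sides), the score is the fraction of
interface residues matched within 2 Å, averaged over both directions. It is
a deliberately simple stand-in for a full interface-alignment score and is
not guaranteed to match one on distant cases; at the 0.7 threshold used for
de-duplication the two agree on the symmetric-copy cases that matter here.

## The twelve features

| name | meaning | units |
|---|---|---|
| `num_intf_residues` | interface residues, both chains | count |
| `conserved_interface` | interface residues in the most-conserved quartile of their chain | count |
| `charged` | fraction of interface residues that are Asp/Glu/Lys/Arg | [0,1] |
| `polar` | fraction Ser/Thr/Asn/Gln/His/Tyr | [0,1] |
| `hydrophobic` | fraction Ala/Leu/Ile/Val/Phe/Trp/Cys/Met | [0,1] |
| `contact_pairs` | inter-chain heavy-atom pairs ≤ 4.5 Å between interface residues | count |
| `sc` | shape complementarity statistic | [−1,1] |
| `hb` | donor–acceptor atom pairs ≤ 3.5 Å across the interface | count |
| `sb` | opposite-charge residue pairs with charged-group atoms ≤ 4.0 Å | count |
| `int_solv_en` | solvation energy change on complexation | kcal/mol |
| `p_value` | specificity of interface hydrophobicity (patch permutation test) | [0,1] |
| `int_area` | half the solvent-accessible area buried on complexation | Å² |

Gly, Pro and unrecognised residues belong to none of the three composition
classes, so the three fractions sum to at most 1. Modified residues with an
obvious parent (MSE → Met, etc.) are classified as the parent.

### Surface areas (SASA)

Shrake–Rupley sphere sampling with a deterministic Fibonacci lattice
(default 960 points per atom; no RNG anywhere in the geometry stack). Radii
are a bundled Chothia-style protein set (C 1.87, N 1.65, O 1.40, S 1.85 Å)
with a 1.4 Å probe; only heavy atoms are considered. At 960 points the
total SASA of a test chain is converged to better than 1 % against a
4000-point reference, and single-sphere / two-sphere fixtures agree with
the closed-form areas to 1–2 %. Interface area is
(SASA(A) + SASA(B) − SASA(AB)) / 2 with each chain's isolated SASA computed
in place (no re-centering).

### Shape complementarity (Sc)

Each chain's dot surface is built in isolation: per heavy atom,
`density·4πr²` Fibonacci dots at the van der Waals radius with outward unit
normals, keeping dots whose solvent-accessible counterpart is not occluded
by a neighbour. The *interface patch* of a chain consists of the dots whose
solvent-accessible point becomes buried inside the partner's probe-expanded
spheres on complexation — the surface that actually loses solvent contact —
minus a 1.5 Å peripheral rim. (An earlier distance-band patch definition —
all dots within 8 Å of the partner surface — proved degenerate on small
chains, where the band wraps around the back of the molecule and dilutes
the statistic toward zero; the buried-patch definition is the one the
original shape-correlation statistic intends.) Each patch dot x pairs with
the nearest partner-surface dot x′ and scores

    S(x) = (n_x · −n_x′) · exp(−w · d(x, x′)²),  w = 0.5 Å⁻²

and Sc is the mean of the two per-surface medians. Dot density (15 Å⁻²),
w, the pair-distance cap (8 Å) and the trim width are all exposed in
`ScParams`. Sc is symmetric in the chain order by construction and is
reported signed: anti-correlated surfaces can score below zero, which the
[0,1] description of tightly meshed native interfaces never reaches in
practice. On flat-slab fixtures Sc reaches ≥ 0.95 in tight contact and
decreases strictly with the inter-slab gap.

### Hydrogen bonds and salt bridges

Distance-only criteria over explicit atom tables; no angular terms, because
the aim is a reproducible count of *potential* bonds, not a full geometry
check. Donors: backbone N (except Pro) plus side-chain N/O/S donors per
residue type; acceptors: backbone O/OXT plus side-chain acceptors. Hydrogen
bonds are counted per donor–acceptor atom pair; salt bridges per residue
pair (a bidentate Arg–Asp contact counts once). Both conventions are stated
in the report header. Counts are non-increasing as the distance criteria
tighten.

### Solvation energy

Eisenberg–McLachlan atomic solvation parameters (cal mol⁻¹ Å⁻²: C +16,
neutral N/O −6, carboxylate O −24, charged N −50, S +21), bundled as a
documented data file. The energy is Σ σ(class) · ΔASA / 1000 over all heavy
atoms, where ΔASA is the per-atom area change from isolated chain to
complex. Burying apolar area is favourable (negative); the value tends to 0
as the chains separate, and it scales linearly with buried area by
construction.

### Hydrophobic p-value

The published feature is a probability that the interface is a specifically
hydrophobic patch; its original algorithm is not public, so the package
defines it as a seeded permutation test. Surface residues of the two
isolated chains (isolated SASA ≥ 5 Å², Cα present) form a pool; random
connected patches of the same residue count as the interface are grown by
Cα adjacency (10 Å graph) from a random seed residue. Each patch is scored
by its mean per-residue burial energy gain (−Σ σ·ASA/1000, more negative =
more hydrophobic), and

    p = (1 + #{patches with gain ≤ observed}) / (n_samples + 1)

so p ∈ [1/(n+1), 1]. Under the null (interfaces drawn by the same
procedure) p is approximately uniform; an interface engineered as the most
hydrophobic patch on a fixture scores p ≤ 0.05. The test needs the surface
pool to be at least twice the interface size; otherwise the feature is
imputed at 0.5 and flagged. On the bundled helix-pair toys the interface
often covers about half of each chain, so this imputation path is common
there — a property of the toys, not of real assemblies.

### Conservation

Conservation is ingested, never computed: a three-column table
(chain, seq_id, score) in the Rate4Site convention (lower = more
conserved). An interface residue counts as conserved when it lies in the
most-conserved quartile of its chain (cutoff configurable). Ties at the
quantile boundary are counted fractionally — each tied residue contributes
its share of the remaining quota — and the sum is rounded, so uniform
scores give round(0.25 · interface size) deterministically. Without a
table the count is imputed as 0.25 · num_intf_residues and flagged, keeping
the feature-vector shape stable.

## Decoy generation and training data

The training-set construction mirrors the native / near-native / non-native
(PD1 / PD2 / ND) design, with docking replaced by seeded rigid-body
perturbation so no external corpus or docking program is needed. Toy
complexes are two idealized chains (default: two antiparallel 28-residue
helices, Cα rise 3.8 Å along the contour, backbone + Cβ atoms, 0.25 Å
coordinate jitter, sequences drawn from globular-surface composition
weights) packed to form an interface of ~14 residues per side. Chain B is
rotated about its centroid (axis uniform on the sphere) and translated;
poses are rejection-sampled until the measured interface recovery and RMSD
satisfy the class rule:

* near-native: f_Nal ≥ 0.7 **and** iRMSD ≤ 3 Å
  (sampling ranges: 0–8°, 0–1.5 Å)
* negative: f_Nal < 0.3 **or** iRMSD > 4 Å
  (ranges 10–120°, 2–10 Å, with half the draws biased toward the partner
  to include sterically clashing as well as loose/displaced poses)

Poses in the gap between the two regions are discarded, the regions being
disjoint by construction. Negatives must still present a ≥ 10-residue
interface so their features are computable — the analogue of scoring docked
(not merely separated) poses. iRMSD is the RMSD over the native interface
Cαs after optimal (Kabsch) superposition, Cα-only; f_Nal is the fraction of
native interface residues recovered in the model interface, with residue
correspondence by identical (chain, seq_id) keys by default.

Feature vectors that fail hard (e.g. surfaces not in contact) are logged
and skipped, mirroring the drop of feature-incomplete interfaces in the
original dataset construction.

## Classifier and PI-score

`InterfaceClassifier` is a scikit-learn estimator wrapping standardization
(fitted on training rows only) and an SVM (RBF kernel, C = 1,
gamma = "scale"; linear kernel available). The kernel and hyperparameters
of the published model are not stated, so its absolute score scale (the
±2.5 reliability thresholds) is not reproducible bit-for-bit — only its
construction is. The PI-score is the raw SVM decision value; its sign is
the predicted class, and sign(decision) == predict() is exercised as a test
contract. Alternative learners (random forest, MLP, gradient boosting)
train through the same interface for performance comparison and expose
2·P(native) − 1 as a comparable signed score.

Cross-validation is ten independent stratified 70/30 shuffle resamples
("stratified shuffle split with ten splits" read literally, not 10-fold
partitioning), reporting accuracy, precision, recall, F1 and MCC per split;
the final model refits on all rows. Model variant "A" trains on
decoy-derived rows only (provenance PD2+ND); variant "B" (default) uses
everything. On the default generated decoy dataset (5 toy complexes,
200 decoys per class plus natives) the 10-split mean CV accuracy exceeds
0.90 — the desk-scale analogue of the published 86 % validation accuracy,
which would require the original PDB-derived corpus. Undefined metrics
(0/0) are reported as missing, never as 0. Trained SVMs serialize to a
versioned JSON text file (scaler parameters, support vectors, dual
coefficients, intercept, config, training checksum); ensemble/NN variants
are not serialized to this format.

Feature importance is ranked by five methods (Ridge, random forest, RFE,
linear regression, Lasso; sklearn defaults), each min–max normalized to
[0,1] and averaged. A single planted informative feature reliably attains
the top mean rank.

## Density-based scores

Simulated model maps place a unit-amplitude isotropic Gaussian of width
σ = 0.356 · resolution (a common blurring convention; configurable) on each
heavy atom, on a cubic grid padded ≥ 3σ beyond the model. Global CCC is the
Pearson correlation between the experimental map and the simulated map
resampled onto its grid by trilinear interpolation, over a mask (default:
voxels above the simulated map's mean; unmasked and custom masks
available). Per-residue scores are overlap coefficients
Σuv/√(Σu²·Σv²) over voxels within max(3.0, 0.5·resolution) Å of the atoms
of each residue ± 1 chain neighbour — a local Manders-style fit score in
[0,1] for non-negative maps. iCCC is the arithmetic mean of the per-residue
scores over the interface residues (missing residues excluded with a
warning). Map I/O is MRC/CCP4 via gemmi, with axis order canonicalized,
origin taken from the ORIGIN header record with fallback to
nstart · voxel, and mode-2 float output.

## Weighted combined score

The PI-score is normalized with saturation at |2.5| (the score magnitude
beyond which calls are essentially always right in the published bin
analysis):

    norm = min(pi/2.5, 1)  if pi > 0;   max(pi/2.5, −1)  if pi < 0;   0 at 0

The weight w1 is the index of the 0.1-wide bin containing |norm|
(w1 = ceil(10·|norm|) ∈ 0..10, with a value sitting exactly on a bin edge
kept in the lower bin), and

    combined = (w1 · norm + w2 · iCCC) / (w1 + w2),   w2 = 10.

The published description of w1 ("the respective indices for the score") is
ambiguous; the upper-bin-index rule is fixed here because it reproduces
both published worked examples (−0.12 and 0.43 at PI ∓1.67, iCCC 0.27),
and the test suite brute-forces the candidate rules
({floor, round, ceil} × {signed, absolute}) to confirm that signed-index
and floor rules fail. (round coincides with ceil at the two printed
magnitudes, whose fractional parts exceed 0.5; ceil is the rule that is a
genuine bin index covering (0, 1].) The TFIID example evaluates to −0.26
against a printed −0.27; the printed inputs are themselves rounded to 2–3
significant figures, which accounts for the last-digit difference. The
combined score lies in [−1, 1], is monotone in iCCC for fixed PI-score,
and equals iCCC exactly when the PI-score is 0.

## Numerical and policy choices

* Only model 1 of multi-model files; altlocs resolved to highest occupancy
  (ties alphabetical); waters, ligands and nucleic acids dropped;
  hydrogens retained but excluded from all heavy-atom computations.
* Residue identity is (chain, seq_id, insertion_code) in author numbering.
* All dot/point sampling is a deterministic Fibonacci lattice; the only RNG
  is in decoy sampling, sequence drawing and the p-value permutation test,
  all governed by explicit seeds.
* Kabsch superposition rejects < 3 points and rank-deficient (collinear)
  point sets; the proper-rotation branch uses the sign-corrected SVD.
* Degenerate inputs fail loudly with named errors (zero-variance
  correlation regions, empty dot surfaces, single-class training data,
  confusion tables with all-zero counts).

## What the synthetic generators do and do not show

The toy complexes have ideal backbone geometry, no side chains beyond Cβ,
no physical packing optimization and no evolutionary signal; decoys are
rigid-body perturbations without re-docking or side-chain repacking. They
exercise every feature extractor, the class-construction rules and the
full training/scoring path with strong, controllable class signal. Passing
tests therefore demonstrate correctness of the machinery and the expected
qualitative orderings (native > loose decoy in Sc, favourable solvation on
burial, uniform p-value null), not the absolute performance figures
obtainable on real crystal-structure corpora. Problem sizes used in the
test suite — 28-residue chains, ~200 decoys per class, 960 SASA points,
dot density 15 Å⁻² — were chosen as the smallest sizes at which these
properties are stable.
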