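# Methods

This note documents the models, conventions and design choices behind
`pepatlas`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Curation model

A raw entry is a set of protein chains with author numbering, occupancies
and altlocs (PDB or mmCIF, parsed with gemmi; hydrogens, waters and
non-amino-acid residues are dropped, and only blank/'A' altlocs are kept
before any occupancy check). Chains are classified by sequence only:

- *heavy chain*: global alignment identity > 50% to a 180-residue
  reference platform sequence (BLOSUM62, gap open −11 / extend −1,
  identity = matches / reference length);
- *β2-microglobulin*: same rule against a β2m reference when supplied
  (β2m presence is not required for retention);
- *peptide*: chain length 8–10 residues;
- everything else: *other*.

Retention filters: numeric resolution ≤ 3.0 Å (read as "3.0 Å or better");
no *other* chain atom within 5 Å of any peptide atom (the converse of the
stated retention rule — an interpretation, flagged here); complete
peptide backbone heavy atoms (N, Cα, C, O) with positive occupancy;
≥ 180 heavy-chain residues. Zero-occupancy heavy-chain atoms produce a
warning flag, not a rejection. Heavy chains missing 1–2 N-terminal
residues are flagged `rebuilt_nterm_needed`; rebuilding is out of scope,
so such entries are excluded from geometry analyses. When an asymmetric
unit contains several pHLA copies, the first complete assembly in chain
order is curated and the rest are ignored.

Accepted entries are trimmed to the first 180 heavy-chain residues
(platform, renumbered 1–180, chain "A") and the peptide (renumbered 1–n,
chain "C"), then typed by pairwise alignment against every allele in the
user-supplied reference FASTA (maximal identity; ties break to the
lexicographically smallest allele name; identity ≤ 50% is a typing
failure). The dataset summary FASTA carries
`PDB ID|chain|allele|release date|resolution` headers and round-trips
losslessly. Curation is idempotent: re-curating a curated file returns an
identical record.

The entry date is taken from the deposition date in the coordinate header
(the only date a PDB-format header reliably carries); for historical
analyses it stands in for the release year.

## Backbone geometry

Dihedrals follow the IUPAC convention, degrees in (−180, +180], with φ
undefined at residue 1 and ψ at residue n. Chains are rebuilt from
dihedrals by sequential NeRF placement with fixed covalent geometry:

| parameter | value |
|---|---|
| N–Cα, Cα–C, C–N, C=O | 1.458, 1.525, 1.329, 1.231 Å |
| N–Cα–C (τ) | 109.5° |
| Cα–C–N, C–N–Cα, Cα–C–O | 117.2°, 121.7°, 120.5° |
| ω | 180° (planar trans) |

Bond lengths and the carbonyl/amide angles are standard ideal values; τ
is kept at the tetrahedral angle, the idealisation simple fragment
builders use. This choice is deliberate: it is calibrated so that a
uniform PPII nonamer (φ=−75°, ψ=+145°) reproduces the published 21.4 Å
P2–P9 Cα distance within ±0.2 Å (the package computes 21.475 Å); with
Engh–Huber-style τ ≈ 111° the same construction lands near 21.67 Å,
outside that band. The build↔measure round trip is exact to well below
1e-6 degrees, which the suite asserts for arbitrary dihedrals.

The anchor-distance Ramachandran surface scans a 1° lattice from −180° to
+180° on both axes (361 points per axis; the duplicated ±180° column is
retained deliberately, so the periodic boundary appears on both edges),
building one uniform-dihedral nonamer per cell, vectorised across the
whole grid. The groove-compatibility mask marks cells with P2–P9 distance
in [17.5, 20.0] Å.

Anchor assignment searches *all* peptide residues for the one nearest
each pocket probe (platform residues 24 and 123, Cα–Cα); ties break to
the lowest index for the B anchor and the highest for the F anchor.
RMSD between two complexes is evaluated in the groove frame: Kabsch
superposition on platform Cα atoms, then unfitted RMSD over the requested
peptide positions and atom set.

## D-score

D(θ₁,θ₂) = 2(1 − cos(θ₁−θ₂)) per angle; the backbone score sums D(φ) and
D(ψ) over the central window — P4–P7 for Δ7 (8 terms), P4–P6 for Δ6,
P4–P8 for Δ8. The Δ7 neighbor criterion is ≤ 1.5 ("≤", not "<": the two
phrasings coexist in the source analysis and the inclusive form is
adopted); other classes scale the threshold by angle count (Δ6: 1.125,
Δ8: 1.875). The scaled values are an inference from the stated
proportionality, not independently published numbers — user-visible in
the docstring. Structures with undefined window dihedrals are excluded
from pairwise matrices rather than imputed, and listed as such.

## Greedy atlas

On the thresholded adjacency matrix the selection repeats: recompute
neighbor counts on the remaining structures, take the maximum (ties:
lexicographically smallest id), remove it and its remaining neighbors.
Counts are recomputed each iteration on the reduced matrix; removals
within an iteration happen once, exactly as stated. The result is a
partition (each structure appears in exactly one representative set) and
is invariant to input order, which the suite checks, along with exact
agreement with a brute-force re-implementation on random 20-node graphs.
The historical analysis reruns the full selection on each year's
cumulative subset. PCA featurization uses sin(φ), sin(ψ) over P4–P7
(sines keep the circular coordinates continuous), standardised before a
2-component PCA. Supertype assignments are configuration data supplied by
the user, never hard-coded.

## Sequence-bias analysis

Central positions P3–P8 are enumerated as the cartesian product of
per-position alphabets in lexicographic order. The packaged alphabet TSV
is a clearly-labelled synthetic transcription stand-in: the published
per-position sets are defined by a similarity-matrix cutoff whose full
table is not reproduced here, but their sizes are pinned by the published
space size — 8·9·9·10·11·11 = 784,080, the unique size multiset in the
stated 8–11-plus-proline range — and the shipped sets reproduce those
sizes with proline at every position. Users substitute their own TSV via
`load_alphabets`.

Top-fraction selection keeps floor(f·N) lowest-energy candidates (floor,
not round: 784,080 → 7,840), breaking ties by input order. PPM cells
that would be zero are set to 0.02 and columns are *not* renormalised —
the floor patches zeros only, so flanked columns sum to slightly more
than 1; KL divergence (Σ p ln(p/q), natural log, via `scipy.special.rel_entr`)
consumes the matrix exactly as built. This mildly improper distribution
is intentional and documented rather than silently corrected.

Energy scoring is a pluggable callable; the packaged `motif_scorer` is a
deterministic synthetic surrogate (planted motif bonus + CRC-derived
pseudo-noise) for tests only and implies no physics.

## Template ranking

Candidate hygiene: (target, template) pairs whose peptides differ at ≤ 3
of 9 positions are homologs and removed; refined candidates that drift
more than D-score 1.5 from their template crystal are dropped; templates
whose relaxed copy moves more than D-score 1.0 are screened out of the
template set. Training rows with true D-score > 7 are excluded from
fitting (extreme failures add no ranking signal).

The regressor is an RBF-kernel SVR on uniform-quantile-transformed
features. C and epsilon are chosen by grid search over nine powers of ten
each (1e-4..1e4) using mean R² over 5-fold inner cross-validation on the
training split; an inner CV (rather than training-set R²) is used because
training-set R² degenerates toward the largest C. The transform lives
inside the cross-validated pipeline, so no held-out information reaches
either the transform or the hyperparameter choice — the suite asserts
this directly. Feature count is opaque to the pipeline (the reference
configuration uses 129 per-residue energy terms; any `f1..fF` schema
works).

Selection is argmin of predicted D-score; with an abstention threshold
set (2.0 in the non-A02 operating mode) no model is reported unless the
minimum prediction is below it. The leave-one-target-out benchmark
removes *all* rows of the held-out target before refitting, marks success
at true D-score ≤ 1.5, and reports overall accuracy, accuracy inside vs
outside the most common backbone class (a target's class is the template
with its lowest true D-score), and the expected accuracy of uniformly
random template choice. Fitted models persist as versioned JSON
(quantile landmarks + SVR support data); prediction after reload
re-evaluates the RBF expansion directly and matches the in-memory
pipeline to ~1e-9 on continuous features.

## Synthetic data

The fixture generator emulates only what downstream code reads:

- *Toy complexes*: a peptide built from dihedrals sampled around
  configurable means (PPII by default, matching the conserved groove-bound
  conformation) and a dummy 180-residue platform whose only load-bearing
  geometry is the two pocket-probe Cα positions, placed 3 Å from the
  requested anchor residues along the direction of maximal clearance.
  Optional decorations (an "other" chain at a set distance, a
  zero-occupancy atom, off-spec resolution) exercise each filter.
  Reference alleles are deterministic synthetic sequences, not real HLA.
- *Backbone families*: Gaussian dihedral perturbations (default 2°)
  around a centre; small spreads make all members mutual neighbors, which
  mirrors the tight conformational families seen in real data.
- *Feature tables*: per-pair true D-scores (one planted low-error
  template per target, the rest folded-normal around 3) with the first
  three features affine in the true score plus configurable noise, the
  remainder pure noise.

What passing tests on these fixtures do **not** show: real crystal
structures carry correlated coordinate error, non-ideal covalent geometry,
alternate conformations and genuinely physical energy features; the
synthetic platform has no groove, so curation's contact filter and anchor
assignment are tested on geometry, not chemistry; and the planted
feature→error relation is far cleaner than ref2015-style energies. The
two acceptance checks that quantify behaviour on real structures
therefore require user-supplied coordinate files (see
`tests/test_acceptance.py`) and report their absence otherwise.

## Problem sizes and numerical choices

Test-suite simulations are sized for a deep-but-quick default run: the
Ramachandran surface is computed at the full 1° lattice (130,321 chain
builds, vectorised, ~1 s); greedy-oracle comparisons use 20-node random
graphs; regression tests use 15–30 targets × 8 templates with a reduced
2×2 hyperparameter grid and 3-fold inner CV (the full 9×9×5 default
remains the library default); the top-fraction acceptance check uses the
full 784,080-candidate pool. Degenerate inputs are handled explicitly:
constant features pass through the quantile transform (logged by
sklearn), empty candidate sets yield abstentions with reasons, undefined
dihedrals propagate as NaN and exclude structures from matrices.

## Interface shape

The regression layer follows the model/results idiom
(`TemplateRankingModel.fit()` → `TemplateRankingResults` with
`summary()`), since a model fitted to data is genuinely the core there.
The curation/geometry/atlas layers are plain functions over small
dataclasses with a thin `click` CLI — they are pipeline stages, not
fitted models, and a Results object would be ceremony.

## Known limitations

- Anchor classes outside {6, 7, 8} are unsupported, mirroring the
  observed classes; noncanonical-anchor decamers are flagged, not
  truncated.
- The curation date is the deposition date, which can precede release.
- The Δ6/Δ8 thresholds are proportional inferences (see above).
- Threading/refinement and physical energy evaluation are external by
  design; the package treats their outputs as inputs.
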