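# Methods

## The problem and the model

HLA-DQ2.5 and HLA-DQ8.1 are MHC class II heterodimers whose carriage
predisposes to celiac disease; they present gluten-derived peptides to CD4+
T cells. A peptide binds with a nine-residue core (positions p1–p9) in the
open groove, with flanking residues (p−1, p0, p10, p11) extending beyond it.
`dockqm` implements a docking-based route to a predictive model of this
binding: a position × amino-acid **quantitative matrix (QM)** derived from the
docking affinities of a single-amino-acid-substitution (SAAS) combinatorial
library, plus the screening and validation machinery built on top of it.

### SAAS libraries

A parent peptide bound in a known register (e.g. the α-gliadin 11-mer
QPFPQPELPYP in HLA-DQ2.5, or the 13-mer SGEGSFQPSQENP in HLA-DQ8.1 with its
terminal p−1/p11 residues held fixed) is expanded position by position: the
residue at each open position is replaced by each of the 19 alternative
standard amino acids, one substitution per peptide. With 11 open positions
(p0–p10) the library has 19 × 11 + 1 = 210 members. Variants are ordered by
position and then alphabetically by residue so that peptide identifiers are
stable across runs; cysteine is not excluded from the substitution alphabet.

### From affinities to a matrix

Docking produces one best affinity s (kcal/mol, more negative = stronger) per
library member. Pose lists are filtered to the energy window above the best
pose before taking the minimum; this cannot change the best score, and is kept
because the retained pose count is part of the docking protocol's provenance.

Let N be the **normalization set**: the parent plus every variant whose
substitution falls within the matrix's covered positions, and μ the mean
affinity over N. The default contribution of residue *a* at position *L* is

    c(L, a) = s(L, a) / μ − 1,

with the parent's own affinity supplying s at each position's wild-type
residue. Because realistic affinities are negative, stronger-than-average
binders get positive coefficients (positive = favourable), the mean of c over
N is exactly zero, the matrix is invariant to rescaling all affinities by a
positive constant, and within a position c is a strictly decreasing affine
function of affinity — so noise-free additive inputs are recovered with
Spearman correlation −1 between planted per-position energies and
coefficients. The exact functional form of "mean-normalization" admits
alternatives; μ − s and the z-score (s − μ)/σ are selectable via
`build_qm(..., formula=...)` but non-default, and only the default is covered
by the validation suite.

Two normalization modes mirror the nonamer/endecamer matrices of the
workflow:

* `core` — covers p1–p9; N has 9 × 19 + 1 = 172 members;
* `whole_peptide` — covers p0–p10; N has 11 × 19 + 1 = 210 members.

Whether flank-substituted variants should enter μ in core mode is genuinely
open; `dockqm` excludes them (the mode's covered positions define N), which
keeps the mean-zero identity exact per matrix. A known artefact of SAAS
designs is that the wild-type residue's coefficient is identical across
positions, since a single parent affinity is reused at all of them.

### Scoring, decoys, validation

A peptide's score is the sum of coefficients over its core positions (plus
p0/p10 where the matrix covers them; a flank missing at a protein terminus
contributes 0). Peptides and proteins longer than 9 residues are scanned over
all L − 8 registers and the maximum is reported, with ties broken to the
smallest offset. Windows containing non-standard residues (X, B, Z, U…) are
skipped and counted, not imputed; a non-standard residue in a flank position
only makes that flank contribute 0. The binder call is **score ≥ cutoff**
(inclusive).

Non-binder decoys follow the validation-set construction of the underlying
study: a random combination of non-preferred residues — negative coefficient,
threshold 0 by default — at all nine core positions (flank residues, when the
requested length exceeds 9, are uniform over the full alphabet, with the core
centred and extra residues split evenly, leading side first). Any decoy's
core score is therefore a sum of strictly negative terms, guaranteeing
separation from peptides built of positive-coefficient residues.

Validation scans cutoffs over an inclusive grid, by default −0.5 to +0.5 in
steps of 0.1, generated by exact rational arithmetic so printed cutoffs are
hit without float drift. Sensitivity = 100·TP/(TP+FN), specificity =
100·TN/(TN+FP), accuracy = 100·(TP+TN)/total; the selected cutoff maximizes
accuracy, ties broken to the lowest cutoff, then to the highest sensitivity.
Percentages are stored at full precision and displayed rounded half-up to
integers.

## The synthetic docking simulator

Real docking runs are out of scope; the simulator stands in for the engine so
the whole derivation is testable at desk scale. It plants an additive energy
model: affinity = base + Σ per-position residue increments (deltas) +
Gaussian noise from one seeded stream consumed in library order. Deltas are
i.i.d. uniform on [−spread, +spread] — uniform rather than Gaussian so that
preferred/non-preferred residues are bounded and binder/decoy constructions
have guaranteed separation. Defaults: base −7.0 kcal/mol and spread
1.0 kcal/mol, echoing typical docking-score magnitudes; noise defaults to 0
(the exact-recovery regime), with 0.1 kcal/mol used as the noisy-recovery
condition in the test suite.

The demonstration pipeline parametrizes the planted model **relative to the
parent peptide**: the parent residue's delta is pinned to 0 at every position,
so the base affinity is the parent's exact noise-free score. This mirrors a
SAAS experiment around a known binder and guarantees (up to a ~10⁻⁵-per-seed
tail event) that every core position has both positive- and
negative-coefficient residues, which the binder/decoy construction requires.
Without pinning, the parent residue is the per-position extremum somewhere in
the register for most seeds, and the decoy recipe would be ill-posed there.

What the simulator deliberately does **not** emulate: pose geometry, backbone
conformation effects (the rigid poly-proline gliadin backbone versus flexible
non-gliadin binders, which real docking resolves and which drive
position-specific preference differences), non-additive coupling between
positions, and deamidation chemistry. Consequently, passing tests demonstrate
that the derivation pipeline recovers additive structure from docking-style
scores and that its classification machinery is correct — not that any
particular accuracy will be achieved on experimentally measured binder sets,
which depend on the docking engine and on real peptide–HLA physics.

## Numerical and design choices

* Position labels are symbolic (p−1…p11) and mapped to sequence offsets via
  the parent's `core_start`; all file output reports labels.
* Sequences are forced to upper case; any character outside the 20 standard
  one-letter codes is an error at parent construction.
* μ = 0 (and zero score variance for the z-score formula) are rejected as
  degenerate normalizations rather than propagated as infinities.
* Inter-matrix comparison is the Pearson correlation of the 20 paired raw
  coefficients at a position; a position with zero variance raises an
  `UndefinedCorrelationError` instead of silently reporting 0.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the demo derives its binder/decoy seeds as seed+1/seed+2 and stamps
  seed and a configuration hash into every text artifact it writes (FASTA has
  no comment syntax; its provenance lives in the paired manifest).
* Unicode minus signs in pasted docking logs are normalized to ASCII before
  numeric parsing.

## Problem sizes in the test suite and reproduction script

The demonstration pipeline and reproduction script use the full study-scale
validation set — 4249 synthetic binders and 4249 decoys, matching the size of
the external test set used for the original HLA-DQ2.5 matrices — and complete
in about a second. Additive-scoring verification uses 100 random 9–25-mers
against a brute-force window-enumeration oracle; unit tests use smaller decoy
batches (hundreds) where the property checked does not depend on the count.

## Known limitations

* The parent residue's identical coefficient across positions (see above)
  slightly distorts within-position rankings around the wild type when noise
  is present.
* Longer-peptide scoring assumes the best register; experimentally determined
  registers may differ.
* Table-style headline accuracies on experimentally eluted binder sets are
  not reproducible here: they require the external mass-spectrometry datasets
  and real docking runs. The property-based suite (exact normalization
  identity, brute-force additivity, planted-parameter recovery, end-to-end
  separation, metric correctness) is the validation surface of this package.
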