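# dockqm

Docking-derived **quantitative matrices (QMs)** for predicting peptide binding
to HLA-DQ2.5 and HLA-DQ8.1, the MHC class II alleles associated with celiac
disease. The package is aimed at immunoinformaticians and food-safety risk
assessors who need to screen novel proteins — up to whole proteomes — for
potential HLA-DQ binders without running binding assays for every candidate
peptide.

## The method

A parent peptide bound in a known register (e.g. the α-gliadin 11-mer
QPFPQPELPYP in HLA-DQ2.5) is expanded into a **single amino acid substitution
(SAAS)** combinatorial library: each open position is substituted with the 19
alternative residues, one peptide per substitution, giving
19 × 11 + 1 = 210 peptides. Each library member receives one best docking
affinity s (kcal/mol). With μ the mean affinity over the normalization set
(parent + variants substituted within the matrix's positions), the
contribution of residue *a* at position *L* is

```
c(L, a) = s(L, a) / μ − 1
```

so stronger-than-average binders get positive coefficients. A candidate
peptide is then scored additively,

```
score = Σ_{L = p1..p9} c(L, a_L)   (+ p0/p10 terms for flank-covering QMs)
```

over every 9-mer core register, and called a binder when the best register
scores at or above a cutoff chosen by scanning −0.5 … +0.5 in steps of 0.1
for maximal accuracy on a labelled binder/non-binder set. Non-binder decoys
are generated as random combinations of non-preferred (negative-coefficient)
residues at all nine core positions.

Running a docking engine is out of scope: the package parses docking output
(result tables or `REMARK VINA RESULT:` lines) or score tables, and ships a
**synthetic docking simulator** — a planted additive per-position energy model
with Gaussian noise — so the entire derivation is testable and demonstrable at
desk scale. See `docs/methods.md` for the model, its assumptions and its
limits.

## Worked example

```python
from dockqm import (ParentPeptide, build_saas_library,
                    QuantitativeMatrixModel, LabelledSet)
from dockqm.synthetic import sample_ground_truth, simulate_library_scores
from dockqm.screening import (preferred_from_qm, nonpreferred_from_qm,
                              sample_core_peptides)

parent = ParentPeptide("a-gliadin", "QPFPQPELPYP", core_start=1)
lib = build_saas_library(parent)          # 210 peptides

truth = sample_ground_truth(              # stand-in for the docking engine
    [f"p{i}" for i in range(11)], seed=1,
    reference_residues={pl.label: parent.sequence[pl.offset]
                        for pl in parent.labels()},
)
scores = simulate_library_scores(truth, lib)

res = QuantitativeMatrixModel(lib, scores, mode="core",
                              allele="HLA-DQ2.5").fit()
print(res.summary())
```

The summary opens with the fit's provenance (matrix body abbreviated here):

```
Quantitative Matrix Results
==================================================================
Allele:              HLA-DQ2.5
Parent peptide:      a-gliadin (QPFPQPELPYP)
Normalization mode:  core (9 positions, n = 172 peptides)
Formula:             ratio
Mean affinity (mu):  -6.9669 kcal/mol
Docking engine:      synthetic (exhaustiveness 8, energy range 3.0 kcal/mol)
```

μ is the mean simulated affinity over the 172-peptide normalization set; each
matrix cell is that peptide set's mean-normalized score. Scoring a longer
peptide picks the best 9-mer register:

```python
best, register, _ = res.score_peptide("LQPFPQPELPYPQPQL")
# best score 0.226 at register 3
```

Validating against 4249 synthetic binders (preferred residues at every core
position) and 4249 decoys (non-preferred residues):

```python
binders = sample_core_peptides(preferred_from_qm(res.qm), 9, 4249, seed=2)
decoys  = sample_core_peptides(nonpreferred_from_qm(res.qm), 9, 4249, seed=3)
scan = res.cutoff_scan(LabelledSet.from_lists(binders, decoys))
print(scan.to_dataframe(rounded=True).to_string(index=False))
```

```
 cutoff   TP   FN   TN  FP  sensitivity  specificity  accuracy
   -0.5 4249    0 3879 370          100           91        96
   -0.4 4249    0 4194  55          100           99        99
   -0.3 4249    0 4246   3          100          100       100
   -0.2 4249    0 4249   0          100          100       100
   ...
    0.5 2692 1557 4249   0           63          100        82
selected cutoff: -0.2
```

By construction the two classes separate perfectly at some grid cutoff
(here −0.2, the lowest cutoff reaching exact 100% accuracy); sensitivity falls
and specificity rises monotonically with the cutoff, as they must under the
inclusive `score ≥ cutoff` call rule.

## Command line

Every stage is also a subcommand of `dockqm`:

```sh
dockqm saas-lib --parent-id glia --parent-seq QPFPQPELPYP --core-start 1 \
       --out-fasta lib.fasta --out-manifest lib.csv
dockqm simulate-dock --library-fasta lib.fasta --library-manifest lib.csv \
       --seed 1 --out scores.csv
dockqm build-qm --library-fasta lib.fasta --library-manifest lib.csv \
       --scores scores.csv --mode core --allele HLA-DQ2.5 --out qm.csv
dockqm screen --qm qm.csv --fasta proteome.fa --cutoff 0.1 --out hits.tsv
dockqm demo --seed 1 --outdir demo_out     # the whole pipeline in one shot
```

`parse-dock` ingests real docking logs instead of `simulate-dock` when engine
output is available. The 13-mer HLA-DQ8.1 parent is handled with
`--parent-seq SGEGSFQPSQENP --core-start 2 --fixed p-1,p11`.

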