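"""Quantitative matrices: mean-normalized per-position amino-acid contributions.

A quantitative matrix (QM) turns the best docking affinities of a SAAS library
into a position x amino-acid table of dimensionless contribution coefficients.
Let N be the normalization set -- the parent plus every variant whose
substitution falls within the matrix's covered positions -- and mu the mean
affinity over N (negative for realistic docking scores). The default
contribution of residue a at position L is

    c(L, a) = s(L, a) / mu - 1

where s(L, a) is the best affinity of the variant carrying a at L, and the
parent's own affinity supplies s at each position's wild-type residue. Because
affinities are negative, a stronger-than-average binder (s below mu) gets a
positive coefficient: positive = favourable, negative = unfavourable. The mean
of c over N is exactly 0, the matrix is invariant to rescaling all affinities
by a positive constant, and within a position c is a strictly decreasing
affine function of affinity.

Two normalization modes mirror the nonamer/endecamer matrices of the
workflow: ``core`` covers p1..p9 (N has 9 x 19 + 1 = 172 members), and
``whole_peptide`` covers p0..p10 (N has 11 x 19 + 1 = 210 members).

A statsmodels-style surface is provided by :class:`QuantitativeMatrixModel`
(data in) and :class:`QMResults` (estimates, diagnostics, screening and
validation methods out).
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .docking import DockingConfig, ScoreTable, read_score_table
from .peptide_library import (
    AMINO_ACIDS,
    CORE_LABELS,
    CombinatorialLibrary,
    label_offset_index,
    read_library,
)

NormalizationMode = Literal["core", "whole_peptide"]

#: Covered position labels per normalization mode.
MODE_LABELS: dict[str, tuple[str, ...]] = {
    "core": CORE_LABELS,
    "whole_peptide": ("p0",) + CORE_LABELS + ("p10",),
}

#: Normalization formulas. ``ratio`` (s/mu - 1) is the default and the only
#: one the validation suite targets; the alternatives invert or rescale the
#: sign convention and are provided for sensitivity analyses.
FORMULAS = ("ratio", "mu_minus_s", "zscore")


class UndefinedCorrelationError(ValueError):
    """Raised when a position's contributions have zero variance, so the
    inter-matrix correlation there is undefined (never silently reported as 0)."""


@dataclass
class QuantitativeMatrix:
    """Per-position, per-amino-acid contribution coefficients.

    ``contributions`` maps ``(label, aa)`` to a dimensionless coefficient,
    defined for all 20 residues at every covered label. Positive = predicted
    favourable. ``normalization_mean_kcal`` stores mu so any score can be
    mapped back to a pseudo-affinity.
    """

    allele: str
    labels: tuple[str, ...]
    contributions: dict[tuple[str, str], float]
    normalization_mode: str
    normalization_mean_kcal: float
    parent_id: str
    config: DockingConfig = field(default_factory=DockingConfig)
    recommended_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        for label in self.labels:
            missing = [aa for aa in AMINO_ACIDS if (label, aa) not in self.contributions]
            if missing:
                raise ValueError(
                    f"contributions missing residues {missing} at label {label}"
                )

    def contribution(self, label: str, aa: str) -> float:
        if label not in self.labels:
            raise ValueError(f"label {label} not covered by this QM ({self.labels})")
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue {aa!r}")
        return self.contributions[(label, aa)]

    @property
    def covers_flanks(self) -> bool:
        return "p0" in self.labels or "p10" in self.labels

    def as_dataframe(self) -> pd.DataFrame:
        """Matrix view: rows = position labels, columns = residues (alphabetical)."""
        data = {
            aa: [self.contributions[(label, aa)] for label in self.labels]
            for aa in AMINO_ACIDS
        }
        return pd.DataFrame(data, index=list(self.labels))


def normalization_set(
    lib: CombinatorialLibrary, covered: Sequence[str]
) -> list:
    """Library members entering the normalization: parent + variants whose
    substituted position is covered."""
    covered_set = set(covered)
    return [
        v for v in lib.variants
        if v.is_parent or v.substituted_label in covered_set
    ]


def build_qm(
    lib: CombinatorialLibrary,
    scores: ScoreTable,
    mode: NormalizationMode = "core",
    allele: str = "",
    formula: str = "ratio",
) -> QuantitativeMatrix:
    """Build a quantitative matrix from a library's best docking scores.

    Parameters
    ----------
    lib, scores
        The SAAS library and one best affinity per member; every library
        member must be scored.
    mode
        ``core`` (positions p1..p9) or ``whole_peptide`` (p0..p10).
    formula
        ``ratio`` -> s/mu - 1 (default); ``mu_minus_s`` -> mu - s;
        ``zscore`` -> (s - mu)/sigma over the normalization set (note this
        one makes favourable residues negative).
    """
    if mode not in MODE_LABELS:
        raise ValueError(f"mode must be one of {sorted(MODE_LABELS)}, got {mode!r}")
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
    covered = MODE_LABELS[mode]
    not_mutable = [l for l in covered if l not in lib.parent.mutable_labels]
    if not_mutable:
        raise ValueError(
            f"labels {not_mutable} required by mode {mode!r} are not mutable in "
            f"the library, so their 19 substitutions are missing"
        )
    missing = [v.peptide_id for v in lib.variants if v.peptide_id not in scores]
    if missing:
        raise ValueError(f"missing scores for library members: {missing}")

    norm_set = normalization_set(lib, covered)
    affinities = np.array([scores[v.peptide_id] for v in norm_set], dtype=float)
    mu = float(affinities.mean())
    if mu == 0.0:
        raise ValueError("mean affinity over the normalization set is 0; "
                         "normalization is degenerate")

    if formula == "ratio":
        def transform(s: float) -> float:
            return s / mu - 1.0
    elif formula == "mu_minus_s":
        def transform(s: float) -> float:
            return mu - s
    else:  # zscore
        sigma = float(affinities.std(ddof=0))
        if sigma == 0.0:
            raise ValueError("zero score variance; z-score normalization is degenerate")
        def transform(s: float) -> float:
            return (s - mu) / sigma

    parent = lib.parent
    parent_affinity = scores[lib.parent_variant.peptide_id]
    contributions: dict[tuple[str, str], float] = {}
    # wild-type residue at every covered position reuses the single parent
    # affinity (an artefact of SAAS designs: it is identical across positions)
    for label in covered:
        contributions[(label, parent.residue_at(label))] = transform(parent_affinity)
    for v in lib.variants:
        if v.is_parent or v.substituted_label not in covered:
            continue
        contributions[(v.substituted_label, v.substituted_aa)] = transform(
            scores[v.peptide_id]
        )

    return QuantitativeMatrix(
        allele=allele,
        labels=covered,
        contributions=contributions,
        normalization_mode=mode,
        normalization_mean_kcal=mu,
        parent_id=parent.id,
        config=scores.config,
    )


def compare_qms(
    qm_a: QuantitativeMatrix,
    qm_b: QuantitativeMatrix,
    label: str | None = None,
) -> float | pd.Series:
    """Pearson correlation of the 20 paired contributions at one position.

    With ``label=None``, returns a Series over all shared positions. Raw
    coefficients are correlated (no rank transform). A position with zero
    variance in either matrix raises :class:`UndefinedCorrelationError`.
    """
    if label is None:
        shared = [l for l in qm_a.labels if l in qm_b.labels]
        if not shared:
            raise ValueError("the two QMs share no position labels")
        return pd.Series(
            {l: compare_qms(qm_a, qm_b, l) for l in shared}, name="pearson_r"
        )
    if label not in qm_a.labels or label not in qm_b.labels:
        raise ValueError(f"label {label} not covered by both QMs")
    x = np.array([qm_a.contributions[(label, aa)] for aa in AMINO_ACIDS])
    y = np.array([qm_b.contributions[(label, aa)] for aa in AMINO_ACIDS])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            f"zero contribution variance at {label}; correlation undefined"
        )
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# serialization: YAML front-matter + CSV matrix (labels x 20 residues)

def write_qm(qm: QuantitativeMatrix, path: str | Path) -> None:
    """Write a QM as YAML front-matter (between ``---`` fences) followed by a
    CSV matrix with one row per position label and one column per residue,
    at full float precision."""
    meta = {
        "allele": qm.allele,
        "normalization_mode": qm.normalization_mode,
        "normalization_mean_kcal": qm.normalization_mean_kcal,
        "parent_id": qm.parent_id,
        "config": qm.config.to_dict(),
        "recommended_cutoff": qm.recommended_cutoff,
    }
    with open(path, "w", newline="") as fh:
        fh.write("---\n")
        fh.write(yaml.safe_dump(meta, sort_keys=True))
        fh.write("---\n")
        writer = csv.writer(fh)
        writer.writerow(["label"] + list(AMINO_ACIDS))
        for label in qm.labels:
            writer.writerow(
                [label] + [repr(qm.contributions[(label, aa)]) for aa in AMINO_ACIDS]
            )


def read_qm(path: str | Path) -> QuantitativeMatrix:
    """Read a QM written by :func:`write_qm` (round-trip identity)."""
    text = Path(path).read_text()
    if not text.startswith("---\n"):
        raise ValueError(f"{path}: missing YAML front-matter fence")
    _, meta_text, csv_text = text.split("---\n", 2)
    meta = yaml.safe_load(meta_text)

    reader = csv.reader(io.StringIO(csv_text))
    header = next(reader)
    if header[0] != "label":
        raise ValueError(f"{path}: first column must be 'label', got {header[0]!r}")
    missing_cols = [aa for aa in AMINO_ACIDS if aa not in header[1:]]
    if missing_cols:
        raise ValueError(f"{path}: missing residue columns {missing_cols}")
    col_of = {aa: header.index(aa) for aa in AMINO_ACIDS}

    labels: list[str] = []
    contributions: dict[tuple[str, str], float] = {}
    for row in reader:
        if not row:
            continue
        label = row[0]
        label_offset_index(label)  # raises on unknown label form
        labels.append(label)
        for aa in AMINO_ACIDS:
            contributions[(label, aa)] = float(row[col_of[aa]])

    mode = meta["normalization_mode"]
    if mode in MODE_LABELS and tuple(labels) != MODE_LABELS[mode]:
        raise ValueError(
            f"{path}: mode {mode!r} expects labels {MODE_LABELS[mode]}, "
            f"file has {tuple(labels)}"
        )
    return QuantitativeMatrix(
        allele=meta.get("allele", ""),
        labels=tuple(labels),
        contributions=contributions,
        normalization_mode=mode,
        normalization_mean_kcal=float(meta["normalization_mean_kcal"]),
        parent_id=meta.get("parent_id", ""),
        config=DockingConfig.from_dict(meta["config"]) if meta.get("config") else DockingConfig(),
        recommended_cutoff=meta.get("recommended_cutoff"),
    )


# ---------------------------------------------------------------------------
# statsmodels-style surface

class QuantitativeMatrixModel:
    """Model object: a SAAS library plus its docking scores, ready to fit.

    ``fit()`` estimates the position x residue contribution matrix and returns
    a :class:`QMResults`.

    Examples
    --------
    >>> from dockqm import ParentPeptide, build_saas_library
    >>> from dockqm.synthetic import sample_ground_truth, simulate_library_scores
    >>> parent = ParentPeptide("glia", "QPFPQPELPYP", core_start=1)
    >>> lib = build_saas_library(parent)
    >>> truth = sample_ground_truth([f"p{i}" for i in range(11)], seed=7)
    >>> scores = simulate_library_scores(truth, lib)
    >>> res = QuantitativeMatrixModel(lib, scores, mode="core",
    ...                               allele="HLA-DQ2.5").fit()
    >>> res.qm.labels
    ('p1', 'p2', 'p3', 'p4', 'p5', 'p6', 'p7', 'p8', 'p9')
    """

    def __init__(
        self,
        library: CombinatorialLibrary,
        scores: ScoreTable,
        mode: NormalizationMode = "core",
        allele: str = "",
        formula: str = "ratio",
    ) -> None:
        self.library = library
        self.scores = scores
        self.mode = mode
        self.allele = allele
        self.formula = formula

    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        manifest_path: str | Path,
        scores_path: str | Path,
        mode: NormalizationMode = "core",
        allele: str = "",
        formula: str = "ratio",
    ) -> "QuantitativeMatrixModel":
        """Construct from a library FASTA + manifest and a score-table CSV."""
        lib = read_library(fasta_path, manifest_path)
        scores = read_score_table(scores_path)
        return cls(lib, scores, mode=mode, allele=allele, formula=formula)

    def fit(self) -> "QMResults":
        qm = build_qm(
            self.library, self.scores,
            mode=self.mode, allele=self.allele, formula=self.formula,
        )
        return QMResults(self, qm)


class QMResults:
    """Fitted quantitative matrix with diagnostics and downstream methods.

    Attributes
    ----------
    qm : QuantitativeMatrix
        The estimated contribution matrix.
    contributions : pandas.DataFrame
        Matrix view, rows = positions, columns = residues.
    normalization_mean_kcal : float
        mu, the mean affinity over the normalization set.
    """

    def __init__(self, model: QuantitativeMatrixModel, qm: QuantitativeMatrix) -> None:
        self.model = model
        self.qm = qm

    # -- estimates ---------------------------------------------------------
    @property
    def contributions(self) -> pd.DataFrame:
        return self.qm.as_dataframe()

    @property
    def normalization_mean_kcal(self) -> float:
        return self.qm.normalization_mean_kcal

    def preferred(self, threshold: float = 0.0) -> dict[str, set[str]]:
        """Residues with contribution > threshold at each covered position."""
        return {
            label: {aa for aa in AMINO_ACIDS
                    if self.qm.contributions[(label, aa)] > threshold}
            for label in self.qm.labels
        }

    def nonpreferred(self, threshold: float = 0.0) -> dict[str, set[str]]:
        """Residues with contribution < threshold at each covered position."""
        from .screening import nonpreferred_from_qm
        return nonpreferred_from_qm(self.qm, threshold=threshold)

    # -- scoring and screening --------------------------------------------
    def score_peptide(self, peptide: str):
        from .screening import score_peptide
        return score_peptide(self.qm, peptide)

    def screen_fasta(self, fasta_path: str | Path, cutoff: float):
        from .screening import screen_fasta
        return screen_fasta(self.qm, fasta_path, cutoff)

    def generate_decoys(self, count: int, length: int = 9, seed: int = 0,
                        threshold: float = 0.0) -> list[str]:
        from .screening import DecoySpec, generate_decoys
        spec = DecoySpec(
            nonpreferred=self.nonpreferred(threshold=threshold),
            length=length, count=count, seed=seed,
        )
        return generate_decoys(spec)

    # -- validation --------------------------------------------------------
    def cutoff_scan(self, labelled_set, lo: float = -0.5, hi: float = 0.5,
                    step: float = 0.1, select: bool = True):
        """Scan sensitivity/specificity/accuracy over a cutoff grid and, with
        ``select=True``, store the accuracy-maximizing cutoff on the matrix."""
        from .validation import cutoff_scan
        result = cutoff_scan(self.qm, labelled_set, lo=lo, hi=hi, step=step)
        if select:
            self.qm.recommended_cutoff = result.selected_cutoff
        return result

    def compare(self, other: "QMResults | QuantitativeMatrix",
                label: str | None = None):
        other_qm = other.qm if isinstance(other, QMResults) else other
        return compare_qms(self.qm, other_qm, label=label)

    # -- reporting ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        write_qm(self.qm, path)

    def summary(self) -> str:
        """Human-readable fit report: provenance, mu, the contribution matrix,
        and the most/least preferred residue per position."""
        qm = self.qm
        n_norm = len(normalization_set(self.model.library, qm.labels))
        lines = [
            "Quantitative Matrix Results",
            "=" * 66,
            f"Allele:              {qm.allele or '-'}",
            f"Parent peptide:      {qm.parent_id} "
            f"({self.model.library.parent.sequence})",
            f"Normalization mode:  {qm.normalization_mode} "
            f"({len(qm.labels)} positions, n = {n_norm} peptides)",
            f"Formula:             {self.model.formula}",
            f"Mean affinity (mu):  {qm.normalization_mean_kcal:.4f} kcal/mol",
            f"Docking engine:      {qm.config.engine_tag} "
            f"(exhaustiveness {qm.config.exhaustiveness}, "
            f"energy range {qm.config.energy_range_kcal} kcal/mol)",
            f"Recommended cutoff:  "
            f"{'-' if qm.recommended_cutoff is None else qm.recommended_cutoff}",
            "",
            "Contributions (positive = favourable):",
            self.contributions.round(3).to_string(),
            "",
            "Extremes per position:",
        ]
        df = self.contributions
        for label in qm.labels:
            row = df.loc[label]
            lines.append(
                f"  {label:>4}: best {row.idxmax()} ({row.max():+.3f}), "
                f"worst {row.idxmin()} ({row.min():+.3f})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<QMResults allele={self.qm.allele!r} mode={self.qm.normalization_mode!r} "
            f"positions={len(self.qm.labels)} mu={self.qm.normalization_mean_kcal:.3f}>"
        )
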