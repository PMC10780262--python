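"""Cutoff-scan validation: sensitivity, specificity and accuracy on labelled sets.

A labelled set of binders and non-binders is scored against a quantitative
matrix (best register per peptide); a peptide is predicted a binder iff its
score >= cutoff. Scanning cutoffs between -0.5 and +0.5 with a step of 0.1 and
selecting the accuracy-maximizing cutoff gives the matrix's operating point.

Sensitivity is the percentage of binders called correctly, specificity the
percentage of non-binders, accuracy the percentage of all peptides.
Percentages are reported rounded to integers (half-up) but stored at full
precision; the grid is generated by exact rational arithmetic so printed
cutoffs like 0.1 are hit exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from math import isnan
from pathlib import Path

import pandas as pd

from .screening import score_peptide

BINDER = "binder"
NON_BINDER = "non_binder"


@dataclass(frozen=True)
class LabelledSet:
    """Peptides with binder/non-binder labels, for validation."""

    peptides: tuple[tuple[str, str], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        for seq, label in self.peptides:
            if label not in (BINDER, NON_BINDER):
                raise ValueError(
                    f"label must be {BINDER!r} or {NON_BINDER!r}, got {label!r}"
                )
            if len(seq) < 9:
                raise ValueError(f"peptide {seq!r} shorter than the 9-mer core")

    @classmethod
    def from_lists(
        cls, binders, non_binders, provenance: str = ""
    ) -> "LabelledSet":
        peptides = [(s, BINDER) for s in binders] + [
            (s, NON_BINDER) for s in non_binders
        ]
        return cls(peptides=tuple(peptides), provenance=provenance)

    @property
    def n_binders(self) -> int:
        return sum(1 for _, l in self.peptides if l == BINDER)

    @property
    def n_non_binders(self) -> int:
        return sum(1 for _, l in self.peptides if l == NON_BINDER)


@dataclass(frozen=True)
class MetricsRow:
    """Confusion counts and metrics (percent, full precision) at one cutoff."""

    cutoff: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # NaN if the set has no binders
    specificity: float  # NaN if the set has no non-binders
    accuracy: float

    def rounded(self) -> dict[str, object]:
        """Table-style view: percentages rounded half-up to integers."""
        def r(x: float):
            return None if isnan(x) else int(
                Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
            )
        return {
            "cutoff": self.cutoff,
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "sensitivity": r(self.sensitivity),
            "specificity": r(self.specificity),
            "accuracy": r(self.accuracy),
        }


def _scores_and_labels(qm, labelled: LabelledSet) -> list[tuple[float, str]]:
    return [
        (score_peptide(qm, seq)[0], label) for seq, label in labelled.peptides
    ]


def _metrics_from_scores(
    scored: list[tuple[float, str]], cutoff: float
) -> MetricsRow:
    tp = fn = tn = fp = 0
    for score, label in scored:
        predicted_binder = score >= cutoff  # inclusive call rule
        if label == BINDER:
            tp, fn = (tp + 1, fn) if predicted_binder else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if predicted_binder else (fp, tn + 1)
    n_b, n_nb = tp + fn, tn + fp
    total = n_b + n_nb
    sens = 100.0 * tp / n_b if n_b else float("nan")
    spec = 100.0 * tn / n_nb if n_nb else float("nan")
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    return MetricsRow(
        cutoff=cutoff, tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
    )


def evaluate_at_cutoff(qm, labelled: LabelledSet, cutoff: float) -> MetricsRow:
    """Confusion counts and metrics for one cutoff.

    Each peptide is scored at its best 9-mer register and called a binder iff
    score >= cutoff. A set missing one class gets NaN for that class's metric.
    """
    return _metrics_from_scores(_scores_and_labels(qm, labelled), cutoff)


@dataclass
class CutoffScanResult:
    """Metrics across a cutoff grid, with the accuracy-maximizing cutoff."""

    rows: list[MetricsRow]
    selected_cutoff: float

    @property
    def grid(self) -> list[float]:
        return [r.cutoff for r in self.rows]

    @property
    def selected_row(self) -> MetricsRow:
        return next(r for r in self.rows if r.cutoff == self.selected_cutoff)

    def to_dataframe(self, rounded: bool = False) -> pd.DataFrame:
        if rounded:
            return pd.DataFrame([r.rounded() for r in self.rows])
        return pd.DataFrame(
            [
                {
                    "cutoff": r.cutoff, "TP": r.tp, "FN": r.fn,
                    "TN": r.tn, "FP": r.fp,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "accuracy": r.accuracy,
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path, header_comments=()) -> None:
        with open(path, "w") as fh:
            for c in header_comments:
                fh.write(f"# {c}\n")
            fh.write(f"# selected_cutoff: {self.selected_cutoff}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def cutoff_grid(lo: float = -0.5, hi: float = 0.5, step: float = 0.1) -> list[float]:
    """Inclusive arithmetic grid by exact rational stepping (no float drift)."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if lo >= hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    f_lo, f_hi, f_step = (Fraction(repr(x)) for x in (lo, hi, step))
    grid, i = [], 0
    while f_lo + i * f_step <= f_hi:
        grid.append(float(f_lo + i * f_step))
        i += 1
    return grid


def cutoff_scan(
    qm,
    labelled: LabelledSet,
    lo: float = -0.5,
    hi: float = 0.5,
    step: float = 0.1,
) -> CutoffScanResult:
    """Scan metrics over the cutoff grid and select the best operating point.

    Peptides are scored once and re-thresholded per cutoff. The selected
    cutoff maximizes accuracy; ties break to the lowest cutoff, then (for
    grids with duplicate cutoffs) the highest sensitivity.
    """
    scored = _scores_and_labels(qm, labelled)
    rows = [_metrics_from_scores(scored, c) for c in cutoff_grid(lo, hi, step)]
    best = min(
        rows,
        key=lambda r: (-r.accuracy, r.cutoff, -(r.sensitivity if not isnan(r.sensitivity) else -1.0)),
    )
    return CutoffScanResult(rows=rows, selected_cutoff=best.cutoff)


def read_peptide_list(path: str | Path) -> list[str]:
    """Plain-text peptide list: one sequence per line, ``#`` comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.upper())
    return out


def read_labelled_csv(path: str | Path) -> LabelledSet:
    """CSV with header ``sequence,label``; label values binder/non_binder."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(f for f in fh if not f.startswith("#")))
    if not rows or set(rows[0]) != {"sequence", "label"}:
        raise ValueError(f"{path}: expected header sequence,label")
    return LabelledSet(
        peptides=tuple((r["sequence"].upper(), r["label"]) for r in rows),
        provenance=str(path),
    )
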