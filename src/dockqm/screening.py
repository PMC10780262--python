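"""Additive QM scoring of peptides and proteins, and decoy construction.

A peptide's predicted binding score under a quantitative matrix is the sum of
the per-position contribution coefficients over the nine binding-core
positions (plus p0/p10 when the matrix covers flanks). Proteins and peptides
longer than 9 residues are scanned over every 9-mer core register and the best
(maximum) register is reported. Binders are called at ``score >= cutoff``
(inclusive).

Non-binder decoys are built the way validation sets for these matrices are:
a random combination of non-preferred residues -- negative contribution at
that position -- at all nine core positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .peptide_library import AMINO_ACIDS, CORE_LABELS


@dataclass(frozen=True)
class ScoredWindow:
    """One scored 9-mer core register within a protein or peptide."""

    protein_id: str
    register_offset: int  # 0-based offset of p1
    core_sequence: str
    flank_p0: str | None
    flank_p10: str | None
    score: float
    call: str  # "binder" | "non-binder"


@dataclass(frozen=True)
class DecoySpec:
    """Recipe for non-binder decoys.

    ``nonpreferred`` maps each core label (p1..p9) to the residue set drawn
    from at that position; entries for other labels are ignored. Flank
    residues (for length > 9) are drawn uniformly from the full alphabet.
    """

    nonpreferred: Mapping[str, frozenset | set]
    length: int = 9
    count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 9:
            raise ValueError(f"decoy length must be >= 9, got {self.length}")
        if self.count < 0:
            raise ValueError(f"decoy count must be >= 0, got {self.count}")
        for label in CORE_LABELS:
            if not self.nonpreferred.get(label):
                raise ValueError(
                    f"empty non-preferred residue set at core label {label}"
                )


def score_core(qm, core9: str, p0: str | None = None, p10: str | None = None) -> float:
    """Additive score of a 9-mer binding core under a QM.

    Flank residues contribute only when the matrix covers p0/p10; an absent
    flank (window at a protein terminus) contributes 0.
    """
    core9 = core9.upper()
    if len(core9) != 9:
        raise ValueError(f"binding core must be a 9-mer, got length {len(core9)}")
    total = 0.0
    for label, aa in zip(CORE_LABELS, core9):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue {aa!r} in core {core9}")
        total += qm.contributions[(label, aa)]
    for label, aa in (("p0", p0), ("p10", p10)):
        if label in qm.labels and aa is not None:
            aa = aa.upper()
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-standard flank residue {aa!r}")
            total += qm.contributions[(label, aa)]
    return total


def _window_at(peptide: str, offset: int) -> tuple[str, str | None, str | None]:
    core = peptide[offset:offset + 9]
    p0 = peptide[offset - 1] if offset >= 1 else None
    p10 = peptide[offset + 9] if offset + 9 < len(peptide) else None
    return core, p0, p10


def score_peptide(qm, peptide: str) -> tuple[float, int, list[float]]:
    """Score every 9-mer core register of a peptide; return the best.

    Returns ``(best_score, best_register_offset, register_scores)`` where
    ``register_scores[k]`` is the score with p1 at offset k. Ties are broken
    towards the smallest offset.
    """
    peptide = peptide.upper()
    if len(peptide) < 9:
        raise ValueError(
            f"peptide of length {len(peptide)} < 9 cannot fill the binding core"
        )
    register_scores: list[float] = []
    for offset in range(len(peptide) - 8):
        core, p0, p10 = _window_at(peptide, offset)
        register_scores.append(score_core(qm, core, p0=p0, p10=p10))
    best_register = int(np.argmax(register_scores))  # argmax takes first maximum
    return register_scores[best_register], best_register, register_scores


@dataclass
class ScreeningReport:
    """Per-window calls plus per-protein aggregates from a FASTA screen."""

    windows: list[ScoredWindow]
    cutoff: float
    skipped: dict[str, int]  # protein_id -> windows skipped (non-standard residues)
    n_proteins: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": w.protein_id,
                    "register_offset": w.register_offset,
                    "core_sequence": w.core_sequence,
                    "score": w.score,
                    "call": w.call,
                }
                for w in self.windows
            ]
        )

    def per_protein(self) -> pd.DataFrame:
        """Per-protein best score/register and binder count."""
        rows = []
        by_protein: dict[str, list[ScoredWindow]] = {}
        for w in self.windows:
            by_protein.setdefault(w.protein_id, []).append(w)
        for pid, ws in by_protein.items():
            best_score = max(w.score for w in ws)
            best = next(w for w in ws if w.score == best_score)  # first-offset tie-break
            rows.append(
                {
                    "protein_id": pid,
                    "n_windows": len(ws),
                    "n_skipped": self.skipped.get(pid, 0),
                    "best_score": best.score,
                    "best_register": best.register_offset,
                    "n_binders": sum(w.call == "binder" for w in ws),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for c in header_comments:
                fh.write(f"# {c}\n")
            fh.write(f"# cutoff: {self.cutoff}\n")
            fh.write("protein_id\tregister_offset\tcore_sequence\tscore\tcall\n")
            for w in self.windows:
                fh.write(
                    f"{w.protein_id}\t{w.register_offset}\t{w.core_sequence}\t"
                    f"{w.score:.6f}\t{w.call}\n"
                )
            fh.write("\n# per-protein summary\n")
            for _, r in self.per_protein().iterrows():
                fh.write(
                    f"# {r.protein_id}: best {r.best_score:.6f} at register "
                    f"{r.best_register}, {r.n_binders}/{r.n_windows} binders, "
                    f"{r.n_skipped} windows skipped\n"
                )


def screen_fasta(qm, fasta_path: str | Path, cutoff: float) -> ScreeningReport:
    """Scan every protein in a FASTA over all 9-mer registers.

    Windows containing residues outside the 20-letter alphabet (X, B, Z, U,
    ...) are skipped and counted per protein rather than scored with imputed
    values. Each clean window is called binder iff score >= cutoff.
    """
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    windows: list[ScoredWindow] = []
    skipped: dict[str, int] = {}
    n_proteins = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_proteins += 1
        seq = str(rec.seq).upper()
        skipped.setdefault(rec.id, 0)
        for offset in range(max(0, len(seq) - 8)):
            core, p0, p10 = _window_at(seq, offset)
            if any(aa not in AMINO_ACIDS for aa in core):
                skipped[rec.id] += 1
                continue
            # flanks with non-standard residues are treated as absent
            if p0 is not None and p0 not in AMINO_ACIDS:
                p0 = None
            if p10 is not None and p10 not in AMINO_ACIDS:
                p10 = None
            score = score_core(qm, core, p0=p0, p10=p10)
            windows.append(
                ScoredWindow(
                    protein_id=rec.id,
                    register_offset=offset,
                    core_sequence=core,
                    flank_p0=p0,
                    flank_p10=p10,
                    score=score,
                    call="binder" if score >= cutoff else "non-binder",
                )
            )
    if n_proteins == 0:
        raise ValueError(f"no sequences found in {fasta_path}")
    return ScreeningReport(
        windows=windows, cutoff=cutoff, skipped=skipped, n_proteins=n_proteins
    )


def nonpreferred_from_qm(qm, threshold: float = 0.0) -> dict[str, set[str]]:
    """Residues with contribution below ``threshold`` at each core position.

    Empty sets are allowed here; :class:`DecoySpec` rejects them when decoys
    are actually requested.
    """
    missing = [l for l in CORE_LABELS if l not in qm.labels]
    if missing:
        raise ValueError(f"QM does not cover core labels {missing}")
    return {
        label: {
            aa for aa in AMINO_ACIDS if qm.contributions[(label, aa)] < threshold
        }
        for label in CORE_LABELS
    }


def preferred_from_qm(qm, threshold: float = 0.0) -> dict[str, set[str]]:
    """Residues with contribution above ``threshold`` at each core position."""
    missing = [l for l in CORE_LABELS if l not in qm.labels]
    if missing:
        raise ValueError(f"QM does not cover core labels {missing}")
    return {
        label: {
            aa for aa in AMINO_ACIDS if qm.contributions[(label, aa)] > threshold
        }
        for label in CORE_LABELS
    }


def sample_core_peptides(
    residue_sets: Mapping[str, set | frozenset | list],
    length: int,
    count: int,
    seed: int,
) -> list[str]:
    """Random peptides with core residues drawn from per-position sets.

    Core residues at p1..p9 are drawn uniformly from each position's set (kept
    in sorted order for reproducibility); for lengths > 9 the core sits
    mid-sequence (extra residues split evenly, leading side first) and flank
    residues are uniform over the full alphabet.
    """
    if length < 9:
        raise ValueError(f"length must be >= 9, got {length}")
    pools = {}
    for label in CORE_LABELS:
        if not residue_sets.get(label):
            raise ValueError(f"empty residue set at core label {label}")
        pools[label] = sorted(residue_sets[label])
    rng = np.random.default_rng(seed)
    n_lead = (length - 9) // 2
    n_trail = length - 9 - n_lead
    peptides: list[str] = []
    for _ in range(count):
        core = "".join(
            pools[label][rng.integers(len(pools[label]))] for label in CORE_LABELS
        )
        lead = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(n_lead))
        trail = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(n_trail))
        peptides.append(lead + core + trail)
    return peptides


def generate_decoys(spec: DecoySpec) -> list[str]:
    """Random non-binder peptides from per-position non-preferred residue sets,
    reproducible under the spec's seed."""
    return sample_core_peptides(
        spec.nonpreferred, spec.length, spec.count, spec.seed
    )
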