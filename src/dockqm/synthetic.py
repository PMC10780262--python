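"""Synthetic docking: a planted additive per-position energy model.

Stands in for a docking engine when deriving and validating quantitative
matrices. Each peptide's affinity is

    affinity = base + sum over covered positions of delta(label, residue) + eps

with ``eps ~ Normal(0, noise_sd)`` from a seeded stream, so the additive
structure the QM derivation assumes is planted by construction and recovery
can be checked exactly (noise 0) or statistically (noise > 0).

Deltas are drawn i.i.d. uniform on ``[-spread, +spread]`` rather than Gaussian
so that planted preferred/non-preferred residues are bounded and
binder/decoy constructions have guaranteed separation. Defaults (base
-7.0 kcal/mol, spread 1.0 kcal/mol) echo typical docking-score magnitudes.
The model scores only the labels it covers: a core-only model ignores flank
residues, mirroring the binding-core focus of the matrices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .docking import DockingConfig, ScoreTable
from .peptide_library import AMINO_ACIDS, CombinatorialLibrary, label_offset_index

DEFAULT_BASE_AFFINITY = -7.0  # kcal/mol, a typical engine-reported magnitude
DEFAULT_SPREAD = 1.0  # kcal/mol


@dataclass(frozen=True)
class GroundTruthModel:
    """Planted additive energy model: base affinity + per-(position, residue) deltas.

    ``delta`` maps ``(label, amino acid)`` to a kcal/mol increment (negative =
    stabilizing) and must cover all 20 residues at every covered label.
    """

    base_affinity_kcal: float
    delta: Mapping[tuple[str, str], float]
    noise_sd_kcal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_kcal < 0:
            raise ValueError(f"noise_sd_kcal must be >= 0, got {self.noise_sd_kcal}")
        for label in self.labels:
            missing = [aa for aa in AMINO_ACIDS if (label, aa) not in self.delta]
            if missing:
                raise ValueError(
                    f"delta not defined for residues {missing} at label {label}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        """Covered position labels, in register order."""
        return tuple(sorted({l for l, _ in self.delta}, key=label_offset_index))

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded with the model's seed."""
        return np.random.default_rng(self.seed)


def sample_ground_truth(
    labels: Sequence[str],
    seed: int,
    delta_spread_kcal: float = DEFAULT_SPREAD,
    base_affinity_kcal: float = DEFAULT_BASE_AFFINITY,
    noise_sd_kcal: float = 0.0,
    reference_residues: Mapping[str, str] | None = None,
) -> GroundTruthModel:
    """Draw a random ground-truth model over the given position labels.

    Deltas are i.i.d. uniform on ``[-delta_spread, +delta_spread]``, drawn in a
    fixed (label order, alphabetical residue) sequence from a generator seeded
    with ``seed``, so the model is fully reproducible.

    With ``reference_residues`` (label -> residue, typically the parent
    peptide's composition), the reference residue's delta at each label is
    pinned to 0 after drawing, so ``base_affinity_kcal`` becomes the reference
    peptide's exact noise-free affinity and substitution effects are measured
    relative to it. This mirrors a SAAS experiment around a known binder and
    keeps the zero of each position's delta scale strictly inside the drawn
    range with overwhelming probability.
    """
    if not labels:
        raise ValueError("empty label set")
    if delta_spread_kcal < 0:
        raise ValueError(f"delta_spread_kcal must be >= 0, got {delta_spread_kcal}")
    rng = np.random.default_rng(seed)
    ordered = sorted(set(labels), key=label_offset_index)
    delta = {
        (label, aa): float(rng.uniform(-delta_spread_kcal, delta_spread_kcal))
        for label in ordered
        for aa in AMINO_ACIDS
    }
    if reference_residues is not None:
        for label in ordered:
            ref = reference_residues.get(label)
            if ref is None:
                raise ValueError(f"reference_residues does not cover label {label}")
            delta[(label, ref)] = 0.0
    return GroundTruthModel(
        base_affinity_kcal=base_affinity_kcal,
        delta=delta,
        noise_sd_kcal=noise_sd_kcal,
        seed=seed,
    )


def simulate_score(
    model: GroundTruthModel,
    peptide_sequence: str,
    label_map: Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> float:
    """Affinity of one peptide under the planted model.

    ``label_map`` maps each covered label to its 0-based offset in the
    sequence. With ``noise_sd_kcal == 0`` the result is the exact additive sum.
    """
    total = model.base_affinity_kcal
    for label in model.labels:
        if label not in label_map:
            raise ValueError(f"label_map does not place label {label}")
        offset = label_map[label]
        if not (0 <= offset < len(peptide_sequence)):
            raise ValueError(
                f"label {label} maps to offset {offset}, outside the "
                f"{len(peptide_sequence)}-mer"
            )
        aa = peptide_sequence[offset]
        if aa not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue {aa!r} at offset {offset}")
        total += model.delta[(label, aa)]
    if model.noise_sd_kcal > 0:
        if rng is None:
            rng = model.rng()
        total += float(rng.normal(0.0, model.noise_sd_kcal))
    return total


def simulate_library_scores(
    model: GroundTruthModel, lib: CombinatorialLibrary
) -> ScoreTable:
    """Simulated score table for a whole library: one best affinity per member.

    A single seeded stream drives all noise draws, consumed in library order,
    so the table is byte-identical across runs with the same seed.
    """
    parent = lib.parent
    parent_labels = {pl.label for pl in parent.labels()}
    gaps = [l for l in model.labels if l not in parent_labels]
    if gaps:
        raise ValueError(
            f"model covers labels {gaps} not present in the library register"
        )
    label_map = {l: parent.offset_of(l) for l in model.labels}
    rng = model.rng()
    entries = {
        v.peptide_id: simulate_score(model, v.sequence, label_map, rng=rng)
        for v in lib.variants
    }
    config = DockingConfig(engine_tag="synthetic")
    return ScoreTable(entries=entries, config=config)


def write_ground_truth(model: GroundTruthModel, path: str | Path) -> None:
    """Serialize a model as CSV rows (label, aa, delta) under a YAML comment header."""
    with open(path, "w", newline="") as fh:
        header = {
            "base_affinity_kcal": model.base_affinity_kcal,
            "noise_sd_kcal": model.noise_sd_kcal,
            "seed": model.seed,
        }
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["label", "aa", "delta_kcal"])
        for label in model.labels:
            for aa in AMINO_ACIDS:
                writer.writerow([label, aa, repr(model.delta[(label, aa)])])


def read_ground_truth(path: str | Path) -> GroundTruthModel:
    """Read a model written by :func:`write_ground_truth`."""
    meta_lines: list[str] = []
    data_lines: list[str] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line[1:].lstrip())
            else:
                data_lines.append(line)
    header = yaml.safe_load("".join(meta_lines)) if meta_lines else {}
    delta = {
        (row["label"], row["aa"]): float(row["delta_kcal"])
        for row in csv.DictReader(data_lines)
    }
    return GroundTruthModel(
        base_affinity_kcal=float(header.get("base_affinity_kcal", DEFAULT_BASE_AFFINITY)),
        delta=delta,
        noise_sd_kcal=float(header.get("noise_sd_kcal", 0.0)),
        seed=int(header.get("seed", 0)),
    )
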