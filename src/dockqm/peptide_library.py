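"""SAAS combinatorial peptide libraries with a binding-core register.

MHC class II molecules bind peptides in an open groove that accommodates a
nine-residue binding core (positions p1..p9) plus flanking residues (p0 and
p10, and p-1/p11 for longer parents). A single-amino-acid-substitution (SAAS)
library takes a parent peptide bound in a known register and substitutes the
residue at each open position with the 19 alternative natural amino acids --
one peptide, one substitution -- so that an 11-position parent yields
19 x 11 + 1 = 210 peptides.

Position labels are symbolic (``p-1`` .. ``p11``) and map to 0-based sequence
offsets through the parent's ``core_start`` (the offset of p1). All file
output reports labels, not raw offsets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Labels of the nine binding-core positions.
CORE_LABELS: tuple[str, ...] = tuple(f"p{i}" for i in range(1, 10))

_WT = "wt"


def _label_for_core_relative(n: int) -> str:
    """Symbolic label for core-relative position n (p1 has n == 1)."""
    return f"p{n}"


def label_offset_index(label: str) -> int:
    """Numeric core-relative index of a label (``p-1`` -> -1, ``p4`` -> 4).

    Raises
    ------
    ValueError
        If the label is not of the form ``p<int>``.
    """
    if not label.startswith("p"):
        raise ValueError(f"malformed position label {label!r}")
    try:
        return int(label[1:])
    except ValueError as exc:
        raise ValueError(f"malformed position label {label!r}") from exc


@dataclass(frozen=True)
class PositionLabel:
    """A symbolic peptide position tied to a 0-based sequence offset.

    p1..p9 form the binding core; p0/p10 (and p-1/p11 when the parent is long
    enough) are flanks.
    """

    label: str
    offset: int

    @property
    def is_core(self) -> bool:
        return 1 <= label_offset_index(self.label) <= 9


@dataclass(frozen=True)
class ParentPeptide:
    """A parent peptide with its binding-core register.

    Parameters
    ----------
    id : str
        Identifier used as the prefix of all library peptide ids.
    sequence : str
        Amino-acid sequence (standard 20-letter alphabet; forced upper case).
    core_start : int
        0-based offset of binding-core position p1.
    mutable_labels : tuple of str, optional
        Ordered labels open to substitution. Defaults to every position in the
        sequence. Positions kept fixed (e.g. p-1 and p11 for the 13-mer
        HLA-DQ8.1 parent) are simply omitted.
    """

    id: str
    sequence: str
    core_start: int
    mutable_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"non-standard residue {aa!r} at offset {i} in parent "
                    f"{self.id!r}: only the 20 standard one-letter codes are allowed"
                )
        if len(self.sequence) < 9:
            raise ValueError(
                f"parent {self.id!r} has length {len(self.sequence)} < 9"
            )
        if not (0 <= self.core_start and self.core_start + 9 <= len(self.sequence)):
            raise ValueError(
                f"core_start {self.core_start} out of range for length "
                f"{len(self.sequence)}: the 9-mer core must fit in the sequence"
            )
        all_labels = tuple(pl.label for pl in self.labels())
        if not self.mutable_labels:
            object.__setattr__(self, "mutable_labels", all_labels)
        else:
            object.__setattr__(self, "mutable_labels", tuple(self.mutable_labels))
            unknown = [l for l in self.mutable_labels if l not in all_labels]
            if unknown:
                raise ValueError(
                    f"mutable labels {unknown} not present in parent {self.id!r} "
                    f"(available: {list(all_labels)})"
                )

    def labels(self) -> tuple[PositionLabel, ...]:
        """All position labels of the sequence, in offset order."""
        return tuple(
            PositionLabel(_label_for_core_relative(i - self.core_start + 1), i)
            for i in range(len(self.sequence))
        )

    def offset_of(self, label: str) -> int:
        """0-based sequence offset of a symbolic label."""
        offset = label_offset_index(label) - 1 + self.core_start
        if not (0 <= offset < len(self.sequence)):
            raise ValueError(f"label {label!r} falls outside parent {self.id!r}")
        return offset

    def residue_at(self, label: str) -> str:
        return self.sequence[self.offset_of(label)]


def label_for_offset(parent: ParentPeptide, offset: int) -> PositionLabel:
    """Symbolic position label of a 0-based sequence offset.

    Inverse of :attr:`PositionLabel.offset` for the parent's register.
    """
    if not (0 <= offset < len(parent.sequence)):
        raise ValueError(
            f"offset {offset} out of range for parent {parent.id!r} "
            f"of length {len(parent.sequence)}"
        )
    return parent.labels()[offset]


@dataclass(frozen=True)
class LibraryVariant:
    """One library member: the parent itself or a single-substitution variant."""

    peptide_id: str
    sequence: str
    substituted_label: str | None = None
    substituted_aa: str | None = None

    @property
    def is_parent(self) -> bool:
        return self.substituted_label is None


@dataclass(frozen=True)
class CombinatorialLibrary:
    """A SAAS library: the parent plus every single-substitution variant."""

    parent: ParentPeptide
    variants: tuple[LibraryVariant, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("library must contain at least the parent peptide")
        object.__setattr__(self, "variants", tuple(self.variants))
        seqs = [v.sequence for v in self.variants]
        if len(set(seqs)) != len(seqs):
            raise ValueError("library sequences are not unique")
        bad = [v.peptide_id for v in self.variants if len(v.sequence) != len(self.parent.sequence)]
        if bad:
            raise ValueError(f"variants with wrong length: {bad}")
        if not any(v.is_parent for v in self.variants):
            raise ValueError("library must contain the parent peptide")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def parent_variant(self) -> LibraryVariant:
        return next(v for v in self.variants if v.is_parent)

    def peptide_ids(self) -> list[str]:
        return [v.peptide_id for v in self.variants]


def build_saas_library(parent: ParentPeptide) -> CombinatorialLibrary:
    """Build the SAAS library of a parent peptide.

    The parent comes first, then one variant per (mutable label x 19
    alternative residues), ordered by label position and then alphabetically
    by substituted residue, so peptide ids are stable across runs. Ids are
    ``<parentid>_<label><aa>``; the parent gets ``<parentid>_wt``.

    With m mutable labels the library has exactly 19 m + 1 members: 210 for
    the 11 open positions of the HLA-DQ parents.
    """
    variants: list[LibraryVariant] = [
        LibraryVariant(f"{parent.id}_{_WT}", parent.sequence)
    ]
    ordered = sorted(parent.mutable_labels, key=label_offset_index)
    for label in ordered:
        offset = parent.offset_of(label)
        wt_aa = parent.sequence[offset]
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            seq = parent.sequence[:offset] + aa + parent.sequence[offset + 1:]
            variants.append(
                LibraryVariant(f"{parent.id}_{label}{aa}", seq, label, aa)
            )
    return CombinatorialLibrary(parent=parent, variants=tuple(variants))


def write_library(
    lib: CombinatorialLibrary,
    fasta_path: str | Path,
    manifest_path: str | Path,
) -> None:
    """Serialize a library as FASTA (sequences) + CSV manifest.

    The manifest carries peptide_id, substituted_label and substituted_aa
    (literal ``wt`` in both columns for the parent row) and records the
    parent's register in ``#``-prefixed header comments so the library can be
    reconstructed exactly.
    """
    records = [
        SeqRecord(Seq(v.sequence), id=v.peptide_id, description="")
        for v in lib.variants
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(manifest_path, "w", newline="") as fh:
        fh.write(f"# parent_id: {lib.parent.id}\n")
        fh.write(f"# core_start: {lib.parent.core_start}\n")
        fh.write(f"# mutable_labels: {','.join(lib.parent.mutable_labels)}\n")
        writer = csv.writer(fh)
        writer.writerow(["peptide_id", "substituted_label", "substituted_aa"])
        for v in lib.variants:
            writer.writerow(
                [v.peptide_id, v.substituted_label or _WT, v.substituted_aa or _WT]
            )


def read_library(
    fasta_path: str | Path, manifest_path: str | Path
) -> CombinatorialLibrary:
    """Read a library written by :func:`write_library` (round-trip identity)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {fasta_path}")

    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    with open(manifest_path, newline="") as fh:
        lines = []
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                lines.append(line)
        rows = list(csv.DictReader(lines))
    if "core_start" not in meta or "parent_id" not in meta:
        raise ValueError(
            f"manifest {manifest_path} lacks the '# parent_id:'/'# core_start:' header"
        )

    missing = [r["peptide_id"] for r in rows if r["peptide_id"] not in seqs]
    if missing:
        raise ValueError(
            f"manifest ids absent from FASTA {fasta_path}: {missing}"
        )

    parent_rows = [r for r in rows if r["substituted_label"] == _WT]
    if len(parent_rows) != 1:
        raise ValueError("manifest must contain exactly one parent ('wt') row")
    parent_seq = seqs[parent_rows[0]["peptide_id"]]

    mutable = tuple(
        l for l in meta.get("mutable_labels", "").split(",") if l
    )
    parent = ParentPeptide(
        id=meta["parent_id"],
        sequence=parent_seq,
        core_start=int(meta["core_start"]),
        mutable_labels=mutable,
    )
    variants = []
    for r in rows:
        is_parent = r["substituted_label"] == _WT
        variants.append(
            LibraryVariant(
                peptide_id=r["peptide_id"],
                sequence=seqs[r["peptide_id"]],
                substituted_label=None if is_parent else r["substituted_label"],
                substituted_aa=None if is_parent else r["substituted_aa"],
            )
        )
    return CombinatorialLibrary(parent=parent, variants=tuple(variants))
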