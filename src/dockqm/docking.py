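"""Ingestion of docking results: pose lists, energy-range filtering, score tables.

Docking engines report, per peptide, a ranked list of binding poses with
affinities in kcal/mol (more negative = stronger). The workflow keeps one best
affinity per peptide after discarding poses whose score falls outside the
energy range above the best pose -- a provenance-preserving step: it can never
change the best score, but the retained pose count is part of the docking
protocol's audit trail.

Actual docking execution is out of scope; this module only parses engine
output (result tables or ``REMARK VINA RESULT:`` lines) and reads/writes
plain-text score tables.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

# unicode minus / en dash seen in pasted logs, normalized before float parsing
_MINUS_RE = re.compile("[−–]")

_TABLE_ROW_RE = re.compile(
    r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s*$"
)
_REMARK_RE = re.compile(
    r"REMARK\s+VINA\s+RESULT:\s+(-?\d+(?:\.\d+)?)"
)


@dataclass(frozen=True)
class DockingConfig:
    """Provenance of a docking run.

    ``energy_range_kcal`` is the window above the best pose within which
    alternative poses are retained; ``site_radius_A`` records how the binding
    site was defined (protein residues within that distance of the bound
    peptide).
    """

    exhaustiveness: int = 8
    energy_range_kcal: float = 3.0
    flexible_peptide: bool = True
    flexible_site: bool = True
    site_radius_A: float = 6.0
    engine_tag: str = "vina"

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1:
            raise ValueError(f"exhaustiveness must be >= 1, got {self.exhaustiveness}")
        if self.energy_range_kcal <= 0:
            raise ValueError(
                f"energy_range_kcal must be > 0, got {self.energy_range_kcal}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DockingConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class Pose:
    """One docking pose: rank (1-based) and affinity in kcal/mol."""

    rank: int
    affinity_kcal: float

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"pose rank must be >= 1, got {self.rank}")


def parse_docking_output(text: str) -> list[Pose]:
    """Parse poses from docking-log text.

    Recognizes both the stdout result table (columns mode, affinity,
    rmsd l.b., rmsd u.b.) and ``REMARK VINA RESULT:`` lines from output PDBQT;
    tolerant of surrounding log noise. Unicode minus signs are normalized
    before numeric parsing. rmsd columns are ignored.
    """
    text = _MINUS_RE.sub("-", text)
    poses: list[Pose] = []
    remark_poses: list[Pose] = []
    for line in text.splitlines():
        m = _TABLE_ROW_RE.match(line)
        if m:
            poses.append(Pose(rank=int(m.group(1)), affinity_kcal=float(m.group(2))))
            continue
        m = _REMARK_RE.search(line)
        if m:
            remark_poses.append(
                Pose(rank=len(remark_poses) + 1, affinity_kcal=float(m.group(1)))
            )
    found = poses or remark_poses
    if not found:
        raise ValueError("no poses found in docking output")
    return found


def best_score(poses: list[Pose], energy_range_kcal: float = 3.0) -> float:
    """Best (most negative) affinity after energy-range pose filtering.

    Poses with affinity above ``min + energy_range_kcal`` are discarded; the
    returned value is the minimum of the retained set, which always equals the
    overall minimum. The number of discarded poses is logged.
    """
    if not poses:
        raise ValueError("empty pose list")
    affinities = [p.affinity_kcal for p in poses]
    best = min(affinities)
    retained = [a for a in affinities if a <= best + energy_range_kcal]
    n_dropped = len(affinities) - len(retained)
    if n_dropped:
        logger.info(
            "energy-range filter (%.2f kcal/mol) discarded %d of %d poses",
            energy_range_kcal, n_dropped, len(affinities),
        )
    return min(retained)


@dataclass
class ScoreTable:
    """Map peptide_id -> best docking affinity (kcal/mol), with provenance."""

    entries: dict[str, float]
    config: DockingConfig = field(default_factory=DockingConfig)

    def __post_init__(self) -> None:
        for pid, aff in self.entries.items():
            if not _is_finite(aff):
                raise ValueError(f"non-finite affinity for peptide {pid!r}: {aff}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, peptide_id: str) -> float:
        return self.entries[peptide_id]

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self.entries


def _is_finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def write_score_table(table: ScoreTable, csv_path: str | Path) -> None:
    """Write a score table as CSV with the docking config in a YAML comment block."""
    with open(csv_path, "w", newline="") as fh:
        for line in yaml.safe_dump(table.config.to_dict(), sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["peptide_id", "affinity_kcal"])
        for pid, aff in table.entries.items():
            writer.writerow([pid, repr(aff)])


def read_score_table(csv_path: str | Path) -> ScoreTable:
    """Read a score table CSV (round-trip inverse of :func:`write_score_table`)."""
    meta_lines: list[str] = []
    data_lines: list[str] = []
    with open(csv_path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line[1:].lstrip())
            else:
                data_lines.append(line)
    config = DockingConfig()
    if meta_lines:
        config = DockingConfig.from_dict(yaml.safe_load("".join(meta_lines)))

    entries: dict[str, float] = {}
    reader = csv.DictReader(data_lines)
    if reader.fieldnames is None or set(reader.fieldnames) != {"peptide_id", "affinity_kcal"}:
        raise ValueError(
            f"{csv_path}: expected header peptide_id,affinity_kcal, "
            f"got {reader.fieldnames}"
        )
    for i, row in enumerate(reader, start=2):
        pid = row["peptide_id"]
        if pid in entries:
            raise ValueError(f"{csv_path}: duplicate peptide_id {pid!r}")
        raw = _MINUS_RE.sub("-", row["affinity_kcal"])
        try:
            aff = float(raw)
        except ValueError as exc:
            raise ValueError(
                f"{csv_path}: non-numeric affinity {row['affinity_kcal']!r} "
                f"in row {i}"
            ) from exc
        entries[pid] = aff
    return ScoreTable(entries=entries, config=config)


def format_poses(poses: list[Pose]) -> str:
    """Render poses in the stdout result-table format parsed by
    :func:`parse_docking_output` (formatter/parser round-trip identity)."""
    lines = [
        "mode |   affinity | dist from best mode",
        "     | (kcal/mol) | rmsd l.b.| rmsd u.b.",
        "-----+------------+----------+----------",
    ]
    for p in poses:
        lines.append(f"{p.rank:>4}    {p.affinity_kcal:>10.3f}      0.000      0.000")
    return "\n".join(lines) + "\n"
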