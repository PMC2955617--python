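"""Chip layouts and annotation tables: data model, readers and writers.

A kinase-substrate chip is described by three kinds of table:

* a **layout** (one row per physical spot: substrate identity, replicate
  index, grid position, control status),
* a **substrate -> kinase** annotation (many-to-many: one peptide may be a
  recognition motif for several kinases, as when Src-family members share
  substrates),
* a **kinase -> pathway** membership table plus a kinase metadata table
  (display name, category tags such as ``cell_cycle``, known inhibitors).

All on-disk formats are plain TSV with fixed headers; GPR (GenePix Results)
import is provided for quantified spot intensities, and pathway sets are
additionally accepted in GMT format.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

CONTROL_TYPES = ("positive", "negative", "none")

#: Printed design of the chip emulated by :func:`default_layout`.
DEFAULT_N_SUBSTRATES = 1024
DEFAULT_N_REPLICATES = 3
DEFAULT_N_NEGATIVE_CONTROLS = 16
DEFAULT_N_POSITIVE_CONTROLS = 16

_LAYOUT_COLUMNS = ["spot_id", "substrate_id", "replicate_idx", "block", "row", "col", "control_type"]


@dataclass(frozen=True)
class SpotDef:
    """One physical spot on the chip.

    ``substrate_id`` is ``None`` for control spots; ``control_type`` is
    ``"none"`` for substrate spots. Grid coordinates are 0-based.
    """

    spot_id: str
    substrate_id: str | None
    replicate_idx: int
    block: int
    row: int
    col: int
    control_type: str = "none"

    def __post_init__(self) -> None:
        if self.control_type not in CONTROL_TYPES:
            raise ValidationError(
                f"spot {self.spot_id!r}: control_type {self.control_type!r} "
                f"not in {CONTROL_TYPES}"
            )
        if self.control_type == "none" and self.substrate_id is None:
            raise ValidationError(f"spot {self.spot_id!r}: substrate spot without substrate_id")
        if self.control_type != "none" and self.substrate_id is not None:
            raise ValidationError(f"spot {self.spot_id!r}: control spot must not carry a substrate_id")


@dataclass
class ChipLayout:
    """Physical geometry and identity of every spot on one chip design."""

    chip_id: str
    spots: list[SpotDef]           # substrate spots only
    controls: list[SpotDef]        # control spots only
    n_substrates: int = field(init=False)
    n_replicates: int = field(init=False)

    def __post_init__(self) -> None:
        per_substrate: dict[str, int] = {}
        coords: set[tuple[int, int, int]] = set()
        ids: set[str] = set()
        for spot in list(self.spots) + list(self.controls):
            key = (spot.block, spot.row, spot.col)
            if key in coords:
                raise FormatError(f"duplicate grid coordinates {key} (spot {spot.spot_id!r})")
            coords.add(key)
            if spot.spot_id in ids:
                raise FormatError(f"duplicate spot_id {spot.spot_id!r}")
            ids.add(spot.spot_id)
        for spot in self.spots:
            per_substrate[spot.substrate_id] = per_substrate.get(spot.substrate_id, 0) + 1
        if not per_substrate:
            raise ValidationError("layout contains no substrate spots")
        counts = set(per_substrate.values())
        if len(counts) > 1:
            bad = min(s for s, c in per_substrate.items() if c != max(counts))
            raise ValidationError(
                f"inconsistent replicate counts across substrates (e.g. {bad!r}); "
                f"counts seen: {sorted(counts)}"
            )
        self.n_substrates = len(per_substrate)
        self.n_replicates = counts.pop()
        for spot in self.spots:
            if not 0 <= spot.replicate_idx < self.n_replicates:
                raise ValidationError(
                    f"spot {spot.spot_id!r}: replicate_idx {spot.replicate_idx} "
                    f"outside [0, {self.n_replicates})"
                )

    @property
    def substrate_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for spot in self.spots:
            seen.setdefault(spot.substrate_id, None)
        return list(seen)

    def control_spots(self, control_type: str) -> list[SpotDef]:
        return [c for c in self.controls if c.control_type == control_type]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.spot_id, s.substrate_id if s.substrate_id is not None else "",
             s.replicate_idx, s.block, s.row, s.col, s.control_type)
            for s in self.spots + self.controls
        ]
        return pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)


@dataclass
class SubstrateAnnotation:
    """Many-to-many substrate -> kinase map; unmapped substrates are allowed."""

    mapping: dict[str, frozenset[str]]

    def kinases_of(self, substrate_id: str) -> frozenset[str]:
        return self.mapping.get(substrate_id, frozenset())

    @property
    def kinase_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for ks in self.mapping.values():
            out |= ks
        return frozenset(out)

    def __post_init__(self) -> None:
        for sub, ks in self.mapping.items():
            if not ks:
                raise ValidationError(f"substrate {sub!r} annotated with an empty kinase set")


@dataclass(frozen=True)
class KinaseRecord:
    """Metadata for one kinase: display name, category tags, known inhibitors."""

    kinase_id: str
    name: str = ""
    description: str = ""
    categories: frozenset[str] = frozenset()
    known_drugs: tuple[str, ...] = ()


@dataclass
class PathwayAnnotation:
    """Pathway -> member-kinase sets, with display names."""

    members: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pw, ks in self.members.items():
            if not ks:
                raise ValidationError(f"pathway {pw!r} has no member kinases")
        for pw in self.members:
            self.names.setdefault(pw, pw)


# ---------------------------------------------------------------------------
# layout IO

def load_layout(path: str | Path, chip_id: str | None = None) -> ChipLayout:
    """Read a spot-layout TSV and return a validated :class:`ChipLayout`.

    The file must carry the columns ``spot_id, substrate_id, replicate_idx,
    block, row, col, control_type``; an empty ``substrate_id`` marks a
    control spot.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing layout columns {missing}")
    spots: list[SpotDef] = []
    controls: list[SpotDef] = []
    for rec in df.itertuples(index=False):
        try:
            spot = SpotDef(
                spot_id=rec.spot_id,
                substrate_id=rec.substrate_id or None,
                replicate_idx=int(rec.replicate_idx),
                block=int(rec.block),
                row=int(rec.row),
                col=int(rec.col),
                control_type=rec.control_type or "none",
            )
        except ValueError as exc:  # int() failures
            raise FormatError(f"{path}: bad row for spot {rec.spot_id!r}: {exc}") from exc
        (controls if spot.control_type != "none" else spots).append(spot)
    return ChipLayout(chip_id=chip_id or path.stem, spots=spots, controls=controls)


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def default_layout(chip_id: str = "default-chip") -> ChipLayout:
    """The packaged chip design: 1024 substrates spotted in triplicate plus
    16 negative and 16 positive controls (spotted once each), laid out on an
    8-block, 20x20 grid, filled row-major.

    Whether the vendor spotted the controls in replicate is not documented;
    single control spots are this package's convention.
    """
    spots: list[SpotDef] = []
    controls: list[SpotDef] = []
    positions = _grid_positions(n_blocks=8, n_rows=20, n_cols=20)
    pos = iter(positions)
    counter = 0
    for i in range(DEFAULT_N_SUBSTRATES):
        sub = f"S{i + 1:04d}"
        for r in range(DEFAULT_N_REPLICATES):
            b, row, col = next(pos)
            spots.append(SpotDef(f"spot{counter:05d}", sub, r, b, row, col))
            counter += 1
    for ctype, prefix, n in (
        ("negative", "NEG", DEFAULT_N_NEGATIVE_CONTROLS),
        ("positive", "POS", DEFAULT_N_POSITIVE_CONTROLS),
    ):
        for i in range(n):
            b, row, col = next(pos)
            controls.append(
                SpotDef(f"{prefix}{i + 1:02d}", None, 0, b, row, col, control_type=ctype)
            )
    return ChipLayout(chip_id=chip_id, spots=spots, controls=controls)


def _grid_positions(n_blocks: int, n_rows: int, n_cols: int) -> list[tuple[int, int, int]]:
    return [(b, r, c) for b in range(n_blocks) for r in range(n_rows) for c in range(n_cols)]


# ---------------------------------------------------------------------------
# annotation IO

def load_annotations(
    substrate_path: str | Path,
    kinase_path: str | Path,
    pathway_path: str | Path,
    layout: ChipLayout | None = None,
) -> tuple[SubstrateAnnotation, list[KinaseRecord], PathwayAnnotation]:
    """Read and cross-validate the three annotation tables.

    Raises :class:`ValidationError` when a substrate or pathway references a
    kinase absent from the kinase table, or (if ``layout`` is given) when an
    annotated substrate is not on the chip.
    """
    kin_df = pd.read_csv(kinase_path, sep="\t", dtype=str, keep_default_na=False)
    if "kinase_id" not in kin_df.columns:
        raise FormatError(f"{kinase_path}: missing 'kinase_id' column")
    kinases: list[KinaseRecord] = []
    seen: set[str] = set()
    for rec in kin_df.itertuples(index=False):
        if rec.kinase_id in seen:
            raise ValidationError(f"duplicate kinase_id {rec.kinase_id!r}")
        seen.add(rec.kinase_id)
        kinases.append(
            KinaseRecord(
                kinase_id=rec.kinase_id,
                name=getattr(rec, "name", rec.kinase_id) or rec.kinase_id,
                description=getattr(rec, "description", "") or "",
                categories=frozenset(t for t in (getattr(rec, "categories", "") or "").split(";") if t),
                known_drugs=tuple(d for d in (getattr(rec, "drugs", "") or "").split(";") if d),
            )
        )
    known = {k.kinase_id for k in kinases}

    sub_df = pd.read_csv(substrate_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("substrate_id", "kinase_id"):
        if col not in sub_df.columns:
            raise FormatError(f"{substrate_path}: missing '{col}' column")
    mapping: dict[str, set[str]] = {}
    for rec in sub_df.itertuples(index=False):
        if rec.kinase_id not in known:
            raise ValidationError(
                f"substrate table references unknown kinase {rec.kinase_id!r}"
            )
        mapping.setdefault(rec.substrate_id, set()).add(rec.kinase_id)
    annotation = SubstrateAnnotation({s: frozenset(k) for s, k in sorted(mapping.items())})

    if layout is not None:
        on_chip = set(layout.substrate_ids)
        off = sorted(set(annotation.mapping) - on_chip)
        if off:
            raise ValidationError(f"annotated substrates absent from layout: {off[:5]}...")
        n_unannotated = len(on_chip - set(annotation.mapping))
        logger.info("annotation covers %d substrates; %d on-chip substrates unannotated",
                    len(annotation.mapping), n_unannotated)

    pathways = load_pathways(pathway_path, known_kinases=known)
    return annotation, kinases, pathways


def load_pathways(path: str | Path, known_kinases: set[str] | None = None) -> PathwayAnnotation:
    """Read a pathway table (TSV with pathway_id/kinase_id, or GMT)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        return _load_gmt(path, known_kinases)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("pathway_id", "kinase_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing '{col}' column")
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for rec in df.itertuples(index=False):
        members.setdefault(rec.pathway_id, set()).add(rec.kinase_id)
        if getattr(rec, "pathway_name", ""):
            names[rec.pathway_id] = rec.pathway_name
    return _validated_pathways(members, names, known_kinases)


def _load_gmt(path: Path, known_kinases: set[str] | None) -> PathwayAnnotation:
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields")
            pw, desc, *ks = parts
            members[pw] = set(k for k in ks if k)
            names[pw] = desc or pw
    return _validated_pathways(members, names, known_kinases)


def _validated_pathways(
    members: Mapping[str, set[str]],
    names: dict[str, str],
    known_kinases: set[str] | None,
) -> PathwayAnnotation:
    for pw, ks in members.items():
        if not ks:
            raise ValidationError(f"pathway {pw!r} is empty")
        if known_kinases is not None:
            unknown = sorted(ks - known_kinases)
            if unknown:
                raise ValidationError(f"pathway {pw!r} references unknown kinases {unknown}")
    return PathwayAnnotation(
        {pw: frozenset(ks) for pw, ks in sorted(members.items())}, dict(names)
    )


def write_annotations(
    annotation: SubstrateAnnotation,
    kinases: Iterable[KinaseRecord],
    pathways: PathwayAnnotation,
    substrate_path: str | Path,
    kinase_path: str | Path,
    pathway_path: str | Path,
) -> None:
    """Write the three annotation tables in the TSV dialect load_annotations reads."""
    sub_rows = [
        (s, k) for s, ks in sorted(annotation.mapping.items()) for k in sorted(ks)
    ]
    pd.DataFrame(sub_rows, columns=["substrate_id", "kinase_id"]).to_csv(
        substrate_path, sep="\t", index=False
    )
    kin_rows = [
        (k.kinase_id, k.name, k.description, ";".join(sorted(k.categories)), ";".join(k.known_drugs))
        for k in sorted(kinases, key=lambda k: k.kinase_id)
    ]
    pd.DataFrame(kin_rows, columns=["kinase_id", "name", "description", "categories", "drugs"]).to_csv(
        kinase_path, sep="\t", index=False
    )
    pw_rows = [
        (pw, pathways.names.get(pw, pw), k)
        for pw, ks in sorted(pathways.members.items())
        for k in sorted(ks)
    ]
    pd.DataFrame(pw_rows, columns=["pathway_id", "pathway_name", "kinase_id"]).to_csv(
        pathway_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GPR import

def read_gpr(path: str | Path, intensity_column: str = "F532 Median") -> pd.DataFrame:
    """Import quantified spot intensities from a GenePix Results (GPR) file.

    The ATF header block is skipped; ``Name`` maps to ``substrate_id`` and
    ``intensity_column`` (default ``F532 Median``) to ``raw_intensity``.
    Block/Row/Column are converted from GPR's 1-based convention to the
    package's 0-based one. Returns a DataFrame with columns
    ``substrate_id, block, row, col, raw_intensity``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.upper().startswith("ATF"):
            raise FormatError(f"{path}: not an ATF/GPR file (first line {first!r})")
        try:
            n_header = int(fh.readline().split()[0])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed ATF header-count line") from exc
        for _ in range(n_header):
            fh.readline()
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = [h.strip().strip('"') for h in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: no column header after ATF header block")
        required = ["Block", "Row", "Column", "Name", intensity_column]
        idx: dict[str, int] = {}
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: GPR column {col!r} not found")
            idx[col] = header.index(col)
        rows = []
        for rec in reader:
            if not rec or not rec[0].strip():
                continue
            rows.append(
                (
                    rec[idx["Name"]].strip().strip('"'),
                    int(rec[idx["Block"]]) - 1,
                    int(rec[idx["Row"]]) - 1,
                    int(rec[idx["Column"]]) - 1,
                    float(rec[idx[intensity_column]]),
                )
            )
    return pd.DataFrame(rows, columns=["substrate_id", "block", "row", "col", "raw_intensity"])
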