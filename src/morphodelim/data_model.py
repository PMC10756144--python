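"""Domain types and I/O for specimen-level linear measurements.

All stored measurements are in micrometres (µm).  Literature values quoted in
mm enter only through the two explicit conversion helpers
(:func:`cw_from_reported_head_width`, :func:`clspd_from_drawing_ratio`).

Two observer character systems are packaged: ``SC`` (size character CL1,
absolute traits) and ``BS`` (size character CS = (CL2 + CW)/2, trait/size
indices).  Character codes follow standard ant morphometry usage (CL =
cephalic length, CW = head width, SL = scape length, ML = mesosoma length,
PEW/PPW = petiole/postpetiole width, ...).  A few codes are observer-specific
synonyms for the same anatomical measure; those are carried as configurable
aliases (``CWB`` ≡ ``CW``, ``CLYD`` ≡ ``CLSPD``) rather than hard-coded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MorphometryError",
    "CharacterSystem",
    "MorphRecord",
    "Dataset",
    "CentroidMatrix",
    "SC_WORKER",
    "BS_WORKER",
    "BS_GYNE",
    "read_morphometry_table",
    "write_morphometry_table",
    "compute_cs",
    "nest_centroids",
    "cw_from_reported_head_width",
    "clspd_from_drawing_ratio",
]

#: column names reserved for record metadata in wide tables
_META_COLUMNS = ("specimen_id", "nest_id", "caste", "species", "source")

CASTES = ("worker", "gyne")
SOURCES = ("direct", "antweb_image", "drawing_derived")


class MorphometryError(ValueError):
    """Raised for invalid measurement tables, records or configurations."""


@dataclass(frozen=True)
class CharacterSystem:
    """One observer's character recording protocol.

    Parameters
    ----------
    observer_id:
        ``"SC"`` or ``"BS"``.
    characters:
        Character codes recorded under this protocol (µm).
    size_character:
        The absolute-size indicator: a measured character (``CL1`` for SC) or
        a derived one (``CS`` for BS, the mean of CL2 and CW).
    reference_size:
        Size (µm) to which allometrically corrected indices are standardized
        (480 for workers, 850 for gynes under BS).
    aliases:
        Optional map from synonym code to canonical code, e.g.
        ``{"CWB": "CW", "CLYD": "CLSPD"}``.  Default on for the SC system.
    """

    observer_id: str
    characters: tuple[str, ...]
    size_character: str
    reference_size: float
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.characters)) != len(self.characters):
            raise MorphometryError("duplicate character codes in system")
        if self.reference_size <= 0:
            raise MorphometryError("reference_size must be > 0")
        derivable = self.size_character == "CS" and {"CL2", "CW"} <= set(self.characters)
        if self.size_character not in self.characters and not derivable:
            raise MorphometryError(
                f"size character {self.size_character!r} is neither a member of "
                "nor derivable from the character set"
            )

    def canonical(self, code: str) -> str:
        """Resolve an alias to its canonical character code."""
        return self.aliases.get(code, code)

    def knows(self, code: str) -> bool:
        return self.canonical(code) in self.characters or code in self.characters


SC_WORKER = CharacterSystem(
    observer_id="SC",
    characters=(
        "CL1", "CLYD", "APS", "SAPS", "CWB", "FRS", "CLYW",
        "SL", "MW", "PEW", "PPW", "ML", "PEL", "PEH", "NOH",
    ),
    size_character="CL1",
    reference_size=480.0,
    aliases={"CW": "CWB", "CLSPD": "CLYD"},
)

BS_WORKER = CharacterSystem(
    observer_id="BS",
    characters=(
        "CL2", "CW", "SL", "FL", "FR", "FRS", "EL", "PROC",
        "CLSPLM", "CLSPLL", "CLSPD", "ML", "MW", "MPGR",
        "PEW", "PPW", "PEH", "PPH",
    ),
    size_character="CS",
    reference_size=480.0,
    aliases={"CWB": "CW", "CLYD": "CLSPD"},
)

BS_GYNE = CharacterSystem(
    observer_id="BS",
    characters=(
        "CL2", "CW", "SL", "FL", "FR", "EL", "PROC",
        "CLSPLM", "CLSPLL", "CLSPD", "ML", "MW", "MH",
        "PEW", "PPW", "PEH", "PPH",
    ),
    size_character="CS",
    reference_size=850.0,
    aliases={"CWB": "CW", "CLYD": "CLSPD"},
)


@dataclass
class MorphRecord:
    """One specimen's measurement vector (µm) with nest and caste context."""

    specimen_id: str
    nest_id: str
    caste: str
    measurements: dict[str, float]
    species_label: Optional[str] = None
    source: str = "direct"

    def __post_init__(self) -> None:
        if self.caste not in CASTES:
            raise MorphometryError(f"unknown caste {self.caste!r} for {self.specimen_id}")
        if self.source not in SOURCES:
            raise MorphometryError(f"unknown source {self.source!r} for {self.specimen_id}")
        if not self.nest_id:
            raise MorphometryError(f"record {self.specimen_id!r} has empty nest_id")
        for code, value in self.measurements.items():
            if not np.isfinite(value) or value <= 0:
                raise MorphometryError(
                    f"record {self.specimen_id!r}: non-positive or non-numeric "
                    f"measurement {code}={value!r}"
                )

    def get(self, code: str, system: Optional[CharacterSystem] = None) -> float:
        """Look up a measurement, following system aliases and deriving CS."""
        if code in self.measurements:
            return self.measurements[code]
        if system is not None:
            canon = system.canonical(code)
            if canon in self.measurements:
                return self.measurements[canon]
            for alias, target in system.aliases.items():
                if target == code and alias in self.measurements:
                    return self.measurements[alias]
        if code == "CS" and {"CL2", "CW"} <= self.measurements.keys():
            return compute_cs(self)
        raise MorphometryError(f"record {self.specimen_id!r} lacks character {code!r}")

    def has(self, code: str, system: Optional[CharacterSystem] = None) -> bool:
        try:
            self.get(code, system)
            return True
        except MorphometryError:
            return False


@dataclass
class Dataset:
    """A character system plus the records measured under it."""

    system: CharacterSystem
    records: list[MorphRecord]
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise MorphometryError("a Dataset needs at least one record")
        castes = {r.caste for r in self.records}
        if len(castes) > 1:
            raise MorphometryError(
                f"castes may not be mixed within one dataset: found {sorted(castes)}"
            )

    @property
    def caste(self) -> str:
        return self.records[0].caste

    @property
    def nest_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.nest_id, None)
        return list(seen)

    def species_labels(self) -> dict[str, str]:
        return {
            r.specimen_id: r.species_label
            for r in self.records
            if r.species_label is not None
        }

    def complete_records(
        self, characters: Sequence[str]
    ) -> tuple[list[MorphRecord], list[MorphRecord]]:
        """Split records into (complete, incomplete) on the given characters."""
        ok, bad = [], []
        for r in self.records:
            (ok if all(r.has(c, self.system) for c in characters) else bad).append(r)
        return ok, bad

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "specimen_id": r.specimen_id,
                "nest_id": r.nest_id,
                "caste": r.caste,
                "species": r.species_label if r.species_label is not None else "",
                "source": r.source,
            }
            row.update(r.measurements)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, keep: Iterable[str]) -> "Dataset":
        keep = set(keep)
        return dataclasses.replace(
            self, records=[r for r in self.records if r.specimen_id in keep]
        )


@dataclass
class CentroidMatrix:
    """Per-nest arithmetic means over a nest's records.

    ``frame`` is indexed by nest id with one column per character;
    ``counts`` gives the number of records behind each centroid;
    ``excluded`` maps dropped nests to the reason they were dropped.
    """

    frame: pd.DataFrame
    counts: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def nest_ids(self) -> list[str]:
        return list(self.frame.index)


def compute_cs(record: MorphRecord | Mapping[str, float]) -> float:
    """Cephalic size CS: the arithmetic mean of CL2 and CW (µm)."""
    m = record.measurements if isinstance(record, MorphRecord) else record
    try:
        return (m["CL2"] + m["CW"]) / 2.0
    except KeyError as exc:
        raise MorphometryError(f"CS needs CL2 and CW; missing {exc.args[0]}") from exc


def cw_from_reported_head_width(hw_before_eyes: float, factor: float = 1.148) -> float:
    """Convert a literature 'head width before eyes' to maximum head width CW.

    Both values in the caller's units (typically mm for literature data);
    the default conversion factor is the published 1.148.
    """
    if hw_before_eyes <= 0 or factor <= 0:
        raise MorphometryError("head width and conversion factor must be > 0")
    return hw_before_eyes * factor


def clspd_from_drawing_ratio(ratio: float, cw: float) -> float:
    """Recover CLSPD from a drawing-derived CLSPD/CW ratio and a known CW."""
    if ratio <= 0 or cw <= 0:
        raise MorphometryError("ratio and CW must be > 0")
    return ratio * cw


def read_morphometry_table(
    path: str | Path,
    system: CharacterSystem,
    unknown_columns: str = "error",
) -> Dataset:
    """Read a wide CSV/TSV measurement table (one row per specimen, µm).

    Required columns: ``specimen_id``, ``nest_id``, ``caste``; optional
    ``species`` and ``source``; every remaining column is a character code.
    ``unknown_columns`` is ``"error"`` (default) or ``"ignore"`` for columns
    the character system does not know.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"specimen_id": str, "nest_id": str})
    if df.empty:
        raise MorphometryError(f"{path}: empty table")
    for col in ("specimen_id", "nest_id", "caste"):
        if col not in df.columns:
            raise MorphometryError(f"{path}: missing required column {col!r}")

    char_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [c for c in char_cols if not system.knows(c)]
    if unknown and unknown_columns == "error":
        raise MorphometryError(
            f"{path}: unknown character columns {unknown} for system "
            f"{system.observer_id}; pass unknown_columns='ignore' to drop them"
        )
    char_cols = [c for c in char_cols if c not in unknown]

    records = []
    for idx, row in df.iterrows():
        nest = row.get("nest_id")
        if pd.isna(nest) or str(nest).strip() == "":
            raise MorphometryError(f"{path}: row {idx}: missing nest_id")
        meas = {}
        for c in char_cols:
            v = row[c]
            if pd.isna(v):
                continue
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise MorphometryError(
                    f"{path}: specimen {row['specimen_id']!r}, character {c}: "
                    f"non-numeric value {row[c]!r}"
                ) from None
            if v <= 0:
                raise MorphometryError(
                    f"{path}: specimen {row['specimen_id']!r}, character {c}: "
                    f"non-positive value {v}"
                )
            meas[c] = v
        species = row.get("species")
        if species is not None and (pd.isna(species) or str(species).strip() == ""):
            species = None
        source = row.get("source")
        if source is None or pd.isna(source) or str(source).strip() == "":
            source = "direct"
        records.append(
            MorphRecord(
                specimen_id=str(row["specimen_id"]),
                nest_id=str(nest),
                caste=str(row["caste"]).strip().lower(),
                measurements=meas,
                species_label=None if species is None else str(species),
                source=str(source),
            )
        )
    return Dataset(system=system, records=records, notes=f"read from {path.name}")


def write_morphometry_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to wide CSV/TSV (inverse of the reader)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def nest_centroids(
    dataset: Dataset,
    characters: Sequence[str],
    min_n: int = 1,
) -> CentroidMatrix:
    """Arithmetic per-nest means over records complete on ``characters``.

    Nests with fewer than ``min_n`` complete records are excluded and listed
    in the result's ``excluded`` map rather than silently dropped.
    """
    if min_n < 1:
        raise MorphometryError("min_n must be >= 1")
    by_nest: dict[str, list[MorphRecord]] = {}
    for r in dataset.records:
        by_nest.setdefault(r.nest_id, []).append(r)

    rows, counts, excluded = {}, {}, {}
    for nest, recs in by_nest.items():
        complete = [r for r in recs if all(r.has(c, dataset.system) for c in characters)]
        if len(complete) < min_n:
            excluded[nest] = (
                f"{len(complete)} complete record(s) on {len(characters)} "
                f"character(s), need >= {min_n}"
            )
            continue
        values = np.array(
            [[r.get(c, dataset.system) for c in characters] for r in complete]
        )
        rows[nest] = values.mean(axis=0)
        counts[nest] = len(complete)
    if not rows:
        raise MorphometryError("no nest satisfies the completeness requirement")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(characters))
    return CentroidMatrix(
        frame=frame,
        counts=pd.Series(counts, name="n_records"),
        excluded=excluded,
    )
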