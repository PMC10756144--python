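"""Removal of allometric variance (RAV).

Body size in ants depends strongly on larval nutrition, and shape changes
disproportionately with size (allometry).  RAV strips that size-driven
variance so that the remaining differences approximate the genetically
determined character space.  Two procedures are implemented:

``nestwise_residual``
    Within-nest ordinary least-squares regression of each absolute trait on
    a cephalic-length size character; the final slope/intercept is the
    unweighted mean over nests, and corrected values are residuals in µm.
    Needs no prior species hypothesis.

``index_quotient``
    Regression of trait/size index values on cephalic size CS, fitted within
    each hypothesised species and averaged with equal species weight.  The
    corrected index is observed_index / f(CS) · f(reference_size): the index
    a specimen would show at a common reference head size (480 µm workers,
    850 µm gynes).  The published constants were fitted with CS in mm, so
    evaluation converts from stored µm internally.

The published coefficient sets for both procedures are packaged and
retrievable via :func:`load_published_rav`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CentroidMatrix,
    CharacterSystem,
    Dataset,
    MorphRecord,
    MorphometryError,
)

__all__ = [
    "IndexDef",
    "RAVModel",
    "CorrectedMatrix",
    "fit_rav_nestwise",
    "apply_nestwise_residuals",
    "fit_rav_index",
    "apply_rav_index",
    "load_published_rav",
]


@dataclass(frozen=True)
class IndexDef:
    """A shape index: numerator character over denominator ('CS' or a character)."""

    numerator: str
    denominator: str

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass
class RAVModel:
    """Per-character linear size-dependence functions plus correction method.

    ``entries`` maps a character code (nestwise method) or an index name such
    as ``"SL/CS"`` (index method) to ``(slope, intercept)`` of the fitted
    line against the size character.  ``size_units`` records the units the
    line was fitted in (``"um"`` for nestwise residuals, ``"mm"`` for the
    index method); ``reference_size`` is always stored in µm.
    """

    method: str  # "nestwise_residual" | "index_quotient"
    entries: dict[str, tuple[float, float]]
    size_character: str
    size_units: str = "um"
    reference_size: Optional[float] = None  # µm
    index_defs: dict[str, IndexDef] = field(default_factory=dict)
    printed_multipliers: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("nestwise_residual", "index_quotient"):
            raise MorphometryError(f"unknown RAV method {self.method!r}")
        for key, (slope, intercept) in self.entries.items():
            if not (np.isfinite(slope) and np.isfinite(intercept)):
                raise MorphometryError(f"non-finite coefficients for {key!r}")
        if self.method == "index_quotient":
            if self.reference_size is None or self.reference_size <= 0:
                raise MorphometryError("index_quotient needs a positive reference_size")
            ref = self._to_fit_units(self.reference_size)
            for key in self.entries:
                if self.multiplier(key) <= 0:
                    raise MorphometryError(
                        f"f(reference_size) <= 0 for {key!r} at {ref}"
                    )

    def _to_fit_units(self, size_um: float) -> float:
        return size_um / 1000.0 if self.size_units == "mm" else size_um

    def f(self, key: str, size_um: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted line at a size given in µm."""
        slope, intercept = self.entries[key]
        return slope * self._to_fit_units(size_um) + intercept

    def multiplier(self, key: str) -> float:
        """f(reference_size): the rescaling constant of the index method."""
        if self.reference_size is None:
            raise MorphometryError("model has no reference size")
        return float(self.f(key, self.reference_size))

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "size_character": self.size_character,
            "size_units": self.size_units,
            "reference_size_um": self.reference_size,
            "entries": {k: list(v) for k, v in self.entries.items()},
            "index_defs": {
                k: [d.numerator, d.denominator] for k, d in self.index_defs.items()
            },
            "printed_multipliers": self.printed_multipliers,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RAVModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            method=d["method"],
            entries={k: (float(a), float(b)) for k, (a, b) in d["entries"].items()},
            size_character=d["size_character"],
            size_units=d["size_units"],
            reference_size=d["reference_size_um"],
            index_defs={
                k: IndexDef(n, dn) for k, (n, dn) in d.get("index_defs", {}).items()
            },
            printed_multipliers=d.get("printed_multipliers", {}),
            metadata=d.get("metadata", {}),
        )


@dataclass
class CorrectedMatrix:
    """Size-corrected values per specimen or nest.

    Columns are residuals (µm, nestwise method) or size-standardized indices
    (index method); ``size`` carries the absolute-size annotation (µm) that
    is deliberately kept out of the corrected columns.
    """

    frame: pd.DataFrame
    model: RAVModel
    size: Optional[pd.Series] = None
    excluded: dict[str, str] = field(default_factory=dict)

    def with_size_column(self, name: Optional[str] = None) -> pd.DataFrame:
        """Corrected columns plus the absolute-size annotation column."""
        out = self.frame.copy()
        if self.size is not None:
            out[name or self.model.size_character] = self.size
        return out


# ---------------------------------------------------------------------------
# published constants
# ---------------------------------------------------------------------------

# Index-on-CS lines (CS in mm) with the printed trailing multipliers.
# index name -> (slope, intercept, printed multiplier at the reference size)
_WORKER_BS_FUNCTIONS: dict[str, tuple[float, float, float]] = {
    "CL2/CW":    (-0.5634, 1.4390, 1.1685),
    "SL/CS":     (-0.1460, 0.7688, 0.6987),
    "FL/CS":     (0.0036, 0.2223, 0.2241),
    "FR/CS":     (0.0131, 0.2083, 0.2146),
    "EL/CS":     (0.0772, 0.0575, 0.0945),
    "PROC/CS":   (-0.0135, 0.1939, 0.1874),
    "CLSPLM/CS": (-0.0388, 0.0750, 0.0564),
    "CLSPLL/CS": (-0.0239, 0.0314, 0.0199),
    "CLSPD/CS":  (0.1082, 0.0833, 0.1353),
    "ML/CS":     (-0.0094, 1.1853, 1.1808),
    "MW/CS":     (-0.0881, 0.6335, 0.5912),
    "MPGR/CS":   (0.0051, 0.0244, 0.0269),
    "PEW/CS":    (0.0259, 0.2943, 0.3068),
    "PPW/CS":    (-0.0592, 0.3556, 0.3271),
    "PEH/CS":    (-0.1487, 0.4487, 0.3773),
    "PPH/CS":    (-0.0011, 0.3058, 0.3006),
}

_GYNE_BS_FUNCTIONS: dict[str, tuple[float, float, float]] = {
    "CL2/CW":    (-0.2881, 1.1973, 0.9524),
    "SL/CS":     (-0.2677, 0.8775, 0.6500),
    "FL/CS":     (-0.1515, 0.3890, 0.2602),
    "FR/CS":     (-0.1466, 0.3834, 0.2588),
    "EL/CS":     (-0.1448, 0.4169, 0.2938),
    "PROC/CS":   (0.0899, 0.0388, 0.1152),
    "CLSPLM/CS": (0.0108, 0.0403, 0.0494),
    "CLSPLL/CS": (0.0504, -0.0304, 0.0125),
    "CLSPD/CS":  (0.0011, 0.1395, 0.1405),
    "ML/CS":     (0.5567, 1.5727, 2.0459),
    "MW/CS":     (0.7122, 0.4779, 1.0833),
    "MH/CS":     (0.6220, 0.7668, 1.2854),
    "PEW/CS":    (-0.1511, 0.5986, 0.4701),
    "PPW/CS":    (-0.2844, 0.7683, 0.5265),
    "PEH/CS":    (0.1010, 0.4025, 0.4883),
    "PPH/CS":    (-0.1000, 0.5682, 0.4832),
}

# Trait-on-CL1 lines (µm) for the nestwise residual method.
# character -> (slope, intercept)
_WORKER_SC_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "CLYD": (0.038, 1.555),
    "APS":  (0.239, 74.015),
    "SAPS": (0.143, 5.354),
    "CWB":  (1.020, -110.076),
    "FRS":  (0.219, -10.728),
    "CLYW": (0.168, -33.917),
    "SL":   (0.611, -3.445),
    "MW":   (0.562, -14.713),
    "PEW":  (0.321, -14.704),
    "PPW":  (0.296, 5.081),
    "ML":   (1.183, -60.970),
    "PEL":  (0.400, -11.529),
    "PEH":  (0.294, 26.156),
    "NOH":  (0.196, 2.364),
}


def _index_defs_for(keys: Sequence[str]) -> dict[str, IndexDef]:
    defs = {}
    for k in keys:
        num, den = k.split("/")
        defs[k] = IndexDef(num, den)
    return defs


def load_published_rav(caste: str, system: str) -> RAVModel:
    """Return the published correction constants as a ready-to-apply model.

    Combinations: ``("worker", "BS")`` and ``("gyne", "BS")`` give the 16
    index-on-CS functions standardized to 480 and 850 µm respectively;
    ``("worker", "SC")`` gives the 14 trait-on-CL1 residual coefficient pairs.
    """
    key = (caste, system)
    if key == ("worker", "BS") or key == ("gyne", "BS"):
        table = _WORKER_BS_FUNCTIONS if caste == "worker" else _GYNE_BS_FUNCTIONS
        ref = 480.0 if caste == "worker" else 850.0
        return RAVModel(
            method="index_quotient",
            entries={k: (s, i) for k, (s, i, _) in table.items()},
            size_character="CS",
            size_units="mm",
            reference_size=ref,
            index_defs=_index_defs_for(list(table)),
            printed_multipliers={k: m for k, (_, _, m) in table.items()},
            metadata={"origin": "published", "caste": caste, "system": system},
        )
    if key == ("worker", "SC"):
        return RAVModel(
            method="nestwise_residual",
            entries=dict(_WORKER_SC_COEFFICIENTS),
            size_character="CL1",
            size_units="um",
            metadata={"origin": "published", "caste": caste, "system": system},
        )
    raise MorphometryError(f"no published RAV constants for caste={caste!r}, system={system!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise MorphometryError("degenerate regression: size character is constant")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    return slope, ym - slope * xm


def fit_rav_nestwise(
    dataset: Dataset,
    size_char: str = "CL1",
    min_nest_n: int = 3,
    characters: Optional[Sequence[str]] = None,
) -> RAVModel:
    """Fit trait-on-size lines within each nest, then average over nests.

    Every qualifying nest (>= ``min_nest_n`` records complete on the trait
    and the size character, non-constant size) contributes one OLS
    slope/intercept per trait; the model stores their unweighted means.
    Excluded nests are counted per trait in the model metadata.
    """
    system = dataset.system
    if characters is None:
        characters = [c for c in system.characters if c != size_char]
    by_nest: dict[str, list[MorphRecord]] = {}
    for r in dataset.records:
        by_nest.setdefault(r.nest_id, []).append(r)

    entries: dict[str, tuple[float, float]] = {}
    nests_used: dict[str, int] = {}
    excluded: dict[str, list[str]] = {}
    for char in characters:
        slopes, intercepts = [], []
        dropped = []
        for nest, recs in by_nest.items():
            pts = [
                (r.get(size_char, system), r.get(char, system))
                for r in recs
                if r.has(size_char, system) and r.has(char, system)
            ]
            if len(pts) < min_nest_n:
                dropped.append(f"{nest}: n={len(pts)} < {min_nest_n}")
                continue
            x = np.array([p[0] for p in pts])
            y = np.array([p[1] for p in pts])
            if np.ptp(x) == 0:
                dropped.append(f"{nest}: constant {size_char}")
                continue
            s, i = _ols(x, y)
            slopes.append(s)
            intercepts.append(i)
        if not slopes:
            excluded[char] = dropped
            continue
        entries[char] = (float(np.mean(slopes)), float(np.mean(intercepts)))
        nests_used[char] = len(slopes)
        if dropped:
            excluded[char] = dropped
    if not entries:
        raise MorphometryError(
            f"no nest qualifies for any character (size_char={size_char!r}, "
            f"min_nest_n={min_nest_n})"
        )
    return RAVModel(
        method="nestwise_residual",
        entries=entries,
        size_character=size_char,
        size_units="um",
        metadata={"origin": "fitted", "nests_used": nests_used,
                  "excluded_nests": excluded, "min_nest_n": min_nest_n},
    )


def apply_nestwise_residuals(
    dataset: Dataset,
    model: RAVModel,
    on_missing: str = "exclude",
) -> CorrectedMatrix:
    """Residuals observed − (slope·size + intercept) per character, in µm.

    A record lacking the size character is excluded; a record lacking some
    model characters gets NaN residuals there and is flagged in ``excluded``
    (or rejected outright with ``on_missing="error"``).
    """
    if model.method != "nestwise_residual":
        raise MorphometryError("model is not a nestwise_residual RAV model")
    system = dataset.system
    size_char = model.size_character
    chars = list(model.entries)
    rows, sizes, excluded = {}, {}, {}
    for r in dataset.records:
        if not r.has(size_char, system):
            if on_missing == "error":
                raise MorphometryError(
                    f"record {r.specimen_id!r} lacks size character {size_char!r}"
                )
            excluded[r.specimen_id] = f"missing {size_char}"
            continue
        missing = [c for c in chars if not r.has(c, system)]
        if missing:
            if on_missing == "error":
                raise MorphometryError(
                    f"record {r.specimen_id!r} lacks {missing} for residual RAV"
                )
            if len(missing) == len(chars):
                excluded[r.specimen_id] = "no model character present"
                continue
            excluded[r.specimen_id] = f"missing {missing}"
        size = r.get(size_char, system)
        rows[r.specimen_id] = [
            r.get(c, system) - model.f(c, size) if r.has(c, system) else np.nan
            for c in chars
        ]
        sizes[r.specimen_id] = size
    if not rows:
        raise MorphometryError("no record carries the size character")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=chars)
    return CorrectedMatrix(
        frame=frame, model=model,
        size=pd.Series(sizes, name=size_char), excluded=excluded,
    )


def _record_index_value(
    r: MorphRecord, d: IndexDef, system: CharacterSystem
) -> Optional[float]:
    num_ok = r.has(d.numerator, system)
    den_ok = d.denominator == "CS" or r.has(d.denominator, system)
    if not (num_ok and den_ok):
        return None
    num = r.get(d.numerator, system)
    den = r.get("CS", system) if d.denominator == "CS" else r.get(d.denominator, system)
    if den <= 0:
        raise MorphometryError(f"record {r.specimen_id!r}: non-positive denominator")
    return num / den


def default_index_set(system: CharacterSystem) -> list[IndexDef]:
    """The standard BS index battery: CL2/CW plus every other trait over CS."""
    out = [IndexDef("CL2", "CW")]
    for c in system.characters:
        if c in ("CL2", "CW"):
            continue
        out.append(IndexDef(c, "CS"))
    return out


def fit_rav_index(
    dataset: Dataset,
    species_labels: Optional[Mapping[str, str]] = None,
    size_char: str = "CS",
    reference_size: Optional[float] = None,
    indices: Optional[Sequence[IndexDef]] = None,
    allow_single_species: bool = False,
    min_species_n: int = 3,
) -> RAVModel:
    """Fit index-on-CS lines per species and average with equal species weight.

    Requires a prior species hypothesis (labels on the records or passed as a
    ``specimen_id -> species`` map).  Single-species fitting — used when only
    one species has sufficient sample size — must be requested explicitly via
    ``allow_single_species``.  CS is converted to mm during fitting so that
    coefficients are commensurate with the published constants.
    """
    system = dataset.system
    if size_char != "CS":
        raise MorphometryError("the index method regresses on cephalic size CS")
    if reference_size is None:
        reference_size = system.reference_size
    labels = dict(dataset.species_labels())
    if species_labels:
        labels.update(species_labels)
    by_species: dict[str, list[MorphRecord]] = {}
    for r in dataset.records:
        sp = labels.get(r.specimen_id)
        if sp is not None:
            by_species.setdefault(sp, []).append(r)
    by_species = {sp: rs for sp, rs in by_species.items() if len(rs) >= min_species_n}
    if not by_species:
        raise MorphometryError(f"no species with >= {min_species_n} labeled records")
    if len(by_species) < 2 and not allow_single_species:
        raise MorphometryError(
            "index RAV needs >= 2 labeled species; pass allow_single_species=True "
            "to fit from one species only"
        )
    if indices is None:
        indices = default_index_set(system)

    entries: dict[str, tuple[float, float]] = {}
    index_defs: dict[str, IndexDef] = {}
    for d in indices:
        slopes, intercepts = [], []
        for sp, recs in sorted(by_species.items()):
            pts = []
            for r in recs:
                v = _record_index_value(r, d, system)
                if v is not None:
                    pts.append((r.get("CS", system) / 1000.0, v))
            if len(pts) < min_species_n:
                continue
            x = np.array([p[0] for p in pts])
            y = np.array([p[1] for p in pts])
            if np.ptp(x) == 0:
                raise MorphometryError(
                    f"species {sp!r} has constant CS; cannot fit {d.name}"
                )
            s, i = _ols(x, y)
            slopes.append(s)
            intercepts.append(i)
        if not slopes:
            continue
        entries[d.name] = (float(np.mean(slopes)), float(np.mean(intercepts)))
        index_defs[d.name] = d
    if not entries:
        raise MorphometryError("no index could be fitted")
    return RAVModel(
        method="index_quotient",
        entries=entries,
        size_character="CS",
        size_units="mm",
        reference_size=float(reference_size),
        index_defs=index_defs,
        metadata={"origin": "fitted", "species": sorted(by_species),
                  "n_per_species": {sp: len(rs) for sp, rs in by_species.items()}},
    )


def apply_rav_index(
    records: Dataset | Sequence[MorphRecord],
    model: RAVModel,
    on_missing: str = "exclude",
) -> CorrectedMatrix:
    """Standardize index values to the model's reference head size.

    corrected = observed_index / f(CS) × f(reference_size); at
    CS = reference_size the correction is the identity.
    """
    if model.method != "index_quotient":
        raise MorphometryError("model is not an index_quotient RAV model")
    if isinstance(records, Dataset):
        system = records.system
        recs = records.records
    else:
        recs = list(records)
        system = None
    keys = list(model.entries)
    rows, sizes, excluded = {}, {}, {}
    for r in recs:
        if not r.has("CS", system):
            if on_missing == "error":
                raise MorphometryError(f"record {r.specimen_id!r} lacks CS")
            excluded[r.specimen_id] = "missing CS"
            continue
        cs = r.get("CS", system)
        vals, missing = [], []
        for k in keys:
            d = model.index_defs.get(k)
            if d is None:
                raise MorphometryError(f"model entry {k!r} has no index definition")
            v = _record_index_value(r, d, system)
            if v is None:
                missing.append(k)
                vals.append(np.nan)
                continue
            fcs = model.f(k, cs)
            if fcs <= 0:
                raise MorphometryError(
                    f"record {r.specimen_id!r}: f(CS)={fcs:.4f} <= 0 for {k}"
                )
            vals.append(v / fcs * model.multiplier(k))
        if missing and on_missing == "error":
            raise MorphometryError(f"record {r.specimen_id!r} lacks {missing}")
        if len(missing) == len(keys):
            excluded[r.specimen_id] = "no index computable"
            continue
        rows[r.specimen_id] = vals
        sizes[r.specimen_id] = cs
    if not rows:
        raise MorphometryError("no record yields any corrected index")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=keys)
    return CorrectedMatrix(
        frame=frame, model=model,
        size=pd.Series(sizes, name="CS"), excluded=excluded,
    )
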