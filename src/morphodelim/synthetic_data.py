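"""Generator of nest-structured, allometry-bearing morphometric datasets.

The model mirrors what the analyses assume about real samples.  Each species
has a grand mean body size; a nest draws an additive Gaussian size effect
(larval nutrition is shared within a colony), each specimen adds individual
size noise, and optionally sizes come from a two-mode mixture (worker or
gyne size dimorphism).  Every character is linear in size —
``char = intercept + slope · size + Gaussian noise`` — which is the linear
allometry the correction procedures are built to remove.  For CS-based
systems the head measurements CL2 and CW are generated through a head-shape
ratio line so that the computed cephalic size CS = (CL2 + CW)/2 equals the
latent size exactly.

The packaged two-species scenario defaults reproduce the published species
parameters: per-character lines are derived from the published index-on-CS
functions and the per-species corrected index means, so that after RAV the
simulated indices match the published means and SDs, and the raw indices
show the published allometric size dependence.  Nest effects act on size
only; character-level nest effects are a documented simplification.

Values are kept strictly positive by resampling a violating specimen, not by
truncation, so moments stay close to their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .data_model import (
    BS_GYNE,
    BS_WORKER,
    CharacterSystem,
    Dataset,
    MorphRecord,
    MorphometryError,
)
from .rav import _GYNE_BS_FUNCTIONS, _WORKER_BS_FUNCTIONS

__all__ = [
    "CharModel",
    "RatioPairModel",
    "SizeMixture",
    "SpeciesConfig",
    "SimulationConfig",
    "TruthTable",
    "simulate_dataset",
    "default_config",
]

SCENARIOS = ("fugax_juliae_workers", "fugax_juliae_gynes", "null_one_species")


@dataclass(frozen=True)
class CharModel:
    """char = intercept + slope·size + N(0, resid_sd), all in µm."""

    slope: float
    intercept: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise MorphometryError("residual SD must be >= 0")


@dataclass(frozen=True)
class RatioPairModel:
    """Generate CL2 and CW from a CL2/CW-ratio line so that CS equals size.

    ratio = intercept + slope·size + N(0, resid_sd);
    CL2 = 2·ratio·size/(1+ratio), CW = 2·size/(1+ratio).
    """

    slope: float
    intercept: float
    resid_sd: float


@dataclass(frozen=True)
class SizeMixture:
    """Two-mode size dimorphism: modes in µm, ``weight`` = share of mode 1."""

    modes: tuple[float, float]
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise MorphometryError("mixture weight must be in [0, 1]")


@dataclass
class SpeciesConfig:
    name: str
    mean_size: float  # µm (ignored for the base draw when a mixture is set)
    between_nest_sd: float
    within_nest_sd: float
    n_nests: int
    records_per_nest: tuple[int, int] = (3, 5)
    characters: dict[str, CharModel] = field(default_factory=dict)
    ratio_pair: Optional[RatioPairModel] = None
    mixture: Optional[SizeMixture] = None

    def __post_init__(self) -> None:
        if self.between_nest_sd < 0 or self.within_nest_sd < 0:
            raise MorphometryError("size SDs must be >= 0")
        lo, hi = self.records_per_nest
        if not 1 <= lo <= hi:
            raise MorphometryError("records_per_nest bounds must satisfy 1 <= lo <= hi")
        if self.n_nests < 1:
            raise MorphometryError("n_nests must be >= 1")
        total_sd = float(np.hypot(self.between_nest_sd, self.within_nest_sd))
        base_means = self.mixture.modes if self.mixture else (self.mean_size,)
        for m in base_means:
            p_neg = 1.0 if total_sd == 0 and m <= 0 else (
                0.0 if total_sd == 0 else float(norm.cdf(0.0, loc=m, scale=total_sd))
            )
            if p_neg > 0.01:
                raise MorphometryError(
                    f"species {self.name!r}: P(size <= 0) = {p_neg:.3f} > 1%; "
                    "increase the mean size or reduce the size SDs"
                )


@dataclass
class SimulationConfig:
    system: CharacterSystem
    caste: str
    species: list[SpeciesConfig]
    scenario: str = "custom"

    def __post_init__(self) -> None:
        if not self.species:
            raise MorphometryError("need at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise MorphometryError("duplicate species names")


@dataclass
class TruthTable:
    specimen_species: dict[str, str]
    nest_species: dict[str, str]


def _draw_specimen(
    rng: np.random.Generator,
    sp: SpeciesConfig,
    nest_effect: float,
    size_char: str,
) -> dict[str, float]:
    for _ in range(100):
        if sp.mixture is not None:
            base = sp.mixture.modes[0] if rng.random() < sp.mixture.weight \
                else sp.mixture.modes[1]
        else:
            base = sp.mean_size
        size = base + nest_effect + rng.normal(0.0, sp.within_nest_sd)
        if size <= 0:
            continue
        meas: dict[str, float] = {}
        if sp.ratio_pair is not None:
            rp = sp.ratio_pair
            ratio = rp.intercept + rp.slope * size + rng.normal(0.0, rp.resid_sd)
            if ratio <= 0:
                continue
            meas["CL2"] = 2.0 * ratio * size / (1.0 + ratio)
            meas["CW"] = 2.0 * size / (1.0 + ratio)
        elif size_char != "CS":
            meas[size_char] = size
        ok = True
        for char, cm in sp.characters.items():
            v = cm.intercept + cm.slope * size + rng.normal(0.0, cm.resid_sd)
            if v <= 0:
                ok = False
                break
            meas[char] = v
        if ok:
            return meas
    raise MorphometryError(
        f"species {sp.name!r}: could not draw a positive specimen in 100 tries; "
        "the configuration implies too-frequent non-positive values"
    )


def simulate_dataset(
    config: SimulationConfig, seed: int = 0
) -> tuple[Dataset, TruthTable]:
    """Draw a nest-structured dataset; bit-reproducible for a given seed."""
    rng = np.random.default_rng(seed)
    size_char = config.system.size_character
    records: list[MorphRecord] = []
    spec_truth: dict[str, str] = {}
    nest_truth: dict[str, str] = {}
    nest_no = 0
    for sp in config.species:
        for _ in range(sp.n_nests):
            nest_no += 1
            nest_id = f"N{nest_no:03d}"
            nest_truth[nest_id] = sp.name
            nest_effect = rng.normal(0.0, sp.between_nest_sd)
            lo, hi = sp.records_per_nest
            n_rec = int(rng.integers(lo, hi + 1))
            for j in range(1, n_rec + 1):
                sid = f"{nest_id}-{j}"
                meas = _draw_specimen(rng, sp, nest_effect, size_char)
                records.append(
                    MorphRecord(
                        specimen_id=sid, nest_id=nest_id, caste=config.caste,
                        measurements=meas,
                    )
                )
                spec_truth[sid] = sp.name
    dataset = Dataset(
        system=config.system, records=records,
        notes=f"simulated scenario={config.scenario} seed={seed}",
    )
    return dataset, TruthTable(specimen_species=spec_truth, nest_species=nest_truth)


# ---------------------------------------------------------------------------
# packaged scenario parameters
# ---------------------------------------------------------------------------

# per-species corrected index means and SDs at the reference size
# (index name -> (mean, sd)); workers standardized to 480 µm, gynes to 850 µm
_WORKER_IDX = {
    "fugax": {
        "CL2/CW": (1.184, 0.022), "SL/CS": (0.705, 0.014), "FL/CS": (0.231, 0.010),
        "FR/CS": (0.221, 0.009), "EL/CS": (0.091, 0.010), "PROC/CS": (0.191, 0.010),
        "CLSPLM/CS": (0.058, 0.005), "CLSPLL/CS": (0.021, 0.006),
        "CLSPD/CS": (0.123, 0.012), "ML/CS": (1.214, 0.029), "MW/CS": (0.601, 0.013),
        "MPGR/CS": (0.028, 0.009), "PEW/CS": (0.320, 0.014), "PPW/CS": (0.333, 0.013),
        "PEH/CS": (0.388, 0.011), "PPH/CS": (0.303, 0.013),
    },
    "juliae": {
        "CL2/CW": (1.152, 0.020), "SL/CS": (0.692, 0.013), "FL/CS": (0.218, 0.007),
        "FR/CS": (0.210, 0.008), "EL/CS": (0.096, 0.005), "PROC/CS": (0.184, 0.008),
        "CLSPLM/CS": (0.055, 0.006), "CLSPLL/CS": (0.018, 0.004),
        "CLSPD/CS": (0.148, 0.009), "ML/CS": (1.155, 0.019), "MW/CS": (0.585, 0.010),
        "MPGR/CS": (0.027, 0.005), "PEW/CS": (0.296, 0.014), "PPW/CS": (0.324, 0.012),
        "PEH/CS": (0.368, 0.012), "PPH/CS": (0.292, 0.010),
    },
}

_GYNE_IDX = {
    "fugax": {
        "CL2/CW": (0.952, 0.024), "SL/CS": (0.650, 0.014), "FL/CS": (0.260, 0.010),
        "FR/CS": (0.259, 0.008), "EL/CS": (0.294, 0.009), "PROC/CS": (0.115, 0.008),
        "CLSPLM/CS": (0.049, 0.006), "CLSPLL/CS": (0.013, 0.003),
        "CLSPD/CS": (0.141, 0.008), "ML/CS": (2.046, 0.046), "MW/CS": (1.083, 0.042),
        "MH/CS": (1.276, 0.038), "PEW/CS": (0.470, 0.026), "PPW/CS": (0.526, 0.029),
        "PEH/CS": (0.488, 0.019), "PPH/CS": (0.483, 0.023),
    },
    "juliae": {
        "CL2/CW": (0.953, 0.012), "SL/CS": (0.643, 0.013), "FL/CS": (0.237, 0.009),
        "FR/CS": (0.233, 0.008), "EL/CS": (0.287, 0.010), "PROC/CS": (0.131, 0.007),
        "CLSPLM/CS": (0.050, 0.006), "CLSPLL/CS": (0.016, 0.005),
        "CLSPD/CS": (0.162, 0.011), "ML/CS": (2.020, 0.053), "MW/CS": (1.052, 0.034),
        "MH/CS": (1.270, 0.054), "PEW/CS": (0.414, 0.016), "PPW/CS": (0.482, 0.024),
        "PEH/CS": (0.482, 0.018), "PPH/CS": (0.465, 0.019),
    },
}

# per-species size distributions: (mean CS µm, total SD µm)
_WORKER_SIZE = {"fugax": (491.0, 67.0), "juliae": (460.0, 48.0)}
_GYNE_SIZE = {"fugax": (897.0, 29.0), "juliae": (798.0, 11.0)}


def _char_line(
    idx_mean: float, fn: tuple[float, float, float],
    ref_um: float, mu_um: float, idx_sd: float,
) -> CharModel:
    """Linearize char(size) = idx_mean · f(size)/f(ref) · size around mu."""
    s, c, _ = fn
    f_ref = s * ref_um / 1000.0 + c

    def char(size_um: float) -> float:
        return idx_mean * (s * size_um / 1000.0 + c) / f_ref * size_um

    delta = 50.0
    slope = (char(mu_um + delta) - char(mu_um - delta)) / (2 * delta)
    intercept = char(mu_um) - slope * mu_um
    return CharModel(slope=slope, intercept=intercept, resid_sd=idx_sd * mu_um)


def _ratio_line(
    idx_mean: float, fn: tuple[float, float, float],
    ref_um: float, mu_um: float, idx_sd: float,
) -> RatioPairModel:
    s, c, _ = fn
    f_ref = s * ref_um / 1000.0 + c

    def ratio(size_um: float) -> float:
        return idx_mean * (s * size_um / 1000.0 + c) / f_ref

    delta = 50.0
    slope = (ratio(mu_um + delta) - ratio(mu_um - delta)) / (2 * delta)
    intercept = ratio(mu_um) - slope * mu_um
    return RatioPairModel(slope=slope, intercept=intercept, resid_sd=idx_sd)


def _species_config(
    name: str, caste: str, n_nests: int,
    records_per_nest: tuple[int, int],
    mixture: Optional[SizeMixture] = None,
) -> SpeciesConfig:
    if caste == "worker":
        functions, idx_table, sizes, ref = (
            _WORKER_BS_FUNCTIONS, _WORKER_IDX, _WORKER_SIZE, 480.0,
        )
    else:
        functions, idx_table, sizes, ref = (
            _GYNE_BS_FUNCTIONS, _GYNE_IDX, _GYNE_SIZE, 850.0,
        )
    mu, total_sd = sizes[name]
    if mixture is not None:
        # the mixture carries the between-mode part of the size variance
        w = mixture.weight
        m1, m2 = mixture.modes
        mix_mean = w * m1 + (1 - w) * m2
        mix_var = w * (m1 - mix_mean) ** 2 + (1 - w) * (m2 - mix_mean) ** 2
        resid_var = max(total_sd**2 - mix_var, (0.2 * total_sd) ** 2)
        between = np.sqrt(resid_var / 4.0)
        within = np.sqrt(resid_var - between**2)
    else:
        # between-nest SD defaults to half the total size SD
        between = total_sd / 2.0
        within = total_sd * np.sqrt(3.0) / 2.0
    chars: dict[str, CharModel] = {}
    ratio_pair: Optional[RatioPairModel] = None
    for idx_name, (m, sd) in idx_table[name].items():
        fn = functions[idx_name]
        if idx_name == "CL2/CW":
            ratio_pair = _ratio_line(m, fn, ref, mu, sd)
        else:
            char = idx_name.split("/")[0]
            chars[char] = _char_line(m, fn, ref, mu, sd)
    return SpeciesConfig(
        name=name, mean_size=mu, between_nest_sd=float(between),
        within_nest_sd=float(within), n_nests=n_nests,
        records_per_nest=records_per_nest, characters=chars,
        ratio_pair=ratio_pair, mixture=mixture,
    )


def default_config(caste: str, scenario: str) -> SimulationConfig:
    """Packaged two-species and null scenarios at the study's sample sizes.

    * ``fugax_juliae_workers`` — 25 + 16 nests of workers, species sizes
      491 ± 67 and 460 ± 48 µm CS.
    * ``fugax_juliae_gynes`` — gynes at 897 ± 29 and 798 ± 11 µm CS, with a
      two-mode size mixture for the larger species so that its microgynes
      overlap the other species' macrogynes.
    * ``null_one_species`` — a single species: the negative control for
      cluster-number estimation.
    """
    if scenario not in SCENARIOS:
        raise MorphometryError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "fugax_juliae_workers":
        if caste != "worker":
            raise MorphometryError("fugax_juliae_workers is a worker scenario")
        return SimulationConfig(
            system=BS_WORKER, caste="worker", scenario=scenario,
            species=[
                _species_config("fugax", "worker", 25, (3, 5)),
                _species_config("juliae", "worker", 16, (3, 5)),
            ],
        )
    if scenario == "fugax_juliae_gynes":
        if caste != "gyne":
            raise MorphometryError("fugax_juliae_gynes is a gyne scenario")
        mixture = SizeMixture(modes=(905.0, 825.0), weight=0.9)
        return SimulationConfig(
            system=BS_GYNE, caste="gyne", scenario=scenario,
            species=[
                _species_config("fugax", "gyne", 16, (1, 3), mixture=mixture),
                _species_config("juliae", "gyne", 8, (1, 2)),
            ],
        )
    # null_one_species
    if caste == "worker":
        return SimulationConfig(
            system=BS_WORKER, caste="worker", scenario=scenario,
            species=[_species_config("fugax", "worker", 25, (3, 5))],
        )
    return SimulationConfig(
        system=BS_GYNE, caste="gyne", scenario=scenario,
        species=[_species_config("fugax", "gyne", 16, (1, 3))],
    )
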