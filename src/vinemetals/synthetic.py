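"""Synthetic point-source pollution gradients with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a smelter-type point source whose soil burden decays exponentially
with distance, a four-layer soil profile with an optional multiplicative
depth trend, deterministic partitioning of each element along the
soil → root → cane → {leaf, grape → must → wine} chain, multiplicative
lognormal replicate noise, and left-censoring below a per-element LOQ.

Every draw is derived deterministically from ``(seed, site, element,
variety, compartment)``, so subsetting the configuration never shifts the
random stream of the remaining cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import CANONICAL_UNITS, DEPTHS, ELEMENTS, RECORD_COLUMNS, validate_records

#: adjacent-compartment pairs along the default transfer chain
CHAIN_PAIRS = (
    ("root", "soil"), ("cane", "root"), ("leaf", "cane"),
    ("grape", "cane"), ("must", "grape"), ("wine", "must"),
)


@dataclass
class ElementTruth:
    """Ground-truth gradient and partition parameters for one element."""

    source_strength: float          # soil concentration at the source, mg/kg
    decay_per_km: float             # exponential distance-decay rate
    partition: dict[str, float]     # ratio per chain step, keyed "root/soil" etc.
    loq: float = 0.0                # censoring threshold (canonical units)
    depth_slope: float = 1.0        # multiplicative trend across the 4 layers

    def __post_init__(self) -> None:
        if self.source_strength < 0 or self.decay_per_km < 0:
            raise ValueError("source strength and decay rate must be nonnegative")
        expected = {f"{a}/{b}" for a, b in CHAIN_PAIRS}
        if set(self.partition) != expected:
            raise ValueError(f"partition must have exactly the keys {sorted(expected)}")
        if any(v < 0 for v in self.partition.values()):
            raise ValueError("partition ratios must be nonnegative")


@dataclass
class SyntheticConfig:
    """Full description of a synthetic study: sites, truth, noise, censoring."""

    seed: int = 0
    sites: list[tuple[str, float]] = field(
        default_factory=lambda: [("Near", 0.0), ("Mid", 5.0), ("Far", 60.0)])
    varieties: list[str] = field(
        default_factory=lambda: ["Feteasca alba", "Feteasca regala", "Italian Riesling"])
    elements: dict[str, ElementTruth] = field(default_factory=dict)
    cv_noise: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be nonnegative")
        if any(d < 0 for _, d in self.sites):
            raise ValueError("distances must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def _cell_rng(seed: int, *key_parts: str) -> np.random.Generator:
    # crc32 of the structured key gives a stable per-cell stream
    crc = zlib.crc32("|".join(key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), crc]))


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and relative spread ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size))


def _true_means(truth: ElementTruth, distance: float) -> dict[str, float]:
    """Noise-free compartment means; soil is the depth-layer average."""
    base = truth.source_strength * np.exp(-truth.decay_per_km * distance)
    layers = [base * truth.depth_slope ** i for i in range(len(DEPTHS))]
    means = {"soil": float(np.mean(layers)), "_layers": layers}
    for num, den in CHAIN_PAIRS:
        means[num] = means[den] * truth.partition[f"{num}/{den}"]
    return means


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate one record table under the configured ground truth."""
    rows = []

    def emit(rng, mean, *, area, distance, variety, compartment, depth=None):
        reps = mean * _lognormal_factors(rng, config.cv_noise, config.n_replicates)
        value = float(reps.mean())
        sd = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
        censored = value < truth.loq
        rows.append({
            "area": area, "distance_km": distance, "variety": variety,
            "compartment": compartment, "depth_cm": depth, "element": el,
            "value": 0.0 if censored else value, "sd": 0.0 if censored else sd,
            "n": config.n_replicates, "unit": CANONICAL_UNITS[compartment],
            "censored": censored,
        })

    for site, distance in config.sites:
        for el, truth in config.elements.items():
            means = _true_means(truth, distance)
            for depth, layer_mean in zip(DEPTHS, means["_layers"]):
                rng = _cell_rng(config.seed, site, el, "soil", depth)
                emit(rng, layer_mean, area=site, distance=distance,
                     variety="n/a", compartment="soil", depth=depth)
            for variety in config.varieties:
                for compartment, _ in CHAIN_PAIRS:
                    rng = _cell_rng(config.seed, site, el, variety, compartment)
                    emit(rng, means[compartment], area=site, distance=distance,
                         variety=variety, compartment=compartment)

    return validate_records(pd.DataFrame(rows, columns=RECORD_COLUMNS))


def replicate_observations(config: SyntheticConfig, compartment: str = "wine") -> pd.DataFrame:
    """Per-replicate element profiles for one compartment.

    One row per (site, variety, replicate), one column per element — the
    observation matrix that multivariate stages (LDA, clustering) consume.
    Draws reuse the per-cell streams of :func:`generate_dataset`, so each
    row is one of the replicates behind the corresponding record mean.
    """
    if compartment == "soil":
        raise ValueError("replicate observations are defined for plant/beverage compartments")
    elements = list(config.elements)
    rows, index = [], []
    for site, distance in config.sites:
        means = {el: _true_means(truth, distance) for el, truth in config.elements.items()}
        for variety in config.varieties:
            reps = {}
            for el in elements:
                rng = _cell_rng(config.seed, site, el, variety, compartment)
                reps[el] = means[el][compartment] * _lognormal_factors(
                    rng, config.cv_noise, config.n_replicates)
            for i in range(config.n_replicates):
                index.append((site, variety, i + 1))
                rows.append({el: reps[el][i] for el in elements})
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["area", "variety", "replicate"]))


def generate_calibration(seed: int, slope: float, intercept: float,
                         resid_sd: float, levels=(2.5, 5.0, 10.0, 25.0, 50.0)) -> pd.DataFrame:
    """Simulate a straight-line calibration series with Gaussian residuals."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if resid_sd < 0:
        raise ValueError("resid_sd must be nonnegative")
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 3:
        raise ValueError("a calibration series needs at least 3 levels")
    rng = np.random.default_rng(int(seed) % (2**31))
    response = intercept + slope * levels + rng.normal(0.0, resid_sd, len(levels))
    return pd.DataFrame({"level": levels, "response": response})


# -------------------------------------------------------------- config I/O

def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["sites"] = [list(s) for s in config.sites]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["sites"] = [tuple(s) for s in doc["sites"]]
    doc["elements"] = {el: ElementTruth(**params) for el, params in doc["elements"].items()}
    return SyntheticConfig(**doc)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The bundled three-site gradient (source, 5 km, 60 km).

    Source strengths mirror heavily polluted topsoil magnitudes, the decay
    rates place the far site at background-like levels, and the partition
    ratios follow the field-observed chain averages, so that the default
    dataset looks like a realistic smelter gradient.
    """
    cfg = config_from_yaml(resources.files("vinemetals.data") / "gradient_default.yaml")
    cfg.seed = int(seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
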