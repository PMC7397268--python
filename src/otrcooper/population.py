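"""Synthetic stave populations: empirical-CDF inverse sampling and parametric models.

The cooperage's original 3064-stave dataset is not distributed, so two
generation routes are provided:

* **Empirical mode** — the production-line procedure itself: build the
  empirical CDF of each feature from a seed sample and draw new values by
  inverse-transform sampling with linear interpolation between order
  statistics. Features are sampled independently.
* **Parametric mode** — calibrated stand-in distributions (truncated
  normals, uniforms, mixtures) whose defaults emulate the published
  population structure: head lengths 42–73 cm, body lengths ≈ 96 cm, body
  widths sized so a 218 cm body takes around 30 staves with bung-capable
  staves (> 10 cm) present, and per-class OTR distributions centred exactly
  on the published class means. All width parameters are synthetic
  defaults — the true cooperage width distribution is not published — and
  every parameter is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from .staves import PART_BODY, PART_HEAD, Stave

# Published stave-population constants ------------------------------------

#: Unweighted mean stave OTR per part over the full cooperage population (hPa/h).
POPULATION_MEAN_OTR = {PART_BODY: 0.03275, PART_HEAD: 0.02928}

#: Mean stave OTR per (part, class) for the preclassified low/high pools (hPa/h).
CLASS_MEAN_OTR = {
    (PART_HEAD, "L"): 0.0148985,
    (PART_BODY, "L"): 0.0165681,
    (PART_HEAD, "H"): 0.0501335,
    (PART_BODY, "H"): 0.0528710,
}

HEAD_LENGTH_RANGE = (420.0, 730.0)  # mm
BODY_LENGTH_MEAN = 960.0  # mm, "approximately 96 cm"
GRAIN_RANGE = (1.88, 4.94)  # mm


# Empirical CDF -------------------------------------------------------------


class EmpiricalCDF:
    """Empirical distribution of a scalar feature.

    ``evaluate`` is the standard right-continuous step ECDF (value i/n at
    the i-th order statistic). ``inverse`` interpolates linearly between
    order statistics at plotting positions (i-1)/(n-1) — numpy's linear
    quantile convention — so u=0 and u=1 map to the sample minimum and
    maximum and intermediate draws fill the gaps the step function leaves
    undefined.
    """

    def __init__(self, values: Sequence[float]):
        v = np.sort(np.asarray(values, dtype=float))
        if v.size == 0:
            raise ValueError("empirical CDF needs at least one value")
        if not np.all(np.isfinite(v)):
            raise ValueError("empirical CDF values must be finite")
        self.values = v

    def evaluate(self, x) -> np.ndarray | float:
        out = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right") / self.values.size
        return out if np.ndim(x) else float(out)

    __call__ = evaluate

    def inverse(self, u) -> np.ndarray | float:
        u_arr = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        out = np.quantile(self.values, u_arr, method="linear")
        return out if np.ndim(u) else float(out)


def empirical_cdf(values: Sequence[float]) -> EmpiricalCDF:
    """Build the empirical CDF of a feature sample."""
    return EmpiricalCDF(values)


def inverse_cdf_sample(cdf: EmpiricalCDF, u):
    """Inverse-transform a uniform(0,1) draw through an empirical CDF."""
    return cdf.inverse(u)


# Feature models ------------------------------------------------------------


class FeatureModel(Protocol):
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray: ...


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [low, high].

    With symmetric bounds around the mean the truncated mean equals ``mean``
    exactly, which is how the class OTR models reproduce the published
    class means.
    """

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)

    @property
    def exact_mean(self) -> float:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class Empirical:
    """Inverse-CDF sampling from a seed sample (the production-line generator)."""

    values: tuple[float, ...]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        cdf = EmpiricalCDF(self.values)
        return np.asarray(cdf.inverse(rng.random(n)))


@dataclass(frozen=True)
class Mixture:
    """Finite mixture of feature models with the given weights."""

    components: tuple
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.components) != len(self.weights):
            raise ValueError("components and weights must have the same length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        which = rng.choice(len(self.components), size=n, p=np.asarray(self.weights))
        out = np.empty(n, dtype=float)
        for k, comp in enumerate(self.components):
            mask = which == k
            cnt = int(mask.sum())
            if cnt:
                out[mask] = comp.sample(cnt, rng)
        return out


@dataclass(frozen=True)
class PopulationModel:
    """Per-feature models for one part kind; features are sampled independently."""

    part: str
    width: FeatureModel
    length: FeatureModel
    otr: FeatureModel
    grain: FeatureModel | None = None
    otr_class: str | None = None  # label stamped on generated staves, if any


def generate_staves(model: PopulationModel, n: int,
                    rng: np.random.Generator | None = None,
                    id_prefix: str = "s") -> list[Stave]:
    """Draw *n* staves from a population model with fresh sequential ids.

    Each feature is drawn from its own model independently of the others,
    mirroring the production-line generation procedure (one uniform random
    vector per feature, pushed through that feature's CDF).
    """
    rng = rng if rng is not None else np.random.default_rng()
    widths = model.width.sample(n, rng)
    lengths = model.length.sample(n, rng)
    otrs = model.otr.sample(n, rng)
    grains = model.grain.sample(n, rng) if model.grain is not None else [None] * n
    return [
        Stave(
            id=f"{id_prefix}{i:05d}",
            part=model.part,
            width=float(widths[i]),
            length=float(lengths[i]),
            otr=float(otrs[i]),
            grain=None if grains[i] is None else float(grains[i]),
            otr_class=model.otr_class,
        )
        for i in range(n)
    ]


# Calibrated defaults --------------------------------------------------------


def default_width_model(part: str) -> FeatureModel:
    """Synthetic stave-width model (mm).

    The bulk of the widths follows truncnorm(72, 15) on [40, 130] mm, so a
    218 cm body takes about 30 staves. Body pools carry an extra 10% "wide"
    component above the 100 mm bung minimum, reflecting that cooperages
    stock bung-capable staves deliberately; heads have no bung requirement
    and use the plain component.
    """
    bulk = TruncatedNormal(mean=72.0, sd=15.0, low=40.0, high=130.0)
    if part == PART_BODY:
        wide = TruncatedNormal(mean=112.0, sd=8.0, low=101.0, high=130.0)
        return Mixture(components=(bulk, wide), weights=(0.9, 0.1))
    return bulk


def default_length_model(part: str) -> FeatureModel:
    """Head lengths uniform on 42–73 cm; body lengths ≈ 96 cm."""
    if part == PART_HEAD:
        return Uniform(*HEAD_LENGTH_RANGE)
    return TruncatedNormal(mean=BODY_LENGTH_MEAN, sd=15.0, low=930.0, high=990.0)


def default_grain_model() -> FeatureModel:
    return Uniform(*GRAIN_RANGE)


def class_otr_model(part: str, label: str, relative_sd: float = 0.15) -> TruncatedNormal:
    """Stave OTR model for a preclassified pool, centred exactly on the
    published class mean (symmetric truncation at ±2.5 sd)."""
    mean = CLASS_MEAN_OTR[(part, label)]
    sd = relative_sd * mean
    return TruncatedNormal(mean=mean, sd=sd, low=max(mean - 2.5 * sd, 0.0), high=mean + 2.5 * sd)


def overall_otr_model(part: str) -> TruncatedNormal:
    """Stave OTR model for a full unclassified pool, centred on the
    published population mean with a realistic ~40% stave-level spread."""
    mean = POPULATION_MEAN_OTR[part]
    sd = 0.0125 if part == PART_BODY else 0.011
    return TruncatedNormal(mean=mean, sd=sd, low=mean - 2.5 * sd, high=mean + 2.5 * sd)


def class_population_model(part: str, label: str) -> PopulationModel:
    """Default model of a preclassified (L or H) stave pool of one part."""
    return PopulationModel(
        part=part,
        width=default_width_model(part),
        length=default_length_model(part),
        otr=class_otr_model(part, label),
        grain=default_grain_model(),
        otr_class=label,
    )


def cooperage_population_model(part: str) -> PopulationModel:
    """Default model of the full (unclassified) stave pool of one part."""
    return PopulationModel(
        part=part,
        width=default_width_model(part),
        length=default_length_model(part),
        otr=overall_otr_model(part),
        grain=default_grain_model(),
    )
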