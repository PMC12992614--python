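"""Dispersal-kernel quantiles.

Converts per-species kernel parameters (Weibull or half-Cauchy) into the two
response variables of the analysis: the median and the 95th-percentile
("long-distance") dispersal distance, on the natural and natural-log scales.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KernelSpec",
    "DispersalSummary",
    "weibull_quantile",
    "halfcauchy_quantile",
    "kernel_summary",
    "summarize_kernels",
]

FAMILIES = ("weibull", "half_cauchy")


@dataclass(frozen=True)
class KernelSpec:
    """Dispersal kernel of one species: family, shape and scale.

    ``shape`` is ignored for the half-Cauchy family (may be None).
    """

    species: str
    family: str
    scale: float
    shape: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not self.scale > 0:
            raise ValueError(f"{self.species}: scale must be > 0")
        if self.family == "weibull" and not (self.shape and self.shape > 0):
            raise ValueError(f"{self.species}: weibull requires shape > 0")


@dataclass(frozen=True)
class DispersalSummary:
    species: str
    median: float
    q95: float
    log_median: float
    log_q95: float


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in the open interval (0, 1), got {p}")


def weibull_quantile(shape: float, scale: float, p: float) -> float:
    """Weibull quantile: scale * (-ln(1-p))**(1/shape)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    _check_p(p)
    return scale * (-np.log1p(-p)) ** (1.0 / shape)


def halfcauchy_quantile(scale: float, p: float) -> float:
    """Half-Cauchy quantile: scale * tan(p * pi / 2)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    _check_p(p)
    return scale * np.tan(p * np.pi / 2.0)


def weibull_cdf(shape: float, scale: float, x) -> float:
    return stats.weibull_min.cdf(x, c=shape, scale=scale)


def halfcauchy_cdf(scale: float, x) -> float:
    return stats.halfcauchy.cdf(x, scale=scale)


def kernel_summary(spec: KernelSpec) -> DispersalSummary:
    """Median and 95th-percentile distance (and their natural logs) of a kernel."""
    if spec.family == "weibull":
        med = weibull_quantile(spec.shape, spec.scale, 0.5)
        q95 = weibull_quantile(spec.shape, spec.scale, 0.95)
    else:
        med = halfcauchy_quantile(spec.scale, 0.5)
        q95 = halfcauchy_quantile(spec.scale, 0.95)
    return DispersalSummary(spec.species, float(med), float(q95),
                            float(np.log(med)), float(np.log(q95)))


def summarize_kernels(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`kernel_summary` over a kernel-parameter table.

    Expects columns ``species``, ``family``, ``shape``, ``scale``; returns a
    DataFrame indexed by species with columns median, q95, log_median, log_q95.
    """
    rows = []
    for rec in table.itertuples(index=False):
        shape = getattr(rec, "shape", None)
        shape = None if shape is None or (isinstance(shape, float) and np.isnan(shape)) else shape
        s = kernel_summary(KernelSpec(rec.species, rec.family, rec.scale, shape))
        rows.append((s.species, s.median, s.q95, s.log_median, s.log_q95))
    out = pd.DataFrame(rows, columns=["species", "median", "q95", "log_median", "log_q95"])
    return out.set_index("species")
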