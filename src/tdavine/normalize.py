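"""Parameterless linear normalization of the amplitude dimension.

Before persistence can be computed on 4-D hyperspace points
(x, y, z, f), the unitless BOLD amplitude must be made commensurate with
the spatial coordinates.  The canonical choice is the unique increasing
linear map whose image range matches the spatial ranges:

* the minimum normalized amplitude equals a0, the average of the per-axis
  coordinate minima, and
* the maximum equals a1, the average of the per-axis coordinate maxima.

Hence the normalized amplitude range equals the average of the three
spatial coordinate ranges, and the construction has no free parameters.
The extremes f_min / f_max are taken over the *whole* series (all time
indices): per-timepoint normalization would erase amplitude dynamics
across time, which is exactly what the vineyard is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Series, ValidationError


@dataclass(frozen=True)
class NormalizationBounds:
    a0: float      # mean of per-axis coordinate minima
    a1: float      # mean of per-axis coordinate maxima
    f_min: float   # raw amplitude minimum over the whole series
    f_max: float   # raw amplitude maximum over the whole series

    def __post_init__(self) -> None:
        if self.a0 > self.a1:
            raise ValidationError("a0 must not exceed a1")
        if self.f_min > self.f_max:
            raise ValidationError("f_min must not exceed f_max")

    def to_dict(self) -> dict:
        return {
            "a0": self.a0, "a1": self.a1,
            "f_min": self.f_min, "f_max": self.f_max,
        }


def compute_bounds(series: Series) -> NormalizationBounds:
    coords = series.coords
    amps = series.amplitude_matrix()
    return NormalizationBounds(
        a0=float(coords.min(axis=0).mean()),
        a1=float(coords.max(axis=0).mean()),
        f_min=float(amps.min()),
        f_max=float(amps.max()),
    )


def normalize_amplitudes(series: Series, bounds: NormalizationBounds | None = None) -> Series:
    """Map amplitudes by the unique increasing linear map f_min->a0, f_max->a1.

    A constant-amplitude series (f_min == f_max) maps to the midpoint
    (a0 + a1) / 2, the symmetric limit of the linear map.
    """
    if bounds is None:
        bounds = compute_bounds(series)
    amps = series.amplitude_matrix()
    if amps.min() < bounds.f_min or amps.max() > bounds.f_max:
        raise ValidationError("series amplitudes fall outside [f_min, f_max]")
    span = bounds.f_max - bounds.f_min
    if span == 0.0:
        out = np.full_like(amps, 0.5 * (bounds.a0 + bounds.a1))
    else:
        out = bounds.a0 + (amps - bounds.f_min) * (bounds.a1 - bounds.a0) / span
    return series.with_amplitude_matrix(out)


def scale_amplitude(series: Series, c: float) -> Series:
    """Dial the amplitude scale by ``c > 0`` about the series-wide mean.

    Mean-centred scaling isolates the scale effect without translating the
    hyperspace cloud; used to probe the dialed-high (homology trivializes)
    and dialed-low (bare lattice) limits.
    """
    if not c > 0:
        raise ValidationError("scale factor must be positive")
    amps = series.amplitude_matrix()
    mean = amps.mean()
    return series.with_amplitude_matrix(mean + c * (amps - mean))
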