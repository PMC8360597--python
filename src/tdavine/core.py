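"""Core containers for time-indexed voxel point clouds.

A time point cloud is the set of voxels observed at one fMRI time index,
each carrying its (x, y, z) stereotactic coordinate and a scalar signal
amplitude.  A series stacks clouds over time with a fixed voxel set, so that
per-timepoint persistence diagrams are comparable across time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FormatError(ValueError):
    """A table could not be parsed as x, y, z, amplitude rows."""


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, misalignment...)."""


class ResourceError(RuntimeError):
    """A computation would exceed a configured size cap."""


@dataclass(frozen=True)
class TimePointCloud:
    """Voxels with amplitudes at a single time index.

    Parameters
    ----------
    t
        Non-negative integer time index.
    coords
        ``(n, 3)`` float array of stereotactic coordinates.  The unit
        (voxel index or mm) is whatever the source table used.
    amplitudes
        ``(n,)`` float array of signal amplitudes, unitless.
    """

    t: int
    coords: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"coords must be (n, 3), got {coords.shape}")
        if amps.shape != (coords.shape[0],):
            raise ValidationError("amplitudes must match coords length")
        if coords.shape[0] == 0:
            raise ValidationError("point cloud must be non-empty")
        if not np.isfinite(coords).all():
            raise ValidationError("non-finite coordinate")
        if not np.isfinite(amps).all():
            raise ValidationError("non-finite amplitude")
        if self.t < 0:
            raise ValidationError("time index must be >= 0")
        uniq = np.unique(coords, axis=0)
        if uniq.shape[0] != coords.shape[0]:
            raise ValidationError("duplicate voxel coordinates")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "amplitudes", amps)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def with_amplitudes(self, amps: np.ndarray) -> "TimePointCloud":
        return TimePointCloud(self.t, self.coords, np.asarray(amps, dtype=float))


@dataclass(frozen=True)
class Series:
    """Ordered time point clouds ``t = 0 .. T-1`` over one fixed voxel set."""

    clouds: tuple[TimePointCloud, ...]

    def __post_init__(self) -> None:
        clouds = tuple(self.clouds)
        if not clouds:
            raise ValidationError("series must contain at least one cloud")
        ref = clouds[0].coords
        for k, c in enumerate(clouds):
            if c.t != k:
                raise ValidationError(f"cloud {k} has time index {c.t}")
            if c.coords.shape != ref.shape or not np.array_equal(c.coords, ref):
                raise ValidationError(
                    f"cloud at t={k} has a different voxel set/order than t=0"
                )
        object.__setattr__(self, "clouds", clouds)

    @property
    def T(self) -> int:
        return len(self.clouds)

    @property
    def coords(self) -> np.ndarray:
        return self.clouds[0].coords

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def amplitude_matrix(self) -> np.ndarray:
        """``(T, n)`` matrix of amplitudes."""
        return np.stack([c.amplitudes for c in self.clouds])

    def with_amplitude_matrix(self, amps: np.ndarray) -> "Series":
        amps = np.asarray(amps, dtype=float)
        if amps.shape != (self.T, self.n_points):
            raise ValidationError("amplitude matrix shape mismatch")
        return Series(
            tuple(c.with_amplitudes(a) for c, a in zip(self.clouds, amps))
        )


@dataclass(frozen=True)
class MaskRegion:
    """Axis-aligned closed box or explicit voxel list in stereotactic space.

    Exactly one of ``box`` / ``voxels`` is set.  Box membership is tested
    per axis with closed intervals ``lo <= v <= hi``.
    """

    box: np.ndarray | None = None          # (2, 3): [lo; hi]
    voxels: np.ndarray | None = None       # (m, 3)

    def __post_init__(self) -> None:
        if (self.box is None) == (self.voxels is None):
            raise ValidationError("specify exactly one of box or voxels")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (2, 3):
                raise ValidationError("box must be (2, 3): [min; max]")
            if np.any(box[0] > box[1]):
                raise ValidationError("box min exceeds max on some axis")
            object.__setattr__(self, "box", box)
        else:
            vox = np.asarray(self.voxels, dtype=float)
            if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] == 0:
                raise ValidationError("voxel list must be non-empty (m, 3)")
            object.__setattr__(self, "voxels", vox)

    @classmethod
    def from_bounds(cls, lo, hi) -> "MaskRegion":
        return cls(box=np.array([lo, hi], dtype=float))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an ``(n, 3)`` array of coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.box is not None:
            lo, hi = self.box
            return np.all((points >= lo) & (points <= hi), axis=1)
        # explicit voxel set: exact coordinate match
        vox = {tuple(v) for v in self.voxels}
        return np.array([tuple(p) in vox for p in points], dtype=bool)
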