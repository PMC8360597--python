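"""Seeded generators for toy geometries and block-design task series.

Everything the pipeline is validated against is generated here: the
displaced-center "bumpy cube" (a 2-sphere-like shell), a cylinder-surface
lattice (one dominant loop), a ring-of-low-amplitude volume (the canonical
hyperspace two-component picture), and a full block-design task series in
which a loop of contrasting amplitude is switched on during one condition.
Each generator is a pure function of its parameters and seed, and each
fixture's ground truth is machine-checkable by running the real pipeline.

Grids are kept small (a few hundred voxels) so that full Vietoris-Rips H1
runs in seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MaskRegion, Series, TimePointCloud, ValidationError
from .stats import TaskDesign

DEFAULT_CYCLE = ("encoding", "consolidation", "retrieval", "consolidation")


def _lattice(grid) -> np.ndarray:
    nx_, ny, nz = grid
    g = np.mgrid[0:nx_, 0:ny, 0:nz].reshape(3, -1).T.astype(float)
    return g


def bumpy_cube(displacement: float = 5.0) -> TimePointCloud:
    """The 27 points of {0,1,2}^3 with the center pushed out of the cube.

    Corners, edge midpoints and face midpoints of a cube plus a center
    displaced ``displacement`` units along +z: at intermediate ball radii
    the 26-point shell is a bumpy sphere enclosing a void (a positive-
    persistence H2 class), while the displaced center stays isolated.
    """
    if displacement < 0:
        raise ValidationError("displacement must be non-negative")
    pts = _lattice((3, 3, 3))
    center = np.all(pts == 1.0, axis=1)
    pts[center] = (1.0, 1.0, 1.0 + displacement)
    return TimePointCloud(0, pts, np.zeros(len(pts)))


def cylinder_cloud(
    n_angular: int = 24,
    n_height: int = 15,
    radius: float = 6.0,
    spacing: float = 1.0,
    split_sectors: int = 0,
) -> TimePointCloud:
    """Deterministic lattice on a cylinder surface (constant amplitude).

    The tube's first homology is one-dimensional: the pipeline should find
    exactly one dominant H1 class, the loop around the axis.
    ``split_sectors`` removes that many angular sectors from the upper half
    to mimic a tube split along its side.
    """
    if n_angular < 8:
        raise ValidationError("need at least 8 angular samples")
    ang = 2.0 * np.pi * np.arange(n_angular) / n_angular
    pts = []
    for h in range(n_height):
        for k, a in enumerate(ang):
            if split_sectors and h >= n_height // 2 and k < split_sectors:
                continue
            pts.append((radius * np.cos(a), radius * np.sin(a), h * spacing))
    pts = np.array(pts)
    return TimePointCloud(0, pts, np.zeros(len(pts)))


def ring_volume(
    grid=(9, 9, 3), ring_radius: float = 3.0, low: float = 0.0, high: float = 10.0
) -> TimePointCloud:
    """Lattice with a high-amplitude core surrounded by low amplitude.

    Radial step profile around the grid center: ``high`` at radial
    distance below ``ring_radius - 0.5``, ``low`` on the ring and beyond.
    In hyperspace, a large ``high - low`` separates the core from its
    surroundings in the amplitude dimension, giving two components and a
    single dominant non-contractible loop in the low-amplitude component,
    wrapped around the lifted core.  (A third, intermediate level outside
    the ring would spawn a second large loop there and break dominance.)
    """
    if high < low:
        raise ValidationError("high must be >= low")
    pts = _lattice(grid)
    cx = (np.array(grid, dtype=float) - 1.0) / 2.0
    rho = np.hypot(pts[:, 0] - cx[0], pts[:, 1] - cx[1])
    amps = np.full(len(pts), float(low))
    amps[rho < ring_radius - 0.5] = high
    return TimePointCloud(0, pts, amps)


def make_design(
    trs_per_block: int = 9,
    cycle=DEFAULT_CYCLE,
    n_cycles: int = 8,
) -> TaskDesign:
    """Block design of ``n_cycles`` repetitions of the condition cycle.

    Defaults emulate an associative-learning acquisition: 4 conditions
    (encoding, consolidation, cued retrieval, consolidation) x 9 samples
    per 27 s block at TR = 3 s x 8 cycles = 288 time indices.
    """
    if trs_per_block < 1 or n_cycles < 1 or not cycle:
        raise ValidationError("design parameters must be positive")
    labels = []
    for _ in range(n_cycles):
        for cond in cycle:
            labels.extend([cond] * trs_per_block)
    return TaskDesign.from_labels(labels)


@dataclass(frozen=True)
class GroundTruth:
    """Machine-checkable summary of what a generated series embeds."""

    region: MaskRegion
    on_condition: str
    on_indices: tuple[int, ...]
    contrast_on: float
    contrast_off: float


def _ring_core_masks(coords: np.ndarray, center: np.ndarray, ring_radius: float):
    rho = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
    ring = np.abs(rho - ring_radius) <= 0.5
    core = rho < ring_radius - 0.5
    return ring, core


def task_series(
    design: TaskDesign | None = None,
    grid=(9, 9, 1),
    ring_radius: float = 2.0,
    on_condition: str = "encoding",
    contrast_on: float = 4.0,
    contrast_off: float = 0.0,
    noise_sd: float = 0.1,
    baseline: float = 0.0,
    ar_coef: float = 0.0,
    seed: int = 0,
) -> tuple[Series, GroundTruth]:
    """Block-design lattice series with a condition-gated amplitude loop.

    Per time index, amplitudes are ``baseline`` + Gaussian noise (optionally
    AR(1) over time with coefficient ``ar_coef``).  Around the grid center a
    ring of elevated amplitude encircles a depressed core -- a region of
    relatively high signal wrapped around relatively lower signal -- with
    ring-minus-core contrast ``contrast_on`` at ``on_condition`` indices and
    ``contrast_off`` otherwise.  In hyperspace the elevated ring is a
    non-contractible loop whenever the contrast dominates the lattice scale.
    """
    if design is None:
        design = make_design()
    if contrast_on < contrast_off or contrast_off < 0:
        raise ValidationError("need contrast_on >= contrast_off >= 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    coords = _lattice(grid)
    center = (np.array(grid, dtype=float) - 1.0) / 2.0
    ring, core = _ring_core_masks(coords, center, ring_radius)
    if not ring.any() or not core.any():
        raise ValidationError("ring_radius does not fit inside the grid")

    rng = np.random.default_rng(seed)
    T, n = design.T, len(coords)
    noise = rng.normal(0.0, noise_sd, size=(T, n)) if noise_sd > 0 else np.zeros((T, n))
    if ar_coef:
        for t in range(1, T):
            noise[t] = ar_coef * noise[t - 1] + np.sqrt(1 - ar_coef**2) * noise[t]

    amps = baseline + noise
    on = np.array([l == on_condition for l in design.labels])
    contrast = np.where(on, contrast_on, contrast_off)
    amps[:, ring] += (contrast / 2.0)[:, None]
    amps[:, core] -= (contrast / 2.0)[:, None]

    clouds = tuple(TimePointCloud(t, coords, amps[t]) for t in range(T))
    ring_pts = coords[ring]
    margin = 0.5
    region = MaskRegion.from_bounds(
        ring_pts.min(axis=0) - margin, ring_pts.max(axis=0) + margin
    )
    truth = GroundTruth(
        region=region,
        on_condition=on_condition,
        on_indices=tuple(int(t) for t in np.flatnonzero(on)),
        contrast_on=float(contrast_on),
        contrast_off=float(contrast_off),
    )
    return Series(clouds), truth
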