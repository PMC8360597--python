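"""Reading and writing per-timepoint voxel tables.

The on-disk layout mirrors common supplementary-data packaging for masked
fMRI: one comma-separated file per time index with columns x, y, z,
amplitude (header optional), loose in a directory or inside a ZIP archive.
The time index is the trailing integer in the file name (``t0.csv``,
``vol_012.csv``...).  ``read_series`` canonicalizes voxel order
lexicographically by (x, y, z) so all clouds align.
"""

from __future__ import annotations

import io as _io
import re
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FormatError, MaskRegion, Series, TimePointCloud, ValidationError

_TRAILING_INT = re.compile(r"(\d+)\D*$")

COLUMNS = ("x", "y", "z", "amplitude")


def parse_time_index(name: str) -> int:
    """Trailing integer in a file name (extension ignored)."""
    stem = Path(name).stem
    m = _TRAILING_INT.search(stem)
    if m is None:
        raise FormatError(f"no time index found in file name {name!r}")
    return int(m.group(1))


def _frame_to_cloud(df: pd.DataFrame, t: int, source: str) -> TimePointCloud:
    if df.shape[1] < 4:
        raise FormatError(f"{source}: expected >=4 columns, got {df.shape[1]}")
    if df.shape[0] < 1:
        raise FormatError(f"{source}: table has no rows")
    block = df.iloc[:, :4].apply(pd.to_numeric, errors="coerce")
    bad = block.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{source}: non-numeric value in data row {row}")
    arr = block.to_numpy(dtype=float)
    return TimePointCloud(t=t, coords=arr[:, :3], amplitudes=arr[:, 3])


def _read_table(handle, t: int, source: str) -> TimePointCloud:
    df = pd.read_csv(handle, header=None, comment="#")
    # optional single header row ("x,y,z,amplitude" or similar)
    first = df.iloc[0]
    if pd.to_numeric(first, errors="coerce").isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    return _frame_to_cloud(df, t, source)


def read_timepoint_table(path: str | Path, t: int | None = None) -> TimePointCloud:
    """Read one voxel table; ``t`` defaults to the file name's trailing integer."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if t is None:
        t = parse_time_index(path.name)
    return _read_table(path, t, str(path))


def write_timepoint_table(cloud: TimePointCloud, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([cloud.coords, cloud.amplitudes]), columns=COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _canonicalize(cloud: TimePointCloud, t: int) -> TimePointCloud:
    order = np.lexsort((cloud.coords[:, 2], cloud.coords[:, 1], cloud.coords[:, 0]))
    return TimePointCloud(t, cloud.coords[order], cloud.amplitudes[order])


def _assemble(named: list[tuple[str, TimePointCloud]]) -> Series:
    if not named:
        raise ValidationError("no timepoint tables found")
    named.sort(key=lambda nc: nc[1].t)
    indices = [c.t for _, c in named]
    if len(set(indices)) != len(indices):
        dup = [i for i in indices if indices.count(i) > 1][0]
        raise ValidationError(f"duplicate time index {dup} across files")
    clouds = [_canonicalize(c, k) for k, (_, c) in enumerate(named)]
    ref = clouds[0].coords
    for (name, _), c in zip(named, clouds):
        if c.coords.shape != ref.shape or not np.array_equal(c.coords, ref):
            raise ValidationError(
                f"voxel set in {name!r} does not match the first time index"
            )
    return Series(tuple(clouds))


def read_series(path: str | Path) -> Series:
    """Read all ``*.csv`` tables in a directory or ZIP archive as a Series.

    Files are ordered by the numeric time index in their names and the time
    axis is re-indexed to ``0 .. T-1``.
    """
    path = Path(path)
    named: list[tuple[str, TimePointCloud]] = []
    if path.is_dir():
        for f in sorted(path.glob("*.csv")):
            named.append((f.name, read_timepoint_table(f)))
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if info.is_dir() or not info.filename.lower().endswith(".csv"):
                    continue
                t = parse_time_index(info.filename)
                data = zf.read(info).decode()
                named.append(
                    (info.filename, _read_table(_io.StringIO(data), t, info.filename))
                )
    else:
        raise FileNotFoundError(f"{path} is neither a directory nor a ZIP archive")
    return _assemble(named)


def write_series(series: Series, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(series.T - 1)))
    paths = []
    for cloud in series.clouds:
        p = directory / f"t{cloud.t:0{width}d}.csv"
        write_timepoint_table(cloud, p)
        paths.append(p)
    return paths


def apply_mask(series: Series, mask: MaskRegion) -> Series:
    """Restrict every cloud to the voxels inside ``mask`` (closed box test)."""
    keep = mask.contains(series.coords)
    if not keep.any():
        raise ValidationError("mask removed all voxels")
    clouds = tuple(
        TimePointCloud(c.t, c.coords[keep], c.amplitudes[keep])
        for c in series.clouds
    )
    return Series(clouds)


def read_nifti_series(image_path: str | Path, mask_path: str | Path | None = None) -> Series:
    """Convenience adapter: 4-D NIfTI volume (+ optional 3-D binary mask).

    Voxel indices become stereotactic coordinates.  The table path is the
    reference path; this adapter just flattens to the same representation.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=float)
    if img.ndim == 3:
        img = img[..., None]
    if img.ndim != 4:
        raise FormatError(f"expected a 3-D or 4-D volume, got shape {img.shape}")
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != img.shape[:3]:
            raise ValidationError("mask shape does not match image")
    else:
        mask = np.ones(img.shape[:3], dtype=bool)
    idx = np.argwhere(mask).astype(float)
    if idx.shape[0] == 0:
        raise ValidationError("mask removed all voxels")
    clouds = []
    for t in range(img.shape[3]):
        amps = img[..., t][mask]
        clouds.append(TimePointCloud(t, idx, amps))
    return _assemble([(f"vol{t}", c) for t, c in enumerate(clouds)])
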