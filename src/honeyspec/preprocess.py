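"""From cube pairs to labeled transmittance curves.

The fixed processing order is: select a region of interest, tile it into
non-overlapping k x k neighborhoods (k = 4), average each tile into one
spectral curve, then divide sample curves by white-reference curves to
obtain transmittance.  Averaging before dividing matches the acquisition
model (the neighborhood mean estimates the transmitted power P at each
band, and tau = P / W); it differs from divide-then-average whenever the
illumination field varies inside a tile.

Transmittance values slightly above 1 can occur under noise; they are
flagged per curve, never clipped, so noise statistics stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DimensionError,
    DivisionDomainError,
    SamplingError,
)
from .grid import WavelengthGrid
from .synthetic import Hypercube

NEIGHBORHOOD = 4

PROVENANCE_COLUMNS = ["cube_id", "tile_row", "tile_col"]


@dataclass(frozen=True)
class RoiSpec:
    """0-based, half-open rectangular region of interest."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self):
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise DimensionError("ROI must have positive extent")
        if min(self.row_start, self.col_start) < 0:
            raise DimensionError("ROI offsets must be >= 0")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    @classmethod
    def centered(cls, n_rows: int, n_cols: int, size: int) -> "RoiSpec":
        if size > min(n_rows, n_cols):
            raise DimensionError(f"centered ROI of size {size} exceeds cube extent")
        r0 = (n_rows - size) // 2
        c0 = (n_cols - size) // 2
        return cls(r0, r0 + size, c0, c0 + size)


@dataclass(frozen=True)
class SpectralCurveSet:
    """Matrix of per-neighborhood spectra with labels and provenance.

    ``curves`` is (n_curves, n_bands); ``labels`` holds one class label per
    curve; ``provenance`` records cube id and tile coordinates;
    ``flagged`` marks curves with any transmittance value above 1.
    """

    curves: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    provenance: pd.DataFrame
    flagged: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.curves, float)
        if c.ndim != 2 or c.shape[1] != self.grid.n_bands:
            raise ConfigurationError("curves must be (n_curves, n_bands) matching the grid")
        labels = np.asarray(self.labels, dtype=object)
        if labels.shape != (c.shape[0],):
            raise ConfigurationError("one label per curve required")
        if len(self.provenance) != c.shape[0]:
            raise ConfigurationError("one provenance row per curve required")
        if np.any(c < 0):
            raise ConfigurationError("spectral curves must be >= 0")
        object.__setattr__(self, "curves", c)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", self.provenance.reset_index(drop=True))

    @property
    def n_curves(self) -> int:
        return self.curves.shape[0]

    def subset(self, idx) -> "SpectralCurveSet":
        idx = np.asarray(idx)
        return replace(
            self,
            curves=self.curves[idx],
            labels=self.labels[idx],
            provenance=self.provenance.iloc[idx].reset_index(drop=True),
            flagged=None if self.flagged is None else self.flagged[idx],
        )

    # -- persistence -------------------------------------------------------

    def to_csv(self, path) -> None:
        """Wide CSV: label, tile_row, tile_col, cube_id, then one column per band (nm)."""
        frame = pd.DataFrame(
            self.curves, columns=[f"{nm:g}" for nm in self.grid.values]
        )
        frame.insert(0, "cube_id", self.provenance["cube_id"].to_numpy())
        frame.insert(0, "tile_col", self.provenance["tile_col"].to_numpy())
        frame.insert(0, "tile_row", self.provenance["tile_row"].to_numpy())
        frame.insert(0, "label", self.labels)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralCurveSet":
        frame = pd.read_csv(path)
        meta_cols = ["label", "tile_row", "tile_col", "cube_id"]
        band_cols = [c for c in frame.columns if c not in meta_cols]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        curves = frame[band_cols].to_numpy(float)
        provenance = frame[["cube_id", "tile_row", "tile_col"]].copy()
        cs = cls(
            curves=curves,
            grid=grid,
            labels=frame["label"].astype(str).to_numpy(object),
            provenance=provenance,
        )
        return replace(cs, flagged=np.any(curves > 1.0, axis=1))

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("curves", data=self.curves)
            f.create_dataset("wavelengths_nm", data=self.grid.values)
            f.create_dataset(
                "labels", data=np.asarray([str(v) for v in self.labels], dtype="S")
            )
            for col in PROVENANCE_COLUMNS:
                vals = self.provenance[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = np.asarray([str(v) for v in vals], dtype="S")
                f.create_dataset(f"provenance/{col}", data=vals)

    @classmethod
    def from_hdf5(cls, path) -> "SpectralCurveSet":
        with h5py.File(path, "r") as f:
            curves = f["curves"][()]
            grid = WavelengthGrid(f["wavelengths_nm"][()])
            labels = np.asarray([v.decode() for v in f["labels"][()]], dtype=object)
            prov = {}
            for col in PROVENANCE_COLUMNS:
                vals = f[f"provenance/{col}"][()]
                if vals.dtype.kind == "S":
                    vals = np.asarray([v.decode() for v in vals], dtype=object)
                prov[col] = vals
        cs = cls(curves=curves, grid=grid, labels=labels, provenance=pd.DataFrame(prov))
        return replace(cs, flagged=np.any(curves > 1.0, axis=1))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_roi(
    cube: Hypercube,
    roi: RoiSpec | str = "center",
    size: int | None = None,
    neighborhood: int = NEIGHBORHOOD,
) -> Hypercube:
    """Crop a cube to a region of interest, preserving all bands.

    ``roi`` may be an explicit :class:`RoiSpec` or ``"center"`` with a
    ``size`` for a centered square window.  Both extents must be positive
    multiples of the neighborhood side so the tiling downstream is exact.
    """
    _, n_rows, n_cols = cube.shape
    if roi == "center":
        if size is None:
            raise DimensionError("'center' ROI requires a size")
        spec = RoiSpec.centered(n_rows, n_cols, size)
    elif isinstance(roi, RoiSpec):
        spec = roi
    else:
        raise DimensionError(f"unsupported roi {roi!r}")
    if spec.row_stop > n_rows or spec.col_stop > n_cols:
        raise DimensionError("ROI exceeds cube bounds")
    if spec.height % neighborhood or spec.width % neighborhood:
        raise DimensionError(
            f"ROI extent {spec.height}x{spec.width} must be a multiple of {neighborhood}"
        )
    data = cube.data[:, spec.row_start : spec.row_stop, spec.col_start : spec.col_stop]
    meta = dict(cube.metadata)
    meta["roi"] = [spec.row_start, spec.row_stop, spec.col_start, spec.col_stop]
    return Hypercube(data=data, grid=cube.grid, kind=cube.kind, metadata=meta)


def average_neighborhoods(
    cube: Hypercube,
    k: int = NEIGHBORHOOD,
    label: str = "",
    cube_id: str = "",
) -> SpectralCurveSet:
    """Average each non-overlapping k x k tile into one spectral curve.

    Returns (H/k)*(W/k) curves ordered row-major by tile coordinate.
    """
    n_bands, n_rows, n_cols = cube.shape
    if n_rows % k or n_cols % k:
        raise DimensionError(f"cube extent {n_rows}x{n_cols} not divisible by {k}")
    tiles_r, tiles_c = n_rows // k, n_cols // k
    means = cube.data.reshape(n_bands, tiles_r, k, tiles_c, k).mean(axis=(2, 4))
    curves = means.reshape(n_bands, tiles_r * tiles_c).T
    tr, tc = np.meshgrid(np.arange(tiles_r), np.arange(tiles_c), indexing="ij")
    provenance = pd.DataFrame(
        {
            "cube_id": np.full(tiles_r * tiles_c, cube_id or cube.kind, dtype=object),
            "tile_row": tr.ravel(),
            "tile_col": tc.ravel(),
        }
    )
    labels = np.full(tiles_r * tiles_c, label, dtype=object)
    return SpectralCurveSet(curves=curves, grid=cube.grid, labels=labels, provenance=provenance)


def compute_transmittance(
    sample_curves: SpectralCurveSet, white_curves: SpectralCurveSet
) -> SpectralCurveSet:
    """Per-curve, per-band ratio of sample to white-reference power.

    Both sets must come from the same ROI/averaging path (same grid, same
    tile coordinates).  A non-positive white value is a hard error naming
    the offending tile and band.  Values above 1 are flagged, not clipped.
    """
    if sample_curves.grid != white_curves.grid:
        raise ConfigurationError("sample and white curve sets are on different grids")
    if sample_curves.n_curves != white_curves.n_curves:
        raise ConfigurationError("sample and white curve counts differ")
    for col in ("tile_row", "tile_col"):
        if not np.array_equal(
            sample_curves.provenance[col].to_numpy(), white_curves.provenance[col].to_numpy()
        ):
            raise ConfigurationError("sample and white tiles are not aligned")
    w = white_curves.curves
    bad = np.argwhere(w <= 0)
    if bad.size:
        i, j = bad[0]
        tile = sample_curves.provenance.iloc[int(i)]
        raise DivisionDomainError(
            f"white reference <= 0 at tile ({tile['tile_row']}, {tile['tile_col']}), "
            f"band {sample_curves.grid.values[int(j)]:g} nm"
        )
    tau = sample_curves.curves / w
    return replace(
        sample_curves,
        curves=tau,
        flagged=np.any(tau > 1.0, axis=1),
    )


def subsample_curves(
    curves: SpectralCurveSet, n_per_class: int = 100, seed: int = 0
) -> SpectralCurveSet:
    """Randomly keep exactly ``n_per_class`` curves per class, without replacement.

    The original acquisition yields far more candidate curves than the
    classifier needs; a seeded uniform subsample caps each class.  Curve
    order within the result follows class order of first appearance.
    """
    rng = np.random.default_rng(seed)
    labels = curves.labels
    keep: list[np.ndarray] = []
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        idx = np.flatnonzero(labels == lab)
        if idx.size < n_per_class:
            raise SamplingError(
                f"class '{lab}' has {idx.size} curves, fewer than requested {n_per_class}"
            )
        chosen = rng.choice(idx, size=n_per_class, replace=False)
        keep.append(np.sort(chosen))
    return curves.subset(np.concatenate(keep))
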