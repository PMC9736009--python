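"""Synthetic hyperspectral acquisitions of honey/syrup mixtures.

The study system is transmission microscopy of honey adulterated with
cheap sugar syrups: a sample on a slide is trans-illuminated, a tunable
bandpass filter sweeps the visible range, and a camera records one image
per band, yielding a hypercube.  Dividing a sample acquisition by a
white-reference acquisition (illumination alone) gives per-pixel
transmittance spectra.

Because no public cube archive exists for this system, this module
generates cube pairs with the statistical structure the downstream
analysis assumes:

* smooth endmember transmittance spectra per material (honeys and syrups),
  built from a few broad Gaussian absorbance bumps mapped through
  ``exp(-A)`` so values stay in (0, 1];
* mixing of honey and syrup endmembers at prescribed mass fractions,
  linear in transmittance by default (Beer-Lambert, i.e. linear in
  absorbance, as an option);
* a smooth multiplicative illumination field (the effect of Koehler
  alignment: near-uniform irradiance with a gentle radial falloff) times a
  broad lamp spectrum;
* additive spatial white noise per band, independent across pixels and
  bands, modelling readout electronics.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DomainError,
    LookupMaterialError,
)
from .grid import WavelengthGrid

DEFAULT_TOTAL_MASS_G = 23.0
DEFAULT_FRACTIONS = (100.0, 90.0, 80.0, 70.0, 60.0)
DEFAULT_SEPARATION = 0.15
DEFAULT_SIGMA_READ = 0.002

MIXTURE_CSV_COLUMNS = ["fraction_pct", "honey_g", "syrup_g", "label"]


# ---------------------------------------------------------------------------
# Mixture design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureDesign:
    """Mass-fraction recipe table: one row per purity class.

    Masses are stored exactly; :meth:`display` rounds to 0.1 g the way a
    bench protocol sheet would.
    """

    total_mass: float
    table: pd.DataFrame  # columns: fraction_pct, honey_g, syrup_g, label

    def __post_init__(self):
        t = self.table
        if not np.allclose(t["honey_g"] + t["syrup_g"], self.total_mass):
            raise DomainError("honey_g + syrup_g must equal total_mass in every row")

    @property
    def fractions(self) -> np.ndarray:
        return self.table["fraction_pct"].to_numpy()

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def row(self, label: str) -> pd.Series:
        match = self.table[self.table["label"] == label]
        if match.empty:
            raise LookupMaterialError(label)
        return match.iloc[0]

    def display(self) -> pd.DataFrame:
        """Recipe rounded to 0.1 g for reporting; storage stays exact."""
        out = self.table.copy()
        out["honey_g"] = out["honey_g"].round(1)
        out["syrup_g"] = out["syrup_g"].round(1)
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=MIXTURE_CSV_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "MixtureDesign":
        t = pd.read_csv(path)
        t["label"] = t["label"].astype(str)
        total = float((t["honey_g"] + t["syrup_g"]).iloc[0])
        return cls(total_mass=total, table=t[MIXTURE_CSV_COLUMNS])


def make_mixture_design(
    total_mass: float = DEFAULT_TOTAL_MASS_G,
    honey_fractions: Sequence[float] = DEFAULT_FRACTIONS,
    labels: Sequence[str] | None = None,
) -> MixtureDesign:
    """Build the recipe table for honey/syrup mixtures.

    Parameters
    ----------
    total_mass : float
        Combined mass of honey plus syrup per container, grams.
    honey_fractions : sequence of float
        Honey mass as percent of total, one per purity class.
    labels : sequence of str, optional
        Class label per row; defaults to the integer-formatted fraction.
    """
    if total_mass <= 0:
        raise DomainError(f"total_mass must be positive, got {total_mass}")
    fracs = [float(f) for f in honey_fractions]
    for f in fracs:
        if not 0.0 <= f <= 100.0:
            raise DomainError(f"honey fraction {f} outside [0, 100]")
    if labels is None:
        labels = [f"{f:g}" for f in fracs]
    honey = [f / 100.0 * total_mass for f in fracs]
    table = pd.DataFrame(
        {
            "fraction_pct": fracs,
            "honey_g": honey,
            "syrup_g": [total_mass - h for h in honey],
            "label": list(labels),
        }
    )
    return MixtureDesign(total_mass=float(total_mass), table=table)


# ---------------------------------------------------------------------------
# Endmember spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndmemberLibrary:
    """Named pure-material transmittance spectra on a common grid."""

    grid: WavelengthGrid
    spectra: dict[str, np.ndarray]

    def __post_init__(self):
        for name, curve in self.spectra.items():
            c = np.asarray(curve, float)
            if c.shape != (self.grid.n_bands,):
                raise ConfigurationError(f"endmember '{name}' does not match the grid")
            if not (np.all(c > 0.0) and np.all(c <= 1.0)):
                raise ConfigurationError(f"endmember '{name}' has values outside (0, 1]")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.spectra[name]
        except KeyError:
            raise LookupMaterialError(f"unknown material '{name}'") from None

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    @property
    def materials(self) -> list[str]:
        return list(self.spectra)

    def max_second_difference(self, name: str) -> float:
        """Largest |second finite difference| of an endmember, per nm^2."""
        c = self[name]
        h = self.grid.step
        return float(np.max(np.abs(np.diff(c, 2))) / h**2)


def _absorbance_curve(lam: np.ndarray, rng: np.random.Generator, n_bumps: int) -> np.ndarray:
    baseline = rng.uniform(0.1, 0.8)
    a = np.full_like(lam, baseline)
    for _ in range(n_bumps):
        centre = rng.uniform(lam[0], lam[-1])
        width = rng.uniform(40.0, 120.0)
        height = rng.uniform(0.2, 1.2)
        a += height * np.exp(-0.5 * ((lam - centre) / width) ** 2)
    return a


def generate_endmembers(
    material_names: Sequence[str],
    grid: WavelengthGrid | None = None,
    seed: int = 0,
    separation: float = DEFAULT_SEPARATION,
    n_bumps_range: tuple[int, int] = (3, 6),
    max_retries: int = 50,
) -> EndmemberLibrary:
    """Draw one smooth transmittance spectrum per material.

    Each spectrum is exp(-absorbance) with absorbance a baseline plus 3-6
    broad Gaussian bumps (seeded), giving curves in (0, 1] that a short
    sinusoid expansion can fit.  The whole library is redrawn until every
    pair of materials differs by at least ``separation`` somewhere on the
    grid, so downstream classes are distinguishable by construction.

    Deterministic given ``seed``.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    names = list(material_names)
    if len(names) < 2:
        raise ConfigurationError("need at least two materials")
    if len(set(names)) != len(names):
        raise ConfigurationError("material names must be unique")
    lo, hi = n_bumps_range
    rng = np.random.default_rng(seed)
    lam = grid.values
    for _ in range(max_retries):
        spectra = {}
        for name in names:
            n_bumps = int(rng.integers(lo, hi + 1))
            spectra[name] = np.exp(-_absorbance_curve(lam, rng, n_bumps))
        ok = all(
            np.max(np.abs(spectra[a] - spectra[b])) >= separation
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
        if ok:
            return EndmemberLibrary(grid=grid, spectra=spectra)
    raise ConfigurationError(
        f"could not achieve pairwise separation {separation} in {max_retries} draws"
    )


def mixture_spectrum(
    library: EndmemberLibrary,
    honey: str,
    syrup: str,
    honey_fraction: float,
    mode: str = "linear",
) -> np.ndarray:
    """Transmittance of a honey/syrup blend at a given honey mass percent.

    ``linear`` mixes transmittances by mass fraction; ``beer_lambert``
    mixes absorbances (tau_h^w * tau_s^(1-w)).  Either way the mixture lies
    pointwise between the two endmembers.
    """
    if not 0.0 <= honey_fraction <= 100.0:
        raise DomainError(f"honey_fraction {honey_fraction} outside [0, 100]")
    tau_h = library[honey]
    tau_s = library[syrup]
    w = honey_fraction / 100.0
    if mode == "linear":
        return w * tau_h + (1.0 - w) * tau_s
    if mode == "beer_lambert":
        return tau_h**w * tau_s ** (1.0 - w)
    raise ConfigurationError(f"unknown mixing mode '{mode}'")


# ---------------------------------------------------------------------------
# Cube simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Additive white readout noise.

    ``sigma_read`` is the standard deviation of the per-pixel, per-band
    Gaussian noise in the same (arbitrary) intensity units as the cube;
    ``per_band_scale`` optionally modulates it across bands.  Draws are
    independent across pixels and bands.
    """

    sigma_read: float = DEFAULT_SIGMA_READ
    per_band_scale: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma_read < 0:
            raise ConfigurationError("sigma_read must be >= 0")
        if self.per_band_scale is not None:
            s = np.asarray(self.per_band_scale, float)
            if np.any(s < 0):
                raise ConfigurationError("per-band noise scale must be >= 0")
            object.__setattr__(self, "per_band_scale", s)

    def sigmas(self, n_bands: int) -> np.ndarray:
        if self.per_band_scale is None:
            return np.full(n_bands, self.sigma_read)
        if self.per_band_scale.size != n_bands:
            raise ConfigurationError("per_band_scale length does not match the grid")
        return self.sigma_read * self.per_band_scale


@dataclass(frozen=True)
class IlluminationParams:
    """Smooth multiplicative illumination: lamp spectrum x spatial field.

    ``falloff`` is the fractional intensity drop from the field centre to
    the corner (a well-aligned Koehler setup keeps this small);
    ``lamp_floor``/``lamp_peak_nm``/``lamp_width_nm`` shape a broad,
    strictly positive lamp spectrum of order one.
    """

    falloff: float = 0.15
    lamp_floor: float = 0.5
    lamp_peak_nm: float = 600.0
    lamp_width_nm: float = 260.0

    def __post_init__(self):
        if not 0.0 <= self.falloff < 1.0:
            raise ConfigurationError("falloff must be in [0, 1)")
        if self.lamp_floor <= 0 or self.lamp_width_nm <= 0:
            raise ConfigurationError("lamp spectrum must be strictly positive")

    def lamp_spectrum(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.values
        return self.lamp_floor + (1.0 - self.lamp_floor) * np.exp(
            -(((lam - self.lamp_peak_nm) / self.lamp_width_nm) ** 2)
        )

    def spatial_field(self, n_rows: int, n_cols: int) -> np.ndarray:
        r = np.arange(n_rows) - (n_rows - 1) / 2.0
        c = np.arange(n_cols) - (n_cols - 1) / 2.0
        rr, cc = np.meshgrid(r, c, indexing="ij")
        d2 = rr**2 + cc**2
        d2max = d2.max() if d2.max() > 0 else 1.0
        return 1.0 - self.falloff * d2 / d2max


FLAT_ILLUMINATION = IlluminationParams(falloff=0.0, lamp_floor=1.0, lamp_width_nm=1.0)
# lamp_floor=1 makes the Gaussian term vanish: lamp == 1 at every band.


@dataclass(frozen=True)
class Hypercube:
    """Banded 3-D intensity array: (n_bands, n_rows, n_cols)."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: str  # "sample" or "white_reference"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, float)
        if d.ndim != 3:
            raise ConfigurationError("cube data must be 3-D (bands, rows, cols)")
        if d.shape[0] != self.grid.n_bands:
            raise ConfigurationError("first cube axis must match the wavelength grid")
        if self.kind not in ("sample", "white_reference"):
            raise ConfigurationError(f"unknown cube kind '{self.kind}'")
        if not np.all(np.isfinite(d)):
            raise ConfigurationError("cube intensities must be finite")
        if np.any(d < 0):
            raise ConfigurationError("cube intensities must be >= 0")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("wavelengths_nm", data=self.grid.values)
            f.create_dataset("kind", data=self.kind)
            for key, value in self.metadata.items():
                f.attrs[key] = value

    @classmethod
    def from_hdf5(cls, path) -> "Hypercube":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            grid = WavelengthGrid(f["wavelengths_nm"][()])
            kind = f["kind"][()]
            if isinstance(kind, bytes):
                kind = kind.decode()
            metadata = {k: _json_safe(v) for k, v in f.attrs.items()}
        return cls(data=data, grid=grid, kind=str(kind), metadata=metadata)


def _json_safe(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def simulate_cube_pair(
    mixture_curve: np.ndarray,
    grid: WavelengthGrid,
    dims: tuple[int, int] = (64, 64),
    illumination: IlluminationParams | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    metadata: dict | None = None,
) -> tuple[Hypercube, Hypercube]:
    """Simulate a (sample, white-reference) acquisition pair.

    The noiseless white cube is ``lamp(lambda) * field(row, col)``; the
    noiseless sample cube is that times the mixture transmittance.
    Independent readout noise is then added to each, so dividing the
    noiseless cubes recovers the mixture curve to machine precision and
    the noisy ratio realises the additive-noise observation model
    rho = tau + eta per band.

    Negative post-noise intensities (vanishingly rare at default noise)
    are clipped to zero to keep the cube physical.
    """
    tau = np.asarray(mixture_curve, float)
    if tau.shape != (grid.n_bands,):
        raise ConfigurationError("mixture curve does not match the grid")
    n_rows, n_cols = dims
    if n_rows < 4 or n_cols < 4:
        raise ConfigurationError("cube dims must be at least 4x4")
    illumination = illumination or IlluminationParams()
    noise = noise or NoiseModel()

    lamp = illumination.lamp_spectrum(grid)
    fld = illumination.spatial_field(n_rows, n_cols)
    if np.any(lamp <= 0) or np.any(fld <= 0):
        raise ConfigurationError("illumination must be strictly positive")

    white_clean = lamp[:, None, None] * fld[None, :, :]
    sample_clean = white_clean * tau[:, None, None]

    rng = np.random.default_rng(seed)
    sig = noise.sigmas(grid.n_bands)[:, None, None]
    shape = (grid.n_bands, n_rows, n_cols)
    white = np.clip(white_clean + sig * rng.standard_normal(shape), 0.0, None)
    sample = np.clip(sample_clean + sig * rng.standard_normal(shape), 0.0, None)

    meta = dict(metadata or {})
    meta["seed"] = int(seed)
    return (
        Hypercube(data=sample, grid=grid, kind="sample", metadata={**meta, "role": "sample"}),
        Hypercube(data=white, grid=grid, kind="white_reference", metadata={**meta, "role": "white"}),
    )
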