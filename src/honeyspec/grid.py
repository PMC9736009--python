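"""Wavelength grid shared by every spectral container.

The acquisition sweeps a tunable bandpass filter over the visible range,
producing one image per centre wavelength.  The default grid is 311 bands
equally spaced from 420 to 730 nm (1 nm step).  All band arithmetic in the
package is done in nanometres, never in band indices, so fitted
coefficients are portable across grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

DEFAULT_START_NM = 420.0
DEFAULT_STOP_NM = 730.0
DEFAULT_N_BANDS = 311


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ConfigurationError("wavelength grid must be a 1-D array of >= 2 values")
        if not np.all(np.diff(v) > 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)
        v.setflags(write=False)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.linspace(DEFAULT_START_NM, DEFAULT_STOP_NM, DEFAULT_N_BANDS))

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> float:
        """Full wavelength extent in nm."""
        return float(self.values[-1] - self.values[0])

    @property
    def step(self) -> float:
        """Mean sample spacing in nm (exact for uniform grids)."""
        return self.span / (self.n_bands - 1)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(self.values, other.values)

    def __hash__(self):
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))

    def __len__(self) -> int:
        return self.n_bands
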