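"""Depth-indexed data series.

A :class:`DepthProfile` is the lingua franca of the pipeline: cell counts,
summed hydrolysis potentials, porewater solute concentrations and modeled
oxidation rates are all (depth, value, error) series in consistent units.
Depths are centimetres below the sediment-water interface (cmbsf) and must
be strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["DepthProfile"]


@dataclass
class DepthProfile:
    """An ordered series of values along sediment depth.

    Parameters
    ----------
    depths:
        Sample depths in cm below seafloor, strictly increasing.
    values:
        Quantity at each depth; units documented by the producer.
    errors:
        Optional 1-sigma standard errors, same units as ``values``.
    label:
        Free-text description (quantity and units).
    """

    depths: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise DomainError("depths and values must be 1-D and congruent")
        if self.depths.size >= 2 and not np.all(np.diff(self.depths) > 0):
            raise DomainError("depths must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.values.shape:
                raise DomainError("errors must match values in shape")
            if np.any(self.errors[np.isfinite(self.errors)] < 0):
                raise DomainError("errors must be nonnegative")

    def __len__(self) -> int:
        return self.depths.size

    @property
    def relative_errors(self) -> np.ndarray:
        """Elementwise error / |value| (nan where value is zero or error absent)."""
        if self.errors is None:
            return np.full_like(self.values, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.values != 0, self.errors / np.abs(self.values), np.nan)

    def interp(self, new_depths) -> np.ndarray:
        """Linear interpolation onto ``new_depths``; extrapolation refused."""
        new_depths = np.atleast_1d(np.asarray(new_depths, dtype=float))
        if new_depths.min() < self.depths[0] - 1e-9 or new_depths.max() > self.depths[-1] + 1e-9:
            raise DomainError(
                f"requested depths [{new_depths.min()}, {new_depths.max()}] outside "
                f"profile range [{self.depths[0]}, {self.depths[-1]}]; no extrapolation"
            )
        return np.interp(new_depths, self.depths, self.values)

    def interp_errors(self, new_depths) -> np.ndarray:
        """Linearly interpolated errors (zeros if the profile carries none)."""
        new_depths = np.atleast_1d(np.asarray(new_depths, dtype=float))
        if self.errors is None:
            return np.zeros_like(new_depths)
        return np.interp(new_depths, self.depths, self.errors)

    def at(self, depth: float) -> float:
        """Value at a single depth by linear interpolation."""
        return float(self.interp([depth])[0])
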