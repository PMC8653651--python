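"""Core containers shared across the package.

Conventions
-----------
* Wavenumber axes are stored in descending order (4000 -> 400 cm^-1),
  matching mid-IR spectrometer output; every algorithm consumes this
  canonical order.
* The regression response y is the adulterant weight fraction in % w/w
  on a 0-100 scale, so all RMSE-type metrics are in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

BandShape = Literal["gaussian", "lorentzian"]
SubsetLabel = Literal["calibration", "test", "unassigned"]


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly monotone wavenumber grid in cm^-1, stored descending."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least two wavenumber points")
        diffs = np.diff(values)
        if np.all(diffs > 0):  # ascending input: normalize
            values = values[::-1]
        elif not np.all(diffs < 0):
            raise ValueError("wavenumber axis must be strictly monotone")
        object.__setattr__(self, "values", values)

    @classmethod
    def default(cls, n_points: int = 7467, low: float = 400.0, high: float = 4000.0) -> "WavenumberAxis":
        """Uniform grid spanning the mid-IR range, descending."""
        if n_points < 2:
            raise ValueError("n_points must be >= 2")
        return cls(np.linspace(high, low, n_points))

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Mean absolute grid spacing in cm^-1."""
        return float(abs(self.values[0] - self.values[-1]) / (self.n_points - 1))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean())))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class Band:
    center: float  # cm^-1
    amplitude: float  # absorbance units
    width: float  # cm^-1 (gaussian sigma / lorentzian HWHM)
    shape: BandShape = "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} cm^-1 has negative amplitude")
        if self.width <= 0:
            raise ValueError(f"band at {self.center} cm^-1 has non-positive width")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class ComponentProfile:
    """Idealized absorbance profile of one powder component as a band list."""

    name: str
    bands: tuple[Band, ...] = ()
    broad_background: Band | None = None

    def all_bands(self) -> tuple[Band, ...]:
        if self.broad_background is None:
            return self.bands
        return self.bands + (self.broad_background,)


@dataclass(frozen=True)
class MixtureDesign:
    """Two-component mixing design: adulterant fractions in % w/w."""

    levels: tuple[float, ...]
    reps_per_level: int
    n_pure_target: int
    n_pure_adulterant: int

    def __post_init__(self) -> None:
        for lv in self.levels:
            if not 0.0 < lv < 100.0:
                raise ValueError(f"mixture level {lv} must lie strictly inside (0, 100) % w/w")
        if self.reps_per_level < 1 or self.n_pure_target < 0 or self.n_pure_adulterant < 0:
            raise ValueError("invalid design counts")

    @property
    def n_adulterated(self) -> int:
        return len(self.levels) * self.reps_per_level

    @property
    def n_total(self) -> int:
        return self.n_adulterated + self.n_pure_target + self.n_pure_adulterant

    def labels(self) -> np.ndarray:
        """Per-sample adulterant fraction, pure target first, then levels, then pure adulterant."""
        parts = [np.zeros(self.n_pure_target)]
        for lv in self.levels:
            parts.append(np.full(self.reps_per_level, float(lv)))
        parts.append(np.full(self.n_pure_adulterant, 100.0))
        return np.concatenate(parts)


@dataclass(frozen=True)
class NoiseModel:
    """Instrumental distortions applied on top of the Beer-Lambert mixture.

    additive_sd            white noise, absorbance units
    multiplicative_slope_sd per-sample gain jitter (1 + a), dimensionless
    offset_sd              per-sample constant offset, absorbance units
    baseline_poly_degree   degree of the smooth per-sample baseline drift
    baseline_coeff_sd      sd of each baseline polynomial coefficient, AU
    """

    additive_sd: float = 0.002
    multiplicative_slope_sd: float = 0.02
    offset_sd: float = 0.005
    baseline_poly_degree: int = 2
    baseline_coeff_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_slope_sd", "offset_sd", "baseline_coeff_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_poly_degree < 0:
            raise ValueError("baseline_poly_degree must be >= 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """All distortions off: clean Beer-Lambert mixtures."""
        return cls(0.0, 0.0, 0.0, 0, 0.0, seed)


@dataclass
class SpectraSet:
    """Absorbance matrix (samples x wavenumbers) with per-sample metadata."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    labels: np.ndarray  # adulterant fraction, % w/w
    subset: np.ndarray  # dtype object/str of SubsetLabel
    ids: np.ndarray  # sample id strings

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float)
        self.subset = np.asarray(self.subset, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        n, p = self.absorbance.shape
        if p != self.axis.n_points:
            raise ValueError(f"matrix has {p} columns but axis has {self.axis.n_points} points")
        if not (self.labels.shape == self.subset.shape == self.ids.shape == (n,)):
            raise ValueError("metadata arrays must have one entry per sample")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")
        if np.any((self.labels < 0) | (self.labels > 100)):
            raise ValueError("labels must lie in [0, 100] % w/w")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def take(self, indices: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            axis=self.axis,
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            subset=self.subset[idx].copy(),
            ids=self.ids[idx].copy(),
        )

    def with_subset(self, tag: str) -> "SpectraSet":
        out = SpectraSet(self.axis, self.absorbance.copy(), self.labels.copy(),
                         np.full(self.n_samples, tag, dtype=object), self.ids.copy())
        return out
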