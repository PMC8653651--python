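"""Spectral pretreatments: SNV, MSC, Savitzky-Golay derivatives and their chains.

The screening set is the eight classical pretreatment chains plus raw
pass-through: {none, MSC, SNV} x {none, 1st derivative, 2nd derivative}
minus the redundant raw row, applied scatter-correction-first.  MSC is
stateful (its reference spectrum is fitted on the calibration set only
and reused on test spectra) to avoid test-set leakage; SNV and SG
derivatives are per-spectrum and stateless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import WavenumberAxis

__all__ = [
    "PreprocessingSpec",
    "FittedPreprocessor",
    "snv",
    "fit_msc",
    "apply_msc",
    "sg_derivative",
    "fit_chain",
    "table1_specs",
]

Scatter = Literal["none", "msc", "snv"]
Derivative = Literal["none", "first", "second"]

_DERIV_ORDER = {"none": 0, "first": 1, "second": 2}


@dataclass(frozen=True)
class PreprocessingSpec:
    """One pretreatment chain: scatter correction then SG derivative."""

    scatter: Scatter = "none"
    derivative: Derivative = "none"
    sg_window: int = 15
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.scatter not in ("none", "msc", "snv"):
            raise ValueError(f"unknown scatter correction {self.scatter!r}")
        if self.derivative not in _DERIV_ORDER:
            raise ValueError(f"unknown derivative {self.derivative!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if _DERIV_ORDER[self.derivative] > self.sg_polyorder:
            raise ValueError("derivative order must be <= sg_polyorder")

    @property
    def name(self) -> str:
        scatter = {"none": "", "msc": "MSC", "snv": "SNV"}[self.scatter]
        deriv = {"none": "", "first": "first derivative", "second": "second derivative"}[
            self.derivative
        ]
        if scatter and deriv:
            return f"{scatter}+{deriv}"
        return scatter or deriv or "Original"

    @property
    def edge_width(self) -> int:
        """Points at each end computed by one-sided polynomial fits."""
        return self.sg_window // 2 if self.derivative != "none" else 0


def table1_specs(sg_window: int = 15, sg_polyorder: int = 3) -> tuple[PreprocessingSpec, ...]:
    """The nine screening chains: raw plus the eight pretreatments."""
    out = [PreprocessingSpec("none", "none", sg_window, sg_polyorder)]
    for scatter in ("msc", "snv"):
        out.append(PreprocessingSpec(scatter, "none", sg_window, sg_polyorder))
    for deriv in ("first", "second"):
        out.append(PreprocessingSpec("none", deriv, sg_window, sg_polyorder))
    for scatter in ("msc", "snv"):
        for deriv in ("first", "second"):
            out.append(PreprocessingSpec(scatter, deriv, sg_window, sg_polyorder))
    return tuple(out)


def spec_by_name(name: str, sg_window: int = 15, sg_polyorder: int = 3) -> PreprocessingSpec:
    for spec in table1_specs(sg_window, sg_polyorder):
        if spec.name.lower() == name.strip().lower():
            return spec
    known = [s.name for s in table1_specs()]
    raise ValueError(f"unknown pretreatment {name!r}; known: {known}")


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit spread.

    Uses the sample (n-1) standard deviation.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] < 2:
        raise ValueError("SNV needs spectra with at least 2 points")
    sd = spectra.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant spectrum (zero spread) at row index {bad[0]}")
    return (spectra - spectra.mean(axis=1, keepdims=True)) / sd[:, None]


def _msc_correct(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    x_mean = spectra.mean(axis=1)
    a = (spectra - x_mean[:, None]) @ ref_c / denom
    if np.any(np.abs(a) < 1e-12):
        bad = int(np.flatnonzero(np.abs(a) < 1e-12)[0])
        raise ValueError(f"MSC slope ~ 0 for spectrum at row index {bad}")
    b = x_mean - a * reference.mean()
    return (spectra - b[:, None]) / a[:, None]


def fit_msc(calibration: np.ndarray) -> np.ndarray:
    """Fit the MSC reference: the mean calibration spectrum."""
    calibration = np.atleast_2d(np.asarray(calibration, dtype=float))
    if calibration.shape[0] < 2:
        raise ValueError("MSC reference needs at least 2 calibration spectra")
    return calibration.mean(axis=0)


def apply_msc(reference: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Regress each spectrum on the reference (x ~ a*ref + b) and invert."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    return _msc_correct(spectra, np.asarray(reference, dtype=float))


def sg_derivative(
    spectra: np.ndarray, axis: WavenumberAxis, spec: PreprocessingSpec
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative along the wavenumber axis.

    Output is scaled per cm^-1 for derivatives; the sign convention is a
    derivative with respect to increasing wavenumber even though the
    canonical storage order is descending.  Edge points (half a window at
    each end) come from one-sided polynomial fits (``mode="interp"``).
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spec.sg_window > spectra.shape[1]:
        raise ValueError("sg_window exceeds the number of spectral points")
    if not axis.is_uniform():
        raise ValueError("Savitzky-Golay derivative requires a uniform wavenumber axis")
    order = _DERIV_ORDER[spec.derivative]
    step = float(axis.values[1] - axis.values[0])  # negative for descending storage
    out = savgol_filter(
        spectra,
        window_length=spec.sg_window,
        polyorder=spec.sg_polyorder,
        deriv=order,
        delta=abs(step),
        axis=1,
        mode="interp",
    )
    if order % 2 == 1 and step < 0:
        out = -out
    return out


@dataclass
class FittedPreprocessor:
    """A pretreatment chain fitted on calibration spectra.

    Holds the MSC reference when the chain uses MSC; SNV and derivatives
    carry no fitted state.  ``edge_flags`` marks wavenumber points whose
    derivative came from one-sided fits.
    """

    spec: PreprocessingSpec
    axis: WavenumberAxis
    msc_reference: np.ndarray | None = None

    @property
    def edge_flags(self) -> np.ndarray:
        flags = np.zeros(self.axis.n_points, dtype=bool)
        w = self.spec.edge_width
        if w:
            flags[:w] = True
            flags[-w:] = True
        return flags

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        if self.spec.scatter == "snv":
            spectra = snv(spectra)
        elif self.spec.scatter == "msc":
            if self.msc_reference is None:
                raise ValueError("preprocessor with MSC was never fitted")
            spectra = apply_msc(self.msc_reference, spectra)
        if self.spec.derivative != "none":
            spectra = sg_derivative(spectra, self.axis, self.spec)
        return spectra


def fit_chain(
    spec: PreprocessingSpec, axis: WavenumberAxis, calibration: np.ndarray
) -> FittedPreprocessor:
    """Fit a pretreatment chain on calibration spectra only."""
    ref = fit_msc(calibration) if spec.scatter == "msc" else None
    return FittedPreprocessor(spec=spec, axis=axis, msc_reference=ref)
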