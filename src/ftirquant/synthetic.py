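"""Synthetic ATR-FTIR spectra of two-component powder mixtures.

Generates ground-truth-labeled absorbance spectra that emulate a
laboratory adulteration study: a target botanical powder spiked with an
adulterant powder at known weight fractions, measured on a mid-IR
(400-4000 cm^-1) grid.  Clean spectra follow Beer-Lambert linear mixing
of the two pure-component profiles; instrumental realism (gain jitter,
offsets, smooth baseline drift, white noise) is layered on per sample so
that scatter corrections and derivatives downstream have something to do.

Randomness is driven by one integer seed through per-sample substreams
(``numpy.random.SeedSequence.spawn``), so generating extra samples never
perturbs earlier ones.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    Band,
    ComponentProfile,
    MixtureDesign,
    NoiseModel,
    SpectraSet,
    WavenumberAxis,
)

__all__ = [
    "generate_component",
    "default_design",
    "default_profiles",
    "planted_profiles",
    "simulate_dataset",
]

# Band centers observed in dried botanical powders: O-H envelope, alkyl
# C-H stretches, C-O stretches, CH2 bending, glycosidic C-O-C, C-H bend.
_SHARED_CENTERS = (2917.0, 2850.0, 1732.0, 1604.0, 1417.0, 1371.0, 1318.0, 1027.0, 808.0)


def _band_profile(band: Band, axis: WavenumberAxis) -> np.ndarray:
    x = axis.values
    if not (x.min() <= band.center <= x.max()):
        raise ValueError(
            f"band center {band.center} cm^-1 lies outside the axis range "
            f"[{x.min():g}, {x.max():g}]"
        )
    d = x - band.center
    if band.shape == "gaussian":
        return band.amplitude * np.exp(-0.5 * (d / band.width) ** 2)
    # lorentzian with HWHM = width
    return band.amplitude * band.width**2 / (d**2 + band.width**2)


def generate_component(profile: ComponentProfile, axis: WavenumberAxis) -> np.ndarray:
    """Noise-free absorbance spectrum of one component: sum of its bands."""
    spectrum = np.zeros(axis.n_points)
    for band in profile.all_bands():
        spectrum += _band_profile(band, axis)
    return spectrum


def default_design() -> MixtureDesign:
    """The study mixing design: 19 levels (5..95 % step 5) x 10 reps,
    plus 10 pure target and 10 pure adulterant samples (210 total)."""
    return MixtureDesign(
        levels=tuple(float(v) for v in range(5, 100, 5)),
        reps_per_level=10,
        n_pure_target=10,
        n_pure_adulterant=10,
    )


def default_profiles() -> tuple[ComponentProfile, ComponentProfile]:
    """Target and adulterant component profiles.

    Both share the same band centers so raw spectra look alike by eye;
    they differ in relative amplitudes, and the adulterant carries an
    extra shoulder near 1580 cm^-1.  Amplitudes are configuration values,
    not claims about real plant chemistry.
    """
    oh = Band(3300.0, 0.55, 200.0, "gaussian")
    target_amps = (0.18, 0.12, 0.20, 0.30, 0.10, 0.16, 0.14, 0.60, 0.08)
    adult_amps = (0.24, 0.17, 0.12, 0.42, 0.14, 0.10, 0.20, 0.44, 0.13)
    widths = (12.0, 12.0, 14.0, 22.0, 14.0, 12.0, 12.0, 28.0, 10.0)
    target = ComponentProfile(
        name="target",
        bands=tuple(
            Band(c, a, w) for c, a, w in zip(_SHARED_CENTERS, target_amps, widths)
        ),
        broad_background=oh,
    )
    adulterant = ComponentProfile(
        name="adulterant",
        bands=tuple(
            Band(c, a, w) for c, a, w in zip(_SHARED_CENTERS, adult_amps, widths)
        )
        + (Band(1580.0, 0.12, 10.0, "lorentzian"),),
        broad_background=Band(3300.0, 0.50, 210.0, "gaussian"),
    )
    return target, adulterant


def planted_profiles(
    axis: WavenumberAxis,
    window: tuple[float, float],
    contrast_amplitude: float = 0.3,
) -> tuple[ComponentProfile, ComponentProfile]:
    """Two profiles identical everywhere except inside ``window`` (cm^-1).

    The adulterant carries extra bands strictly inside the window, so all
    between-class variance of noise-free mixtures is confined there.
    Ground truth for testing wavelength-selection methods.
    """
    lo, hi = min(window), max(window)
    span = hi - lo
    if span <= 0:
        raise ValueError("window must have positive width")
    shared = tuple(
        Band(c, a, w)
        for c, a, w in zip(_SHARED_CENTERS, (0.2,) * 9, (15.0,) * 9)
        if not (lo - 4 * 15.0 <= c <= hi + 4 * 15.0)
    )
    # narrow widths so >4 sigma of each planted band stays inside the window
    width = span / 12.0
    planted = (
        Band(lo + 0.35 * span, contrast_amplitude, width),
        Band(lo + 0.70 * span, 0.6 * contrast_amplitude, width),
    )
    target = ComponentProfile(name="planted_target", bands=shared)
    adulterant = ComponentProfile(name="planted_adulterant", bands=shared + planted)
    return target, adulterant


def _sample_distortion(
    clean: np.ndarray, noise: NoiseModel, rng: np.random.Generator, t: np.ndarray
) -> np.ndarray:
    slope = 1.0 + rng.normal(0.0, noise.multiplicative_slope_sd)
    offset = rng.normal(0.0, noise.offset_sd)
    out = clean * slope + offset
    if noise.baseline_poly_degree > 0 and noise.baseline_coeff_sd > 0:
        coeffs = rng.normal(0.0, noise.baseline_coeff_sd, noise.baseline_poly_degree + 1)
        out = out + np.polynomial.polynomial.polyval(t, coeffs)
    if noise.additive_sd > 0:
        out = out + rng.normal(0.0, noise.additive_sd, clean.size)
    return out


def simulate_dataset(
    design: MixtureDesign,
    target: ComponentProfile,
    adulterant: ComponentProfile,
    noise: NoiseModel,
    axis: WavenumberAxis,
) -> SpectraSet:
    """Simulate the full mixture design on ``axis``.

    For adulterant fraction c (% w/w) the clean spectrum is
    ``(c/100) * adulterant + (1 - c/100) * target``; each sample then
    receives its own multiplicative slope, offset, polynomial baseline
    and white noise drawn from ``noise`` under per-sample substreams of
    ``noise.seed``.  Identical seed => bit-identical output.
    """
    target_spec = generate_component(target, axis)
    adult_spec = generate_component(adulterant, axis)
    labels = design.labels()
    n = labels.size
    # map the axis to [-1, 1] for numerically tame baseline polynomials
    t = np.linspace(-1.0, 1.0, axis.n_points)
    children = np.random.SeedSequence(noise.seed).spawn(n)
    rows = np.empty((n, axis.n_points))
    for i, (c, ss) in enumerate(zip(labels, children)):
        f = c / 100.0
        clean = f * adult_spec + (1.0 - f) * target_spec
        rows[i] = _sample_distortion(clean, noise, np.random.default_rng(ss), t)
    ids = np.array([f"S{i + 1:03d}" for i in range(n)], dtype=object)
    return SpectraSet(
        axis=axis,
        absorbance=rows,
        labels=labels,
        subset=np.full(n, "unassigned", dtype=object),
        ids=ids,
    )
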