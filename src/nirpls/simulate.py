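"""Synthetic NIR transmittance spectra of amorphous/crystalline binary
powder mixtures.

The generator is a statistical stand-in for an undeposited spectral
database, not a spectral reconstruction of indomethacin: band *centers*
follow published assignments for the amorphous (A-INDO) and crystalline
(gamma-INDO) forms — the carboxylic-acid O-H/C-O and C-H/C=O combination
bands near 4600 cm^-1, the hydrogen-bond-sensitive crystalline bands
(4528, 4333 cm^-1, the split pairs at 4468/4464 and 4093/4076 cm^-1),
and the backbone overtones near 8532, 8432 and 5940 cm^-1 — while
depths and widths are free parameters chosen once so that pure spectra
of the two forms are visually distinct below 6000 cm^-1 and the
form-discriminating signal lies in 9000-4000 cm^-1 (nothing above
9000 cm^-1 carries composition information).

Physics of the forward model:

* each band is a Gaussian in absorbance; instrument resolution enters
  as a Gaussian line-shape convolution of FWHM = resolution, applied
  analytically (the band SD and the instrument SD add in quadrature,
  with the peak area conserved);
* a mixture with amorphous mass fraction f mixes the *pure absorbance*
  spectra linearly: A(f) = (f/100) A_am + (1 - f/100) A_cr
  (Beer-Lambert additivity), so percent transmittance 100*10^-A is
  deliberately nonlinear in f — the feature that defeats single-peak
  calibration and motivates PLS;
* per-spectrum nuisance effects emulate scatter and packing variation:
  a multiplicative gain on absorbance, an affine baseline drift, and
  additive detector noise in the transmittance domain.

Everything is a pure function of (design, bands, noise model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .spectra import MODE_TRANSMITTANCE, SpectrumSet

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: calibration mixture contents (w/w% amorphous) of the 21-sample design
CALIBRATION_CONTENTS: tuple[float, ...] = (
    0.0000, 4.9955, 10.0150, 15.0415, 20.0200, 25.0050, 30.0080,
    34.9760, 40.0440, 45.0255, 50.0100, 54.9915, 59.9740, 65.0340,
    70.0360, 74.9825, 79.9860, 85.0230, 89.9660, 95.0105, 100.0000,
)

#: independently prepared validation mixtures (nominally 5/15/25/35/45/70%)
VALIDATION_CONTENTS: tuple[float, ...] = (
    5.0000, 15.0005, 25.0000, 34.9995, 45.0020, 70.0030,
)

#: content level used for the precision/repeatability/stability protocols
REPLICATE_LEVEL: float = 45.0020


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band of one solid form.

    ``width`` is the Gaussian SD in cm^-1 *before* instrument
    broadening; ``depth`` is the peak absorbance the band would have at
    zero instrument broadening.
    """

    center: float
    width: float
    depth: float
    component: str  # 'amorphous' | 'crystalline'

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.depth < 0:
            raise ValueError("band depth must be nonnegative")
        if not 4000.0 <= self.center <= 10000.0:
            raise ValueError("band center outside 10,000-4,000 cm^-1")
        if self.component not in ("amorphous", "crystalline"):
            raise ValueError("component must be amorphous or crystalline")


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum nuisance structure (the effects SNV/MSC/WT target).

    additive_sd            detector noise SD, %T units, i.i.d. per point;
    multiplicative_scatter_sd  SD of the per-spectrum absorbance gain
                           g ~ N(1, .) (particle-size/path-length scatter);
    scatter_tilt_sd        SD of the wavelength-dependent part of that
                           gain, g(nu) = g0 + g1*nu_tilde (scatter is
                           smoothly wavelength dependent, so it is only
                           locally multiplicative);
    baseline_offset_sd     SD of a per-spectrum constant absorbance offset;
    baseline_slope_sd      SD of a per-spectrum linear absorbance tilt
                           across the grid span;
    baseline_curvature_sd  SD of a per-spectrum quadratic baseline bow;
    baseline_offset_mean   shared constant background absorbance (keeps
                           %T safely below 100 under additive noise);
    seed                   RNG seed; generation is a pure function of it.

    The smooth wavelength-dependent terms (tilted gain, curved baseline)
    matter structurally: they need several latent components to model
    over the full spectrum but are locally near-affine, which is what
    makes local interval models beat a component-starved full-spectrum
    model, as observed on the real instrument data.
    """

    additive_sd: float = 0.05
    multiplicative_scatter_sd: float = 0.01
    scatter_tilt_sd: float = 0.01
    baseline_offset_sd: float = 0.005
    baseline_slope_sd: float = 0.004
    baseline_curvature_sd: float = 0.004
    baseline_offset_mean: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_scatter_sd",
                     "scatter_tilt_sd", "baseline_offset_sd",
                     "baseline_slope_sd", "baseline_curvature_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        """Fully deterministic spectra (no nuisance terms at all)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, seed)


@dataclass(frozen=True)
class SampleDesign:
    """Mixture contents of the calibration and validation series plus the
    number of averaged spectra recorded per physical sample."""

    calibration_contents: tuple[float, ...] = CALIBRATION_CONTENTS
    validation_contents: tuple[float, ...] = VALIDATION_CONTENTS
    replicates_per_sample: int = 3

    def __post_init__(self) -> None:
        allc = self.calibration_contents + self.validation_contents
        if any(not 0.0 <= c <= 100.0 for c in allc):
            raise ValueError("contents must lie in [0, 100] w/w%")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least one replicate per sample")


def default_grid(step: float = 1.0) -> np.ndarray:
    """Decreasing wavenumber grid 10,000..4,000 cm^-1 at the given step."""
    n = int(round(6000.0 / step)) + 1
    return np.linspace(10000.0, 4000.0, n)


def default_band_library() -> tuple[BandModel, ...]:
    """Band set for the two solid forms.

    Crystalline-only hydrogen-bond bands (e.g. 4528, 4333 cm^-1) scale
    with crystalline fraction and vanish in the pure amorphous spectrum,
    mirroring the loss of the carboxylic-acid dimer on amorphization;
    amorphous bands are broader (disordered environments), crystalline
    ones sharper.
    """
    A, C = "amorphous", "crystalline"
    return (
        # backbone overtones, broadened/shifted between forms
        BandModel(8532.0, 30.0, 0.10, A), BandModel(8540.0, 14.0, 0.12, C),
        BandModel(8432.0, 28.0, 0.08, A), BandModel(8425.0, 13.0, 0.10, C),
        # aromatic C-H combination region
        BandModel(7720.0, 35.0, 0.06, A), BandModel(7735.0, 16.0, 0.07, C),
        BandModel(7180.0, 30.0, 0.10, A), BandModel(7090.0, 15.0, 0.12, C),
        # O-H first overtone: free (amorphous) vs hydrogen-bonded (crystal)
        BandModel(6890.0, 45.0, 0.14, A), BandModel(6750.0, 35.0, 0.06, C),
        BandModel(6120.0, 30.0, 0.15, A), BandModel(6135.0, 14.0, 0.18, C),
        # C-H first overtones incl. the HC=CH band near 5940 cm^-1
        BandModel(5940.0, 25.0, 0.20, A), BandModel(5948.0, 12.0, 0.24, C),
        BandModel(5800.0, 30.0, 0.22, A), BandModel(5810.0, 14.0, 0.25, C),
        # C=O second overtone region
        BandModel(5230.0, 30.0, 0.08, A), BandModel(5180.0, 15.0, 0.10, C),
        # combination bands near 4600 cm^-1
        BandModel(4659.0, 18.0, 0.25, A), BandModel(4656.0, 20.0, 0.30, A),
        BandModel(4611.0, 18.0, 0.22, A),
        BandModel(4662.0, 8.0, 0.28, C), BandModel(4658.0, 8.0, 0.24, C),
        BandModel(4618.0, 8.0, 0.20, C),
        # hydrogen-bond bands of the crystalline dimer
        BandModel(4528.0, 10.0, 0.25, C),
        BandModel(4468.0, 6.0, 0.15, C), BandModel(4464.0, 6.0, 0.14, C),
        BandModel(4333.0, 8.0, 0.18, C),
        BandModel(4188.0, 8.0, 0.16, C),
        BandModel(4093.0, 6.0, 0.14, C), BandModel(4076.0, 6.0, 0.13, C),
        # low-wavenumber amorphous combination bands
        BandModel(4166.0, 15.0, 0.20, A), BandModel(4073.0, 15.0, 0.18, A),
    )


def pure_absorbance(
    bands: Sequence[BandModel], grid: np.ndarray, resolution: float
) -> np.ndarray:
    """Sum of Gaussian bands convolved (analytically) with a Gaussian
    instrument line shape of FWHM = resolution; peak areas conserved."""
    grid = np.asarray(grid, dtype=float)
    sd_inst = resolution / _FWHM_TO_SD
    A = np.zeros_like(grid)
    for b in bands:
        sd_eff = np.hypot(b.width, sd_inst)
        amp = b.depth * b.width / sd_eff
        A += amp * np.exp(-0.5 * ((grid - b.center) / sd_eff) ** 2)
    return A


def generate_pure_spectrum(
    bands: Sequence[BandModel], grid: np.ndarray, resolution: float
) -> np.ndarray:
    """Noise-free %T spectrum of the given bands: 100 * 10^(-A)."""
    return 100.0 * 10.0 ** (-pure_absorbance(bands, grid, resolution))


def _component_absorbances(bands, grid, resolution):
    am = pure_absorbance([b for b in bands if b.component == "amorphous"],
                         grid, resolution)
    cr = pure_absorbance([b for b in bands if b.component == "crystalline"],
                         grid, resolution)
    return am, cr


def _simulate(
    contents: Sequence[float],
    ids: Sequence[str],
    replicates: int,
    bands: Sequence[BandModel],
    noise: NoiseModel,
    grid: np.ndarray,
    resolution: float,
    rng: np.random.Generator,
) -> SpectrumSet:
    am, cr = _component_absorbances(bands, grid, resolution)
    span = grid[0] - grid[-1]
    tilt = (grid - grid.mean()) / span  # in [-0.5, 0.5]
    bow = 4.0 * tilt**2 - 1.0 / 3.0  # mean-zero quadratic basis
    rows, sample_ids, fractions = [], [], []

    def draw(sd: float) -> float:
        return rng.normal(0.0, sd) if sd else 0.0

    for f, sid in zip(contents, ids):
        w = f / 100.0
        base = w * am + (1.0 - w) * cr
        for _ in range(replicates):
            gain = 1.0 + draw(noise.multiplicative_scatter_sd) \
                + draw(noise.scatter_tilt_sd) * tilt
            offset = noise.baseline_offset_mean + draw(noise.baseline_offset_sd)
            A = gain * base + offset + draw(noise.baseline_slope_sd) * tilt \
                + draw(noise.baseline_curvature_sd) * bow
            T = 100.0 * 10.0 ** (-A)
            if noise.additive_sd:
                T = T + rng.normal(0.0, noise.additive_sd, grid.size)
            rows.append(np.clip(T, 1e-6, 100.0))
            sample_ids.append(sid)
            fractions.append(f)
    return SpectrumSet(
        wavenumbers=grid,
        intensities=np.vstack(rows),
        sample_ids=tuple(sample_ids),
        fractions=np.asarray(fractions),
        resolution=resolution,
        mode=MODE_TRANSMITTANCE,
    )


def generate_mixture_set(
    design: SampleDesign | None = None,
    bands: Sequence[BandModel] | None = None,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    resolution: float = 4.0,
    subset: str = "calibration",
) -> SpectrumSet:
    """Simulate the replicate transmittance spectra of one mixture series.

    ``subset`` picks the calibration (21 samples x 3 replicates = 63
    spectra under the default design) or validation contents.
    """
    design = design or SampleDesign()
    bands = default_band_library() if bands is None else bands
    noise = NoiseModel() if noise is None else noise
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if subset == "calibration":
        contents = design.calibration_contents
        prefix = "cal"
    elif subset == "validation":
        contents = design.validation_contents
        prefix = "val"
    else:
        raise ValueError("subset must be 'calibration' or 'validation'")
    ids = [f"{prefix}_{i:02d}" for i in range(len(contents))]
    rng = np.random.default_rng(noise.seed)
    return _simulate(contents, ids, design.replicates_per_sample,
                     bands, noise, grid, resolution, rng)


def make_validation_and_replicate_sets(
    design: SampleDesign | None = None,
    bands: Sequence[BandModel] | None = None,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    resolution: float = 4.0,
) -> tuple[SpectrumSet, dict[str, SpectrumSet]]:
    """The validation series plus the three 45%-level replicate sets.

    The replicate regimes emulate the three method-performance
    protocols as noise regimes of increasing scope:

    * precision      — back-to-back rescans of one undisturbed loading:
                       additive detector noise only;
    * repeatability  — independently re-packed loadings: the full
                       nuisance model (gain + baseline + additive);
    * stability      — scans spread over a session: additive noise plus
                       baseline drift, no repacking gain.
    """
    design = design or SampleDesign()
    bands = default_band_library() if bands is None else bands
    noise = NoiseModel() if noise is None else noise
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    validation = generate_mixture_set(
        design, bands, replace(noise, seed=noise.seed + 1), grid, resolution,
        subset="validation",
    )
    regimes = {
        "precision": replace(noise, multiplicative_scatter_sd=0.0,
                             scatter_tilt_sd=0.0, baseline_offset_sd=0.0,
                             baseline_slope_sd=0.0, baseline_curvature_sd=0.0,
                             seed=noise.seed + 2),
        "repeatability": replace(noise, seed=noise.seed + 3),
        "stability": replace(noise, multiplicative_scatter_sd=0.0,
                             scatter_tilt_sd=0.0, seed=noise.seed + 4),
    }
    replicate_sets = {}
    for name, nm in regimes.items():
        rng = np.random.default_rng(nm.seed)
        replicate_sets[name] = _simulate(
            [REPLICATE_LEVEL], [f"rep_{name}"], design.replicates_per_sample,
            bands, nm, grid, resolution, rng,
        )
    return validation, replicate_sets
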