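"""Spectral pretreatment operators and fitted, replayable chains.

Implements the pretreatments screened by the pipeline: standard normal
variate (SNV), multiplicative scatter correction (MSC), Savitzky-Golay
first/second derivatives (SG1st/SG2nd) and wavelet denoising (WT), plus
the combinations SNV+WT, MSC+WT, SG1st+WT, SG2nd+WT.

Every operator acts row-wise (one spectrum at a time) and is therefore
permutation-equivariant over samples.  MSC is the only stateful step:
its reference spectrum is the mean *calibration* spectrum, learned by
:func:`fit_apply_chain` and replayed unchanged on validation/unknown
sets by :func:`apply_chain`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Union

import numpy as np
import pywt
import yaml
from scipy.signal import savgol_filter

from .spectra import SpectrumSet


class NotFittedError(RuntimeError):
    """A chain containing MSC was applied before being fitted."""


# ---------------------------------------------------------------------------
# elementary operators
# ---------------------------------------------------------------------------

def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to mean 0,
    sample SD 1 (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return (x - x.mean()) / sd


def msc(x: np.ndarray, reference: np.ndarray, *, b_tol: float = 1e-12) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Fits x ~ a + b*reference by least squares and returns (x - a) / b.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("spectrum and reference lengths differ")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference is constant")
    b = (rc @ (x - x.mean())) / denom
    if abs(b) < b_tol:
        raise ValueError("spectrum uncorrelated with MSC reference (|b| ~ 0)")
    a = x.mean() - b * ref.mean()
    return (x - a) / b


def sg_derivative(
    x: np.ndarray, order: int, window: int = 15, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay smoothed derivative w.r.t. grid index, same length.

    Interior points use the standard SG convolution; edge points are fit
    with a shrinking one-sided window (never fewer than polyorder+1
    points) so no points are truncated and interval widths stay intact.
    """
    x = np.asarray(x, dtype=float)
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if window % 2 == 0 or window <= polyorder or polyorder < order:
        raise ValueError("require odd window > polyorder >= order")
    if x.size < window:
        raise ValueError("spectrum shorter than the SG window")
    out = savgol_filter(x, window, polyorder, deriv=order, delta=1.0, mode="interp")
    half = window // 2
    idx = np.arange(x.size, dtype=float)
    for i in range(half):
        hi = max(i + half + 1, polyorder + 1)
        coef = np.polyfit(idx[:hi] - i, x[:hi], polyorder)
        out[i] = np.polyval(np.polyder(coef, order), 0.0)
        j = x.size - 1 - i
        lo = min(j - half, x.size - polyorder - 1)
        coef = np.polyfit(idx[lo:] - j, x[lo:], polyorder)
        out[j] = np.polyval(np.polyder(coef, order), 0.0)
    return out


def wavelet_denoise(
    x: np.ndarray,
    name: str = "db4",
    level: int | None = None,
    rule: str = "soft-universal",
) -> np.ndarray:
    """Multi-level wavelet shrinkage (VisuShrink-style).

    Decomposes with the named wavelet ('smooth' signal extension),
    estimates the noise SD from the median absolute deviation of the
    finest detail coefficients (sigma = MAD/0.6745), thresholds every
    detail level at sigma*sqrt(2 ln n) (soft or hard), and reconstructs
    to the original length.  The approximation coefficients pass through.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("spectrum too short for wavelet denoising")
    wav = pywt.Wavelet(name)
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    if level is None:
        level = min(5, max_level)
    if level < 1 or level > max_level or n < 2**level:
        raise ValueError(f"level {level} too deep for length {n}")
    if rule not in ("soft-universal", "hard-universal"):
        raise ValueError(f"unknown threshold rule: {rule}")
    coeffs = pywt.wavedec(x, wav, mode="smooth", level=level)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    mode = "soft" if rule.startswith("soft") else "hard"
    if thr > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode=mode)
                                for c in coeffs[1:]]
    return pywt.waverec(coeffs, wav, mode="smooth")[:n]


# ---------------------------------------------------------------------------
# chain configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Snv:
    kind: str = "snv"


@dataclass(frozen=True)
class Msc:
    kind: str = "msc"


@dataclass(frozen=True)
class SgDerivative:
    order: int = 1
    window: int = 15
    polyorder: int = 2
    kind: str = "sg_derivative"


@dataclass(frozen=True)
class WaveletDenoise:
    name: str = "db4"
    level: int | None = None
    rule: str = "soft-universal"
    kind: str = "wavelet"


Step = Union[Snv, Msc, SgDerivative, WaveletDenoise]

_STEP_NAMES = {Snv: "SNV", Msc: "MSC", WaveletDenoise: "WT"}


@dataclass(frozen=True)
class PreprocessConfig:
    """An ordered pretreatment chain; an empty chain is 'raw' (identity).

    ``msc_reference`` is None until :func:`fit_apply_chain` has learned
    the mean calibration spectrum (only relevant when MSC is a step).
    """

    steps: tuple[Step, ...] = ()
    msc_reference: np.ndarray | None = None

    @property
    def name(self) -> str:
        if not self.steps:
            return "raw"
        parts = []
        for s in self.steps:
            if isinstance(s, SgDerivative):
                parts.append("SG1st" if s.order == 1 else "SG2nd")
            else:
                parts.append(_STEP_NAMES[type(s)])
        return "+".join(parts)

    @property
    def is_fitted(self) -> bool:
        needs_ref = any(isinstance(s, Msc) for s in self.steps)
        return (not needs_ref) or self.msc_reference is not None


def chain_from_name(name: str) -> PreprocessConfig:
    """Build a chain from a '+'-joined name, e.g. 'SNV+WT' or 'raw'.

    Tokens: raw, SNV, MSC, SG1st, SG2nd, WT (case-insensitive); chain
    order is exactly the token order.
    """
    steps: list[Step] = []
    for tok in name.split("+"):
        t = tok.strip().lower()
        if t in ("raw", ""):
            continue
        elif t == "snv":
            steps.append(Snv())
        elif t == "msc":
            steps.append(Msc())
        elif t == "sg1st":
            steps.append(SgDerivative(order=1))
        elif t == "sg2nd":
            steps.append(SgDerivative(order=2))
        elif t == "wt":
            steps.append(WaveletDenoise())
        else:
            raise ValueError(f"unknown pretreatment token: {tok!r}")
    return PreprocessConfig(steps=tuple(steps))


def default_chain_grid() -> list[str]:
    """The screening grid: raw, SNV, MSC, SG1st, SG2nd, each with and
    without a trailing wavelet-denoise step."""
    base = ["raw", "SNV", "MSC", "SG1st", "SG2nd"]
    return base + [("WT" if b == "raw" else b + "+WT") for b in base]


def _apply_step(step: Step, Z: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    if isinstance(step, Snv):
        return np.apply_along_axis(snv, 1, Z)
    if isinstance(step, Msc):
        if reference is None:
            raise NotFittedError("MSC step applied before the chain was fitted")
        return np.vstack([msc(row, reference) for row in Z])
    if isinstance(step, SgDerivative):
        return np.vstack(
            [sg_derivative(row, step.order, step.window, step.polyorder) for row in Z]
        )
    if isinstance(step, WaveletDenoise):
        return np.vstack(
            [wavelet_denoise(row, step.name, step.level, step.rule) for row in Z]
        )
    raise TypeError(f"unknown step type: {type(step)!r}")


def _out_mode(config: PreprocessConfig, sset: SpectrumSet) -> str:
    # processed intensities are unbounded, so a non-trivial chain cannot
    # keep the (0, 100] transmittance contract; tag them as absorbance-like
    return sset.mode if not config.steps else "absorbance"


def fit_apply_chain(
    config: PreprocessConfig, train: SpectrumSet
) -> tuple[PreprocessConfig, SpectrumSet]:
    """Learn chain statistics on the calibration set and transform it.

    The MSC reference is the mean calibration spectrum at the point in
    the chain where the MSC step runs.  Returns the fitted config and the
    transformed set.
    """
    if train.n_spectra < 1:
        raise ValueError("empty training set")
    Z = train.intensities.copy()
    reference = config.msc_reference
    for step in config.steps:
        if isinstance(step, Msc) and reference is None:
            reference = Z.mean(axis=0)
        Z = _apply_step(step, Z, reference)
    fitted = dataclasses.replace(config, msc_reference=reference)
    return fitted, train.replace(intensities=Z, mode=_out_mode(config, train))


def apply_chain(fitted: PreprocessConfig, sset: SpectrumSet) -> SpectrumSet:
    """Replay a fitted chain on another set (validation, unknowns)."""
    if not fitted.is_fitted:
        raise NotFittedError("chain contains MSC but has no stored reference")
    Z = sset.intensities.copy()
    for step in fitted.steps:
        Z = _apply_step(step, Z, fitted.msc_reference)
    return sset.replace(intensities=Z, mode=_out_mode(fitted, sset))


# ---------------------------------------------------------------------------
# YAML (de)serialization so a fitted pipeline is reproducible
# ---------------------------------------------------------------------------

def config_to_yaml(config: PreprocessConfig) -> str:
    steps = []
    for s in config.steps:
        d = dataclasses.asdict(s)
        steps.append(d)
    ref = None if config.msc_reference is None else config.msc_reference.tolist()
    return yaml.safe_dump({"steps": steps, "msc_reference": ref}, sort_keys=False)


def config_from_yaml(text: str) -> PreprocessConfig:
    data = yaml.safe_load(text)
    kinds = {
        "snv": Snv,
        "msc": Msc,
        "sg_derivative": SgDerivative,
        "wavelet": WaveletDenoise,
    }
    steps = []
    for d in data.get("steps", []):
        d = dict(d)
        cls = kinds[d.pop("kind")]
        steps.append(cls(**d))
    ref = data.get("msc_reference")
    return PreprocessConfig(
        steps=tuple(steps),
        msc_reference=None if ref is None else np.asarray(ref, dtype=float),
    )
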