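"""Quantitative MRI: multi-echo T2 and multi-b-value ADC mapping.

Defaults mirror the acquisition protocols the pipeline targets: a 20-echo
multi-slice multi-echo train with 6.80 ms echo spacing for T2, and
diffusion weighting at b = 0, 400, 1000 s/mm^2 along three orthogonal
directions for the trace ADC.

Fitting is per-voxel log-linear least squares, weighted by the squared
signal to de-bias the log transform (the maximum-likelihood weighting for
Gaussian noise on S), with one reweighting pass using the fitted signal so
the weights do not correlate with the noise; an unweighted nonlinear fit
is available via ``method="nls"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .params import ParamMap

DEFAULT_TES_MS = tuple(6.80 * (i + 1) for i in range(20))
DEFAULT_BVALS = (0.0, 400.0, 1000.0)
T2_RANGE_MS = (1.0, 2000.0)


@dataclass
class EchoStack:
    """Magnitude images per echo time: data shape (n_echoes, *grid)."""

    data: np.ndarray
    tes_ms: Sequence[float] = DEFAULT_TES_MS
    mask: Optional[np.ndarray] = None
    spacing: Tuple[float, ...] = (1.0,)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.tes_ms = np.asarray(self.tes_ms, dtype=float)
        if self.data.shape[0] != len(self.tes_ms):
            raise ValueError("first data axis must index echoes")
        if np.any(np.diff(self.tes_ms) <= 0):
            raise ValueError("echo times must be strictly ascending")
        if len(self.tes_ms) < 3:
            raise ValueError("need at least 3 echoes to fit T2")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)


@dataclass
class DwiStack:
    """Magnitude images per (b-value, direction): shape (n_b, n_dir, *grid)."""

    data: np.ndarray
    bvals: Sequence[float] = DEFAULT_BVALS
    mask: Optional[np.ndarray] = None
    spacing: Tuple[float, ...] = (1.0,)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        if self.data.shape[0] != len(self.bvals):
            raise ValueError("first data axis must index b-values")
        if 0.0 not in self.bvals:
            raise ValueError("a b=0 image is required")
        if len(np.unique(self.bvals)) < 2:
            raise ValueError("need at least 2 distinct b-values")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-values are not allowed")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[2:], dtype=bool)


# --------------------------------------------------------------------------
# synthetic signal generators
# --------------------------------------------------------------------------

def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def simulate_t2_series(t2_map_ms: np.ndarray, s0: float = 1000.0,
                       tes_ms: Sequence[float] = DEFAULT_TES_MS,
                       snr: Optional[float] = None,
                       seed: Optional[int] = None) -> EchoStack:
    """Mono-exponential echo stack S(TE) = S0 exp(-TE/T2), optional Rician
    noise with sigma = S0 / snr."""
    t2 = np.asarray(t2_map_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive everywhere")
    tes = np.asarray(tes_ms, dtype=float)
    if np.any(tes < 0) or np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be non-negative and ascending")
    shape = (len(tes),) + t2.shape
    data = s0 * np.exp(-tes.reshape((-1,) + (1,) * t2.ndim) / t2)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        data = _rician(data, s0 / snr, np.random.default_rng(seed))
    return EchoStack(data.reshape(shape), tes)


def simulate_dwi_series(adc_map: np.ndarray, s0: float = 1000.0,
                        bvals: Sequence[float] = DEFAULT_BVALS,
                        n_dirs: int = 3, anisotropy: float = 0.0,
                        snr: Optional[float] = None,
                        seed: Optional[int] = None) -> DwiStack:
    """Isotropic DWI stack S(b) = S0 exp(-b * ADC) per direction.

    ``anisotropy`` linearly spreads the per-direction ADCs around the trace
    value (0 = identical directions) while preserving their mean.
    """
    adc = np.asarray(adc_map, dtype=float)
    bv = np.asarray(bvals, dtype=float)
    if np.any(bv < 0):
        raise ValueError("negative b-values are not allowed")
    if 0.0 not in bv:
        raise ValueError("a b=0 image is required")
    offs = np.linspace(-anisotropy, anisotropy, n_dirs) if n_dirs > 1 else [0.0]
    data = np.empty((len(bv), n_dirs) + adc.shape)
    for j, off in enumerate(offs):
        adc_d = adc * (1.0 + off)
        for i, b in enumerate(bv):
            data[i, j] = s0 * np.exp(-b * adc_d)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        data = _rician(data, s0 / snr, np.random.default_rng(seed))
    return DwiStack(data, bv)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _weighted_loglinear(x: np.ndarray, signals: np.ndarray,
                        weights: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-voxel weighted LSQ of ln(S) on x; returns (slope, intercept).

    ``signals``/``weights`` have shape (n_points, n_voxels); weights of
    invalid points must already be zero.
    """
    slope = intercept = None
    for _ in range(2):
        slope, intercept = _loglinear_once(x, signals, weights)
        # reweight with the fitted (noise-free) signal so the weights do not
        # correlate with the noise -- one iteration approximates Gaussian NLS
        pred = np.exp(intercept[None, :] + slope[None, :] * x[:, None])
        weights = np.where(weights > 0, pred ** 2, 0.0)
    return slope, intercept


def _loglinear_once(x: np.ndarray, signals: np.ndarray,
                    weights: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(np.where(signals > 0, signals, np.nan))
    y = np.where(weights > 0, y, 0.0)
    wsum = weights.sum(axis=0)
    xb = (weights * x[:, None]).sum(axis=0) / wsum
    yb = (weights * y).sum(axis=0) / wsum
    sxx = (weights * (x[:, None] - xb) ** 2).sum(axis=0)
    sxy = (weights * (x[:, None] - xb) * (y - yb)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = yb - slope * xb
    return slope, intercept


def fit_t2(stack: EchoStack, method: str = "loglinear") -> Tuple[ParamMap, ParamMap]:
    """Fit T2 (ms) and S0 maps from a multi-echo magnitude stack.

    Voxels with fewer than 3 positive echoes, or fitted T2 outside
    (1, 2000) ms, are masked.
    """
    grid = stack.data.shape[1:]
    n_vox = int(np.prod(grid))
    signals = stack.data.reshape(len(stack.tes_ms), n_vox)
    pos = signals > 0
    valid_vox = (pos.sum(axis=0) >= 3) & stack.mask.reshape(n_vox)

    if method == "loglinear":
        weights = np.where(pos, signals ** 2, 0.0)
        slope, intercept = _weighted_loglinear(stack.tes_ms, signals, weights)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = -1.0 / slope
        s0 = np.exp(intercept)
    elif method == "nls":
        t2 = np.full(n_vox, np.nan)
        s0 = np.full(n_vox, np.nan)
        model = lambda te, a, r: a * np.exp(-te * r)
        for v in np.nonzero(valid_vox)[0]:
            s = signals[:, v]
            try:
                popt, _ = curve_fit(model, stack.tes_ms[pos[:, v]], s[pos[:, v]],
                                    p0=(max(s[0], 1e-9), 1.0 / 50.0), maxfev=2000)
                s0[v], t2[v] = popt[0], 1.0 / popt[1]
            except RuntimeError:
                pass
    else:
        raise ValueError("method must be 'loglinear' or 'nls'")

    in_range = (t2 > T2_RANGE_MS[0]) & (t2 < T2_RANGE_MS[1])
    ok = valid_vox & np.isfinite(t2) & in_range
    t2 = np.where(ok, t2, np.nan).reshape(grid)
    s0 = np.where(ok, s0, np.nan).reshape(grid)
    mask = ok.reshape(grid)
    return (ParamMap(t2, "ms", stack.spacing, mask=mask, name="T2"),
            ParamMap(s0, "a.u.", stack.spacing, mask=mask, name="S0"))


def fit_adc(stack: DwiStack, method: str = "loglinear") -> ParamMap:
    """Trace ADC map (mm^2/s): per-direction log-linear fit over b, averaged
    over the orthogonal directions."""
    n_b, n_dir = stack.data.shape[:2]
    grid = stack.data.shape[2:]
    n_vox = int(np.prod(grid))
    adcs = []
    for j in range(n_dir):
        signals = stack.data[:, j].reshape(n_b, n_vox)
        pos = signals > 0
        if method == "loglinear":
            weights = np.where(pos, signals ** 2, 0.0)
            slope, _ = _weighted_loglinear(stack.bvals, signals, weights)
            adcs.append(-slope)
        elif method == "grid":
            # coarse-to-fine grid search over ADC, for oracle use
            cand = np.linspace(1e-5, 5e-3, 400)
            best = np.full(n_vox, np.nan)
            s0 = signals[stack.bvals == 0][0]
            sse_best = np.full(n_vox, np.inf)
            for a in cand:
                pred = s0[None, :] * np.exp(-stack.bvals[:, None] * a)
                sse = ((signals - pred) ** 2).sum(axis=0)
                better = sse < sse_best
                best[better] = a
                sse_best[better] = sse[better]
            adcs.append(best)
        else:
            raise ValueError("method must be 'loglinear' or 'grid'")
    adc = np.mean(adcs, axis=0)
    ok = np.isfinite(adc) & (adc > 0) & stack.mask.reshape(n_vox)
    adc = np.where(ok, adc, np.nan).reshape(grid)
    return ParamMap(adc, "mm^2/s", stack.spacing, mask=ok.reshape(grid),
                    name="ADC")
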