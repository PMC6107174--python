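"""IAAFT surrogates and the t statistic for nonlinearity.

An IAAFT (iterated amplitude-adjusted Fourier transform) surrogate keeps
exactly the original series' value distribution and approximately its
power spectrum, hence its autocorrelation.  The ensemble of surrogates
therefore realizes the best-fitting *linear* model of the series: same
mean, same SD, same autocorrelation, but no phase organization.  Comparing
the original's multifractal spectrum width W to the ensemble of surrogate
widths gives a t statistic (t_MF): significantly positive t means the
original is *wider* than linearly expectable (nonlinear interactions
amplifying heterogeneity); significantly negative t means *narrower*
(nonlinear interactions constricting variability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ingest import DisplacementSeries
from .multifractal import MultifractalSpectrum, ScalingConfig, estimate_spectrum

__all__ = [
    "iaaft",
    "SurrogateEnsemble",
    "surrogate_widths",
    "TStatistic",
    "t_mf",
]

#: Two-sided 5% significance cut used in cohort counting.
T_CRITICAL = 1.96


def _as_array(u) -> np.ndarray:
    return u.u if isinstance(u, DisplacementSeries) else np.asarray(u, dtype=float)


def iaaft(
    u,
    n_iterations: int = 1000,
    seed: int = 0,
    return_mismatch: bool = False,
):
    """One IAAFT surrogate of a series.

    Starting from a random-phase (conjugate-symmetric) realization of the
    original amplitude spectrum, each iteration (a) imposes the original
    amplitude spectrum on the current series while keeping its phases,
    then (b) replaces the values with the original's sorted values by
    rank.  Ending on (b) guarantees the surrogate's sorted values equal
    the original's bit-exactly.  A fixed iteration count is used rather
    than a convergence stop; the per-iteration relative amplitude-spectrum
    mismatch is available for diagnostics via ``return_mismatch``.
    """
    x = _as_array(u)
    if x.size < 16:
        raise ValueError("series too short for surrogate generation (< 16)")
    if n_iterations < 1:
        raise ValueError("n_iterations must be positive")
    if np.ptp(x) == 0:
        warnings.warn("constant series has no phase information; returning a copy",
                      stacklevel=2)
        mism = np.zeros(n_iterations)
        return (x.copy(), mism) if return_mismatch else x.copy()

    amp = np.abs(np.fft.rfft(x))
    amp_norm = np.linalg.norm(amp)
    sorted_x = np.sort(x)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.size)
    phases[0] = 0.0          # keep the mean real
    if x.size % 2 == 0:
        phases[-1] = 0.0     # Nyquist bin must be real
    s = np.fft.irfft(amp * np.exp(1j * phases), n=x.size)

    mismatch = np.empty(n_iterations)
    for it in range(n_iterations):
        spec = np.fft.rfft(s)
        mag = np.abs(spec)
        # impose the original amplitude spectrum, keeping current phases
        with np.errstate(invalid="ignore", divide="ignore"):
            phase_factor = np.where(mag > 0, spec / mag, 1.0)
        s = np.fft.irfft(amp * phase_factor, n=x.size)
        # rank-replace with the original's values
        ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[ranks]
        mismatch[it] = np.linalg.norm(np.abs(np.fft.rfft(s)) - amp) / amp_norm
    return (s, mismatch) if return_mismatch else s


@dataclass(frozen=True)
class SurrogateEnsemble:
    """Surrogate widths (and optionally the series) for one original series."""

    widths: np.ndarray
    n_retained: np.ndarray
    n_surrogates: int
    n_iterations: int
    seed: int
    series: tuple[np.ndarray, ...] | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "surrogate": np.arange(1, self.n_surrogates + 1),
                "W": self.widths,
                "n_retained_q": self.n_retained,
            }
        )


def surrogate_widths(
    u,
    cfg: ScalingConfig | None = None,
    n_surrogates: int = 50,
    n_iterations: int = 1000,
    seed: int = 0,
    keep_series: bool = False,
) -> SurrogateEnsemble:
    """Generate an IAAFT ensemble and analyze each member.

    Surrogate i uses seed ``seed + i`` so the ensemble is reproducible and
    its members independent.  Every surrogate is analyzed with the *same*
    scaling config as the original series.  The ensemble fails if more
    than 20% of surrogates yield an undefined width.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    cfg = cfg or ScalingConfig()
    x = _as_array(u)
    widths = np.empty(n_surrogates)
    n_ret = np.empty(n_surrogates, dtype=int)
    kept: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-surrogate empty-retention warnings
        for i in range(n_surrogates):
            s = iaaft(x, n_iterations=n_iterations, seed=seed + i)
            spec = estimate_spectrum(s, cfg)
            widths[i] = spec.width
            n_ret[i] = spec.n_retained
            if keep_series:
                kept.append(s)
    n_bad = int(np.isnan(widths).sum())
    if n_bad > 0.2 * n_surrogates:
        raise RuntimeError(
            f"{n_bad}/{n_surrogates} surrogates yielded undefined spectrum width"
        )
    return SurrogateEnsemble(
        widths=widths,
        n_retained=n_ret,
        n_surrogates=n_surrogates,
        n_iterations=n_iterations,
        seed=seed,
        series=tuple(kept) if keep_series else None,
    )


@dataclass(frozen=True)
class TStatistic:
    """t statistic comparing an original width to its surrogate ensemble."""

    w_original: float
    surrogate_mean: float
    surrogate_se: float
    t: float
    n_surrogates: int
    se_mode: str

    @property
    def significant(self) -> bool:
        return np.isfinite(self.t) and abs(self.t) > T_CRITICAL


def t_mf(
    w: float,
    ensemble: SurrogateEnsemble | Sequence[float] | np.ndarray,
    se_mode: Literal["se", "sd"] = "se",
) -> TStatistic:
    """t = (W - mean(W_surr)) / SE(W_surr).

    ``se_mode="se"`` (the default) reads the standard error as sd/sqrt(n);
    ``"sd"`` uses the plain ensemble SD (a z-score reading).  Surrogates
    with undefined width are dropped.  Zero ensemble variance leaves t
    undefined (NaN) with a warning.
    """
    widths = (
        ensemble.widths if isinstance(ensemble, SurrogateEnsemble) else np.asarray(ensemble, dtype=float)
    )
    widths = widths[np.isfinite(widths)]
    if widths.size < 2:
        raise ValueError("need at least 2 defined surrogate widths")
    mean = float(widths.mean())
    sd = float(widths.std(ddof=1))
    if se_mode == "se":
        se = sd / np.sqrt(widths.size)
    elif se_mode == "sd":
        se = sd
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    if se <= 1e-12 * max(abs(mean), 1.0):
        warnings.warn("surrogate widths are all identical; t undefined", stacklevel=2)
        t = float("nan")
    else:
        t = (w - mean) / se
    return TStatistic(
        w_original=float(w),
        surrogate_mean=mean,
        surrogate_se=float(se),
        t=float(t),
        n_surrogates=int(widths.size),
        se_mode=se_mode,
    )
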