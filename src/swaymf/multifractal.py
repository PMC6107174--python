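"""Direct (Chhabra–Jensen style) estimation of the multifractal spectrum.

The displacement series u(t) is treated as a measure.  At each time scale L
the series is cut into N_L complete, non-overlapping bins of L samples; the
bin proportions

    P_i(L) = sum of u over bin i / sum of u over all complete bins

are distorted by an exponent q into the normalized mass

    mu_i(q, L) = P_i(L)^q / sum_j P_j(L)^q .

Two q-weighted sums are then regressed on ln L across the scale set:

    sum_i mu_i ln mu_i  ~  f(q) * ln L      (negative Shannon entropy)
    sum_i mu_i ln P_i   ~  alpha(q) * ln L

The slopes give the Hausdorff-like dimension f(q) and the singularity
strength alpha(q).  A value of q enters the spectrum only when *both*
regressions are convincingly linear (|r| above a correlation floor, .995 by
default); the spectrum width is W = max(alpha) - min(alpha) over the
retained q.  Working directly from bin proportions avoids the
finite-variance assumptions that make SD-based multifractal methods
unreliable on quasiperiodic signals.

Large |q| (the default sweep is -200..200) overflows any direct power, so
all masses are formed in the logarithmic domain with max-subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import DisplacementSeries

__all__ = [
    "ScalingConfig",
    "MultifractalSpectrum",
    "bin_proportions",
    "mass",
    "estimate_spectrum",
    "q_retention_profile",
]


def _default_q() -> np.ndarray:
    return np.arange(-200.0, 201.0)


@dataclass(frozen=True)
class ScalingConfig:
    """Scale sweep and retention rule for spectrum estimation.

    ``l_max=None`` resolves to one quarter of the series length, so the
    same config applies to whole series and to blocks.  The default scale
    set is octave-spaced: bin sizes ``l_min * 2**j`` up to ``l_max``, with
    ``l_max`` itself appended when it extends the top octave by at least a
    quarter (so the stated endpoints of the scaling region are honored).
    Octave spacing weights all decades of scale equally in the log-log
    regressions and aligns exactly with dyadic cascade benchmarks.
    Setting ``n_scales`` overrides this with that many log-spaced integer
    bin sizes, deduplicated.
    """

    q_values: np.ndarray = field(default_factory=_default_q)
    l_min: int = 4
    l_max: int | None = None
    n_scales: int | None = None
    r_threshold: float = 0.995

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        if q.size == 0:
            raise ValueError("q_values must be nonempty")
        object.__setattr__(self, "q_values", q)
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.n_scales is not None and self.n_scales < 3:
            raise ValueError("need at least 3 scales for a regression")

    def resolve_l_max(self, n: int) -> int:
        l_max = self.l_max if self.l_max is not None else n // 4
        if l_max > n // 2:
            raise ValueError(
                f"l_max {l_max} exceeds half the series length ({n // 2})"
            )
        if l_max <= self.l_min:
            raise ValueError(f"l_max {l_max} must exceed l_min {self.l_min}")
        return l_max

    def scales(self, n: int) -> np.ndarray:
        """Integer bin sizes for a series of length n (see class docstring)."""
        l_max = self.resolve_l_max(n)
        if self.n_scales is not None:
            raw = np.geomspace(self.l_min, l_max, self.n_scales)
            return np.unique(np.round(raw).astype(int))
        out = [self.l_min]
        while out[-1] * 2 <= l_max:
            out.append(out[-1] * 2)
        if l_max >= 1.25 * out[-1]:
            out.append(l_max)
        return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class MultifractalSpectrum:
    """Estimated spectrum for one series under one scaling config.

    Arrays are aligned with ``q``; ``retained`` marks the q whose two
    scaling regressions both passed the correlation floor.  ``sums_f`` and
    ``sums_alpha`` keep the per-scale q-weighted sums (rows = q, columns =
    scales) for diagnostics and scaling plots; entries are NaN where a
    scale was dropped (zero-proportion bins at q <= 0).
    """

    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r_alpha: np.ndarray
    r_f: np.ndarray
    retained: np.ndarray
    scales: np.ndarray
    sums_f: np.ndarray
    sums_alpha: np.ndarray

    @property
    def retained_q(self) -> np.ndarray:
        return self.q[self.retained]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def width(self) -> float:
        """Spectrum width W = alpha_max - alpha_min over retained q.

        NaN (with a warning at estimation time) when no q was retained.
        """
        if self.n_retained == 0:
            return float("nan")
        a = self.alpha[self.retained]
        return float(a.max() - a.min())

    def to_frame(self) -> pd.DataFrame:
        """Per-q table mirroring the written spectrum output."""
        return pd.DataFrame(
            {
                "q": self.q,
                "alpha": self.alpha,
                "f": self.f,
                "r_alpha": self.r_alpha,
                "r_f": self.r_f,
                "retained": self.retained,
            }
        )


def bin_proportions(u: np.ndarray | DisplacementSeries, L: int) -> np.ndarray:
    """Proportion of the total measure falling in each complete bin of L samples.

    The trailing partial bin, if any, is discarded; proportions are
    normalized over the complete bins so they sum to 1.
    """
    x = u.u if isinstance(u, DisplacementSeries) else np.asarray(u, dtype=float)
    if np.any(x < 0):
        raise ValueError("series must be nonnegative")
    n = x.size
    if L < 1 or L > n // 2:
        raise ValueError(f"bin size {L} invalid for series of length {n}")
    n_bins = n // L
    sums = x[: n_bins * L].reshape(n_bins, L).sum(axis=1)
    total = sums.sum()
    if total <= 0:
        raise ValueError("series has zero total measure")
    return sums / total


def mass(P: np.ndarray, q: float) -> np.ndarray:
    """q-distorted normalized mass mu_i = P_i^q / sum_j P_j^q.

    Computed in the log domain so |q| up to several hundred is exact to
    floating precision.  Zero proportions contribute no mass for q > 0;
    for q <= 0 they make the mass undefined and raise.
    """
    P = np.asarray(P, dtype=float)
    mu = np.zeros_like(P)
    pos = P > 0
    if not np.all(pos) and q <= 0:
        raise ValueError("zero proportions are incompatible with q <= 0")
    logp = np.log(P[pos])
    a = q * logp
    a -= a.max()
    w = np.exp(a)
    mu[pos] = w / w.sum()
    return mu


def _log_mass(q: np.ndarray, logp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log mu and mu for all q at once; rows = q, cols = (positive) bins."""
    a = np.outer(q, logp)
    a -= a.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        log_z = np.log(np.exp(a).sum(axis=1, keepdims=True))
    log_mu = a - log_z
    return log_mu, np.exp(log_mu)


def _rowwise_linreg(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and Pearson r of each row of y against x, ignoring NaNs.

    Rows with fewer than 3 valid points, or with degenerate variance, get
    slope NaN and r 0 (never retained).
    """
    valid = np.isfinite(y)
    n = valid.sum(axis=1)
    xw = np.where(valid, x, np.nan)
    xm = np.nanmean(xw, axis=1, keepdims=True)
    ym = np.nanmean(np.where(valid, y, np.nan), axis=1, keepdims=True)
    dx = np.where(valid, x - xm, 0.0)
    dy = np.where(valid, y - ym, 0.0)
    sxx = (dx * dx).sum(axis=1)
    syy = (dy * dy).sum(axis=1)
    sxy = (dx * dy).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r = sxy / np.sqrt(sxx * syy)
    bad = (n < 3) | ~np.isfinite(r)
    slope[bad] = np.nan
    r[bad] = 0.0
    return slope, r


def spectrum_sums(
    u: np.ndarray, scales: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale q-weighted sums entering the two scaling regressions.

    Returns ``(sums_f, sums_alpha)``, each of shape (n_q, n_scales):
    sum_i mu_i ln mu_i and sum_i mu_i ln P_i.  Scales containing
    zero-proportion bins are NaN for q <= 0 (dropping them is visible in
    the retention filter; flooring would invent mass).
    """
    n_q = q.size
    sums_f = np.empty((n_q, scales.size))
    sums_alpha = np.empty((n_q, scales.size))
    nonpos_q = q <= 0
    for j, L in enumerate(scales):
        P = bin_proportions(u, int(L))
        pos = P > 0
        logp = np.log(P[pos])
        log_mu, mu = _log_mass(q, logp)
        sums_f[:, j] = (mu * log_mu).sum(axis=1)
        sums_alpha[:, j] = (mu * logp).sum(axis=1)
        if not np.all(pos):
            sums_f[nonpos_q, j] = np.nan
            sums_alpha[nonpos_q, j] = np.nan
    return sums_f, sums_alpha


def estimate_spectrum(
    u: np.ndarray | DisplacementSeries, cfg: ScalingConfig | None = None
) -> MultifractalSpectrum:
    """Estimate the multifractal spectrum of a nonnegative series.

    For each q the slopes of the two q-weighted sums against ln L give
    f(q) and alpha(q); q is retained only when both regressions have
    |r| > ``cfg.r_threshold``.  An empty retained set leaves the width
    undefined (NaN) and emits a warning.
    """
    cfg = cfg or ScalingConfig()
    x = u.u if isinstance(u, DisplacementSeries) else np.asarray(u, dtype=float)
    if x.size < 4 * cfg.l_min:
        raise ValueError(
            f"series of length {x.size} too short for l_min {cfg.l_min}"
        )
    if np.all(x == 0):
        raise ValueError("degenerate all-zero series")
    scales = cfg.scales(x.size)
    if scales.size < 3:
        raise ValueError(f"scale set {scales} has fewer than 3 scales")
    q = cfg.q_values
    sums_f, sums_alpha = spectrum_sums(x, scales, q)
    log_l = np.log(scales.astype(float))
    f_slope, r_f = _rowwise_linreg(log_l, sums_f)
    a_slope, r_alpha = _rowwise_linreg(log_l, sums_alpha)
    retained = (np.abs(r_f) > cfg.r_threshold) & (np.abs(r_alpha) > cfg.r_threshold)
    retained &= np.isfinite(f_slope) & np.isfinite(a_slope)
    if not retained.any():
        warnings.warn(
            "no q passed the regression-fidelity filter; spectrum width is "
            "undefined",
            stacklevel=2,
        )
    return MultifractalSpectrum(
        q=q,
        alpha=a_slope,
        f=f_slope,
        r_alpha=r_alpha,
        r_f=r_f,
        retained=retained,
        scales=scales,
        sums_f=sums_f,
        sums_alpha=sums_alpha,
    )


def q_retention_profile(
    spectra: Sequence[MultifractalSpectrum],
) -> tuple[pd.DataFrame, float]:
    """Retained-q count versus width across a set of spectra.

    Wider (more multifractal) series destabilize the power-law form for
    more q, so the retained-q count should fall as W grows.  Returns the
    per-series table and the Spearman rank correlation of (n_retained, W);
    the correlation is NaN (flagged by a warning) for fewer than 2 series.
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    table = pd.DataFrame(
        {
            "n_retained": [s.n_retained for s in spectra],
            "W": [s.width for s in spectra],
        }
    )
    if len(spectra) < 2:
        warnings.warn("rank correlation undefined for a single series", stacklevel=2)
        return table, float("nan")
    rho = stats.spearmanr(table["n_retained"], table["W"]).statistic
    return table, float(rho)
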