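"""Diagnostic plots: scaling relationships and the spectrum curve."""

from __future__ import annotations

import numpy as np

from .multifractal import MultifractalSpectrum

__all__ = ["plot_scaling", "plot_spectrum", "plot_retention_profile"]


def plot_scaling(spectrum: MultifractalSpectrum, q_show=None, ax=None):
    """Negative Shannon entropy of the q-mass against log time scale.

    One line per shown q (default: up to 7 retained q spread over the
    retained range); the straightness of these lines is what the
    retention filter certifies.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if q_show is None:
        ret = np.flatnonzero(spectrum.retained)
        if ret.size == 0:
            ret = np.arange(spectrum.q.size)
        q_show = spectrum.q[ret[np.linspace(0, ret.size - 1, min(7, ret.size)).astype(int)]]
    log_l = np.log(spectrum.scales.astype(float))
    for qv in np.atleast_1d(q_show):
        i = int(np.argmin(np.abs(spectrum.q - qv)))
        ax.plot(log_l, spectrum.sums_f[i], "o-", label=f"q={spectrum.q[i]:g}")
    ax.set_xlabel("ln L")
    ax.set_ylabel(r"$\sum_i \mu_i \ln \mu_i$  (negative Shannon entropy)")
    ax.legend(fontsize="small")
    return ax


def plot_spectrum(spectrum: MultifractalSpectrum, ax=None):
    """The downward-opening singularity spectrum (alpha(q), f(q))."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r = spectrum.retained
    ax.plot(spectrum.alpha[r], spectrum.f[r], "k.-")
    ax.set_xlabel(r"$\alpha(q)$")
    ax.set_ylabel(r"$f(\alpha(q))$")
    ax.set_title(f"W = {spectrum.width:.4f}, {spectrum.n_retained} retained q")
    return ax


def plot_retention_profile(table, ax=None):
    """Retained-q count against spectrum width across series."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["W"], table["n_retained"], "ko")
    ax.set_xlabel("spectrum width W")
    ax.set_ylabel("number of retained q")
    return ax
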