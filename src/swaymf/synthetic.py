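"""Synthetic signals and study-shaped cohorts with known ground truth.

Three generators cover the needs of the analysis chain:

* :func:`binomial_cascade` — a random-branch multiplicative binomial
  cascade, the canonical multifractal measure with a closed-form
  singularity spectrum; it is the oracle against which the spectrum
  estimator is validated.
* :func:`linear_null_series` — Gaussian series with a prescribed
  power-spectrum envelope (flat, power-law or peaked/quasiperiodic); by
  construction they satisfy the linear null hypothesis that the IAAFT
  surrogate test should not reject.
* :func:`synth_cohort` — a full cohort shaped like the insect
  postural-sway study: 21 subjects by default, each contributing one
  wind and one no-wind displacement series of 6012 nonnegative samples
  at 50 samples/s (four 1000-sample analysis blocks of 20 s each), a
  quasiperiodic sway carrier superposed on cascade-generated amplitude
  heterogeneity, and a condition-dependent sign of nonlinearity.

The two nonlinearity regimes are injected by mechanisms that are
demonstrably non-linear in the surrogate-test sense:

* ``widening`` — the carrier's amplitude is multiplied by a binomial
  cascade.  The multiplicative (phase-coherent) clustering of large
  values is destroyed by phase randomization, so the original series is
  *wider* than its linear surrogates (t_MF > 0).
* ``narrowing`` — the carrier's fluctuations are divided by their own
  running amplitude (a dynamic gain-control feedback).  The original's
  envelope is flatter than any phase-randomized rearrangement of the
  same values can be, so the original is *narrower* than its surrogates
  (t_MF < 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .ingest import DisplacementSeries, write_displacement, write_manifest

__all__ = [
    "CascadeSpec",
    "binomial_cascade",
    "cascade_alpha",
    "cascade_width",
    "linear_null_series",
    "CohortSpec",
    "CohortDataset",
    "synth_cohort",
    "write_cohort",
]

Direction = Literal["narrowing", "widening", "none"]


@dataclass(frozen=True)
class CascadeSpec:
    """Multiplicative binomial cascade: k levels of splitting unit mass
    into fractions p and 1-p, the side receiving p chosen by a fair coin
    per node."""

    p: float
    k: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 0.5):
            raise ValueError(f"cascade weight p must lie in (0, 0.5]; got {self.p}")
        if self.k < 1:
            raise ValueError(f"cascade level count k must be >= 1; got {self.k}")


def binomial_cascade(spec: CascadeSpec) -> np.ndarray:
    """Generate the cascade measure: 2^k positive values summing to 1."""
    rng = np.random.default_rng(spec.seed)
    w = np.ones(1)
    for _ in range(spec.k):
        flip = rng.random(w.size) < 0.5
        left = np.where(flip, spec.p, 1.0 - spec.p)
        out = np.empty(2 * w.size)
        out[0::2] = w * left
        out[1::2] = w * (1.0 - left)
        w = out
    return w


def cascade_alpha(p: float, q: np.ndarray | float) -> np.ndarray | float:
    """Closed-form singularity strength alpha(q) of the binomial cascade
    (base-2 logarithms, unit support)."""
    q = np.asarray(q, dtype=float)
    lp, lq = math.log(p), math.log(1.0 - p)
    # work with normalized weights to avoid overflow at large |q|
    m = np.maximum(q * lp, q * lq)
    wp = np.exp(q * lp - m)
    wq = np.exp(q * lq - m)
    alpha = -(wp * lp + wq * lq) / ((wp + wq) * math.log(2.0))
    return alpha if alpha.ndim else float(alpha)


def cascade_width(p: float) -> float:
    """Theoretical spectrum width alpha_max - alpha_min = log2((1-p)/p)."""
    return math.log2((1.0 - p) / p)


def linear_null_series(
    length: int,
    spectrum_shape: Literal["flat", "powerlaw", "peaked"] = "flat",
    seed: int = 0,
    *,
    exponent: float = 1.0,
    peak_freq: float = 1.0,
    peak_width: float = 0.2,
    sample_rate: float = 50.0,
) -> np.ndarray:
    """Gaussian series with a prescribed power-spectrum envelope.

    Synthesized by inverse transform of uniformly random phases under the
    chosen amplitude envelope; standardized to zero mean, unit variance.
    ``exponent`` is the power-law slope beta in S(f) ~ f^-beta;
    ``peak_freq``/``peak_width`` (Hz) place the quasiperiodic bump.
    """
    if length < 64:
        raise ValueError("length must be >= 64")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(length, d=1.0 / sample_rate)
    if spectrum_shape == "flat":
        env = np.ones_like(freqs)
    elif spectrum_shape == "powerlaw":
        env = np.zeros_like(freqs)
        env[1:] = freqs[1:] ** (-exponent / 2.0)
    elif spectrum_shape == "peaked":
        env = 0.05 + np.exp(-0.5 * ((freqs - peak_freq) / peak_width) ** 2)
    else:
        raise ValueError(f"unknown spectrum_shape {spectrum_shape!r}")
    env = env.copy()
    env[0] = 0.0  # zero mean
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    phases[0] = 0.0
    if length % 2 == 0:
        phases[-1] = 0.0
    x = np.fft.irfft(env * np.exp(1j * phases), n=length)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic postural-sway cohort.

    Defaults mirror the study layout: 21 subjects, two conditions each
    (1 = wind, 0 = no-wind), 6012 samples at 50 Hz, a ~1 Hz sway carrier,
    and opposite-signed nonlinearity per condition (wind narrows the
    spectrum relative to the linear null; no-wind widens it).
    """

    n_subjects: int = 21
    series_length: int = 6012
    sample_rate: float = 50.0
    oscillation_period: float = 1.0   # s
    oscillation_amplitude: float = 0.5
    baseline: float = 1.0
    cascade_p_wind: float = 0.35
    cascade_p_no_wind: float = 0.35
    direction_wind: Direction = "narrowing"
    direction_no_wind: Direction = "widening"
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.series_length < 4000:
            raise ValueError(
                f"series_length {self.series_length} cannot form 4 blocks of 1000"
            )
        for d in (self.direction_wind, self.direction_no_wind):
            if d not in ("narrowing", "widening", "none"):
                raise ValueError(f"unknown nonlinearity direction {d!r}")
        for p in (self.cascade_p_wind, self.cascade_p_no_wind):
            if not (0.0 < p <= 0.5):
                raise ValueError(f"cascade weight {p} outside (0, 0.5]")


@dataclass(frozen=True)
class CohortDataset:
    """Generated series plus the truth table of generating parameters."""

    series: tuple[DisplacementSeries, ...]
    truth: pd.DataFrame
    spec: CohortSpec


def _cascade_envelope(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """First n values of a cascade long enough to cover n, scaled to mean 1."""
    k = max(1, math.ceil(math.log2(n)))
    w = binomial_cascade(CascadeSpec(p=p, k=k, seed=int(rng.integers(2**31))))[:n]
    return w / w.mean()


def _running_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS via cumulative sums (edges padded by reflection)."""
    pad = window // 2
    xx = np.pad(x * x, pad, mode="reflect")
    c = np.cumsum(np.concatenate(([0.0], xx)))
    out = (c[window:] - c[:-window]) / window
    return np.sqrt(out[: x.size])


def _one_series(
    spec: CohortSpec, direction: Direction, cascade_p: float, rng: np.random.Generator
) -> np.ndarray:
    n = spec.series_length
    t = np.arange(n) / spec.sample_rate
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = spec.oscillation_amplitude * np.sin(
        2.0 * np.pi * t / spec.oscillation_period + phase
    )
    noise = spec.noise_scale * linear_null_series(
        n, "powerlaw", seed=int(rng.integers(2**31)),
        exponent=1.0, sample_rate=spec.sample_rate,
    )
    fluct = carrier + noise
    if direction == "widening":
        env = _cascade_envelope(cascade_p, n, rng)
        u = (spec.baseline + fluct) * env
    elif direction == "narrowing":
        # dynamic gain control: normalize fluctuations by their own
        # running amplitude over ~2 carrier periods
        win = max(8, int(2 * spec.oscillation_period * spec.sample_rate))
        rms = _running_rms(fluct, win)
        stabilized = fluct / (0.1 * spec.oscillation_amplitude + rms)
        u = spec.baseline + spec.oscillation_amplitude * stabilized
    else:
        u = spec.baseline + fluct
    return np.abs(u)


def synth_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate the full cohort: n_subjects x 2 conditions, with truth table."""
    series: list[DisplacementSeries] = []
    rows: list[dict] = []
    root = np.random.SeedSequence(spec.seed)
    per_condition = {
        1: (spec.direction_wind, spec.cascade_p_wind),
        0: (spec.direction_no_wind, spec.cascade_p_no_wind),
    }
    for subj_idx, child in enumerate(root.spawn(spec.n_subjects), start=1):
        subject_id = f"S{subj_idx:02d}"
        cond_seeds = child.spawn(2)
        for cond, cseed in zip((1, 0), cond_seeds):
            direction, cascade_p = per_condition[cond]
            rng = np.random.default_rng(cseed)
            u = _one_series(spec, direction, cascade_p, rng)
            series.append(
                DisplacementSeries(
                    u=u,
                    sample_rate=spec.sample_rate,
                    subject_id=subject_id,
                    condition=cond,
                )
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": cond,
                    "direction": direction,
                    "cascade_p": cascade_p if direction == "widening" else np.nan,
                    "oscillation_period": spec.oscillation_period,
                    "oscillation_amplitude": spec.oscillation_amplitude,
                    "noise_scale": spec.noise_scale,
                }
            )
    return CohortDataset(series=tuple(series), truth=pd.DataFrame(rows), spec=spec)


def write_cohort(dataset: CohortDataset, outdir: str | Path) -> Path:
    """Write one displacement file per series, a manifest and the spec as YAML.

    Returns the manifest path.  File layout: ``<subject>_c<condition>.csv``
    for series, ``manifest.csv`` and ``cohort_spec.yaml`` at the top level.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for d, (_, truth) in zip(dataset.series, dataset.truth.iterrows()):
        fname = f"{d.subject_id}_c{d.condition}.csv"
        write_displacement(d, outdir / fname)
        row = {
            "subject_id": d.subject_id,
            "condition": d.condition,
            "file": fname,
            "onset_index": d.onset_index,
        }
        row.update(
            {
                k: truth[k]
                for k in ("direction", "cascade_p", "oscillation_period",
                          "oscillation_amplitude", "noise_scale")
            }
        )
        manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = outdir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    spec_dict = {k: getattr(dataset.spec, k) for k in dataset.spec.__dataclass_fields__}
    with open(outdir / "cohort_spec.yaml", "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=False)
    return manifest_path
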