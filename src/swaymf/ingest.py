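"""Reading postural time series and preparing them for multifractal analysis.

The raw observable is the 3-D position of a tracked point on the animal's
body.  The quantity analysed downstream is the *postural-displacement
series*: the Euclidean distance between each consecutive pair of position
samples.  Displacement is nonnegative by construction, which is what lets
it be treated as a mass-like measure when binned at multiple time scales.

Sample indices are 1-based in documentation and in output tables; internal
arrays use ordinary 0-based, half-open Python indexing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionSeries",
    "DisplacementSeries",
    "BlockSet",
    "to_displacement",
    "partition_blocks",
    "read_positions",
    "read_displacement",
    "write_displacement",
    "read_manifest",
    "write_manifest",
]

#: Condition coding used throughout: 1 = wind stimulation, 0 = no wind.
WIND = 1
NO_WIND = 0


@dataclass(frozen=True)
class PositionSeries:
    """Ordered (x, y, z) samples of one tracked point.

    Parameters
    ----------
    xyz : (n, 3) array of coordinates in consistent length units.
    sample_rate : sampling rate in Hz.
    subject_id : subject label.
    condition : 1 = wind, 0 = no-wind (``None`` if unlabelled).
    """

    xyz: np.ndarray
    sample_rate: float = 50.0
    subject_id: str | None = None
    condition: int | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3); got shape {xyz.shape}")
        if xyz.shape[0] < 2:
            raise ValueError("need at least 2 position samples")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates in position series")
        object.__setattr__(self, "xyz", xyz)

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass(frozen=True)
class DisplacementSeries:
    """Nonnegative displacement magnitudes, one per consecutive sample pair.

    ``onset_index`` marks the (0-based) sample at which stimulation begins;
    block partitioning starts there, while whole-series measures always use
    the entire stored series.
    """

    u: np.ndarray
    sample_rate: float = 50.0
    subject_id: str | None = None
    condition: int | None = None
    onset_index: int = 0

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 1:
            raise ValueError("displacement series must be 1-D")
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite displacement values")
        if np.any(u < 0):
            raise ValueError("displacement values must be nonnegative")
        if self.onset_index < 0:
            raise ValueError("onset_index must be nonnegative")
        object.__setattr__(self, "u", u)

    def __len__(self) -> int:
        return self.u.size


@dataclass(frozen=True)
class BlockSet:
    """Contiguous, non-overlapping, equal-length sub-series of one series."""

    blocks: tuple[DisplacementSeries, ...]
    block_length: int = 1000

    def __post_init__(self) -> None:
        for b in self.blocks:
            if len(b) != self.block_length:
                raise ValueError(
                    f"block of length {len(b)} != block_length {self.block_length}"
                )

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def to_displacement(pos: PositionSeries) -> DisplacementSeries:
    """Euclidean distance between consecutive position samples.

    Returns a series one sample shorter than the input, with metadata
    propagated.
    """
    steps = np.diff(pos.xyz, axis=0)
    u = np.linalg.norm(steps, axis=1)
    return DisplacementSeries(
        u=u,
        sample_rate=pos.sample_rate,
        subject_id=pos.subject_id,
        condition=pos.condition,
    )


def partition_blocks(
    d: DisplacementSeries, block_length: int = 1000, n_blocks: int = 4
) -> BlockSet:
    """Cut the first ``n_blocks`` full blocks starting at the onset index.

    Trailing partial data are discarded.  Raises ``ValueError`` naming the
    shortfall when the series cannot supply ``n_blocks`` full blocks.
    """
    if block_length < 1 or n_blocks < 1:
        raise ValueError("block_length and n_blocks must be positive")
    start = d.onset_index
    available = len(d) - start
    needed = n_blocks * block_length
    if available < needed:
        raise ValueError(
            f"series supplies {max(available, 0)} samples from onset "
            f"{start}, but {needed} are needed for {n_blocks} blocks of "
            f"{block_length}"
        )
    blocks = []
    for i in range(n_blocks):
        lo = start + i * block_length
        seg = d.u[lo : lo + block_length]
        blocks.append(replace(d, u=seg, onset_index=0))
    return BlockSet(blocks=tuple(blocks), block_length=block_length)


# ---------------------------------------------------------------------------
# Delimited-text IO.  Comma or tab is autodetected on read; floats are
# serialized at full (round-trip) precision on write.
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_positions(
    path: str | Path,
    sample_rate: float = 50.0,
    subject_id: str | None = None,
    condition: int | None = None,
) -> PositionSeries:
    """Read a position file with columns x, y, z (an optional t column is
    ignored for analysis but tolerated)."""
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("x", "y", "z") if c not in cols]
    if missing:
        raise ValueError(f"position file {path} lacks columns {missing}")
    xyz = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    return PositionSeries(
        xyz=xyz, sample_rate=sample_rate, subject_id=subject_id, condition=condition
    )


def read_displacement(
    path: str | Path,
    sample_rate: float = 50.0,
    subject_id: str | None = None,
    condition: int | None = None,
    onset_index: int = 0,
) -> DisplacementSeries:
    """Read a displacement file.

    Accepts either a single value column or a table with a ``displacement``
    column (an accompanying ``sample_index`` column is ignored).
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "displacement" in cols:
        u = df[cols["displacement"]].to_numpy(dtype=float)
    elif df.shape[1] == 1:
        u = df.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"displacement file {path} must have a 'displacement' column or a "
            f"single value column; got columns {list(df.columns)}"
        )
    return DisplacementSeries(
        u=u,
        sample_rate=sample_rate,
        subject_id=subject_id,
        condition=condition,
        onset_index=onset_index,
    )


def write_displacement(d: DisplacementSeries, path: str | Path, sep: str = ",") -> None:
    """Write a displacement series as (sample_index, displacement) rows.

    ``sample_index`` is 1-based, matching the conventions of the output
    tables; values round-trip bit-exactly through ``read_displacement``.
    """
    df = pd.DataFrame(
        {"sample_index": np.arange(1, len(d) + 1), "displacement": d.u}
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


MANIFEST_COLUMNS = ["subject_id", "condition", "file", "onset_index"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest (subject_id, condition, file, onset_index)."""
    df = _read_table(path)
    missing = [c for c in ("subject_id", "condition", "file") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    if "onset_index" not in df.columns:
        df["onset_index"] = 0
    df["onset_index"] = df["onset_index"].fillna(0).astype(int)
    df["condition"] = df["condition"].astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
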