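"""Cohort orchestration: per-series and per-block measures, modelling table.

For each displacement series the pipeline computes

* W_ALL, t_ALL — spectrum width and surrogate t over the *entire* stored
  series, with the coarsest bin at one quarter of the series length
  (4..1503 samples for a 6012-sample series);
* W_BLOCK, t_BLOCK — the same measures on each of the first four
  contiguous 1000-sample (20 s) blocks counted from the stimulation
  onset, with the coarsest bin at 250 samples.

Block t statistics are computed against surrogates of that block alone,
so each unit is compared with the best-fitting linear model of that same
unit (surrogates of the whole series are available as an option).  The
result is one tidy table, one row per subject x condition x unit
(ALL, Block1..Block4), with the whole-series measures joined onto every
block row — the direct input to the mixed-effects models.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .ingest import DisplacementSeries, partition_blocks, read_displacement, read_manifest
from .multifractal import ScalingConfig, estimate_spectrum
from .surrogates import T_CRITICAL, surrogate_widths, t_mf

__all__ = [
    "AnalysisConfig",
    "analyze_series",
    "build_cohort_table",
    "condition_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one cohort analysis run."""

    scaling_all: ScalingConfig = ScalingConfig(l_max=None)
    scaling_block: ScalingConfig = ScalingConfig(l_max=250)
    block_length: int = 1000
    n_blocks: int = 4
    n_surrogates: int = 50
    n_iterations: int = 1000
    se_mode: Literal["se", "sd"] = "se"
    block_surrogate_scope: Literal["block", "series"] = "block"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "block_length": self.block_length,
            "n_blocks": self.n_blocks,
            "n_surrogates": self.n_surrogates,
            "n_iterations": self.n_iterations,
            "se_mode": self.se_mode,
            "block_surrogate_scope": self.block_surrogate_scope,
            "seed": self.seed,
        }
        for name, cfg in (("scaling_all", self.scaling_all),
                          ("scaling_block", self.scaling_block)):
            d[name] = {
                "q_min": float(cfg.q_values.min()),
                "q_max": float(cfg.q_values.max()),
                "n_q": int(cfg.q_values.size),
                "l_min": cfg.l_min,
                "l_max": cfg.l_max,
                "n_scales": cfg.n_scales,
                "r_threshold": cfg.r_threshold,
            }
        return d


def _unit_measures(u: np.ndarray, cfg: ScalingConfig, acfg: AnalysisConfig, seed: int):
    spec = estimate_spectrum(u, cfg)
    ens = surrogate_widths(
        u, cfg,
        n_surrogates=acfg.n_surrogates,
        n_iterations=acfg.n_iterations,
        seed=seed,
    )
    stat = t_mf(spec.width, ens, se_mode=acfg.se_mode)
    return spec, stat


def analyze_series(
    d: DisplacementSeries, acfg: AnalysisConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Measures for one series: one ALL row plus one row per block.

    Columns: subject_id, condition, block ('ALL' or '1'..'4'), W, t,
    n_retained_q, W_ALL, t_ALL.  When the series cannot supply the
    requested blocks, only the ALL row is returned and a warning logged.
    """
    acfg = acfg or AnalysisConfig()
    seed = acfg.seed if seed is None else seed
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec_all, t_all = _unit_measures(d.u, acfg.scaling_all, acfg, seed)
    rows.append(
        {
            "subject_id": d.subject_id,
            "condition": d.condition,
            "block": "ALL",
            "W": spec_all.width,
            "t": t_all.t,
            "n_retained_q": spec_all.n_retained,
        }
    )
    try:
        blocks = partition_blocks(d, acfg.block_length, acfg.n_blocks)
    except ValueError as exc:
        logger.warning(
            "series %s/condition %s: %s; block measures skipped",
            d.subject_id, d.condition, exc,
        )
        blocks = None
    if blocks is not None:
        series_surr = None
        if acfg.block_surrogate_scope == "series":
            from .surrogates import iaaft

            series_surr = [
                iaaft(d.u, n_iterations=acfg.n_iterations, seed=seed + 1000 + i)
                for i in range(acfg.n_surrogates)
            ]
        for bi, block in enumerate(blocks, start=1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if series_surr is None:
                    spec_b, t_b = _unit_measures(
                        block.u, acfg.scaling_block, acfg, seed + 100 * bi
                    )
                else:
                    # slice each whole-series surrogate at this block's span
                    spec_b = estimate_spectrum(block.u, acfg.scaling_block)
                    lo = d.onset_index + (bi - 1) * acfg.block_length
                    widths = []
                    for s in series_surr:
                        sspec = estimate_spectrum(
                            s[lo : lo + acfg.block_length], acfg.scaling_block
                        )
                        widths.append(sspec.width)
                    t_b = t_mf(spec_b.width, np.asarray(widths), se_mode=acfg.se_mode)
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "condition": d.condition,
                    "block": str(bi),
                    "W": spec_b.width,
                    "t": t_b.t,
                    "n_retained_q": spec_b.n_retained,
                }
            )
    out = pd.DataFrame(rows)
    out["W_ALL"] = out.loc[out["block"] == "ALL", "W"].iloc[0]
    out["t_ALL"] = out.loc[out["block"] == "ALL", "t"].iloc[0]
    return out


def build_cohort_table(
    manifest: pd.DataFrame | str | Path,
    data_dir: str | Path | None = None,
    acfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over a cohort manifest.

    Unreadable series are skipped with a logged warning; a duplicate
    subject x condition pair is a hard error.  Rows are ordered by
    (subject, condition, block) and the per-series seed is derived
    deterministically from the run seed and the row position, so the
    same inputs and seed give an identical table.
    """
    acfg = acfg or AnalysisConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if data_dir is None:
            data_dir = manifest_path.parent
        manifest = read_manifest(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else Path(".")

    if manifest.empty:
        logger.warning("empty manifest: returning empty cohort table")
        return pd.DataFrame(
            columns=["subject_id", "condition", "block", "W", "t",
                     "n_retained_q", "W_ALL", "t_ALL"]
        )
    dup = manifest.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        pairs = manifest.loc[dup, ["subject_id", "condition"]].to_records(index=False)
        raise ValueError(f"duplicate subject x condition entries: {list(pairs)}")

    manifest = manifest.sort_values(["subject_id", "condition"]).reset_index(drop=True)
    parts = []
    for i, row in manifest.iterrows():
        path = data_dir / row["file"]
        t0 = time.perf_counter()
        try:
            d = read_displacement(
                path,
                subject_id=row["subject_id"],
                condition=int(row["condition"]),
                onset_index=int(row.get("onset_index", 0)),
            )
        except Exception as exc:
            logger.warning("skipping %s (%s/%s): %s",
                           path, row["subject_id"], row["condition"], exc)
            continue
        parts.append(analyze_series(d, acfg, seed=acfg.seed + 10_000 * (i + 1)))
        logger.info(
            "analyzed %s/condition %s in %.1f s",
            row["subject_id"], row["condition"], time.perf_counter() - t0,
        )
    if not parts:
        logger.warning("no readable series in manifest")
        return pd.DataFrame(
            columns=["subject_id", "condition", "block", "W", "t",
                     "n_retained_q", "W_ALL", "t_ALL"]
        )
    return pd.concat(parts, ignore_index=True)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition whole-series summary using the cohort counting scheme.

    Reports mean and SD of W_ALL and t_ALL plus the number of series with
    t_ALL above +1.96 and below -1.96 (two-sided 5% cuts).
    """
    all_rows = table[table["block"] == "ALL"]
    recs = []
    for cond, grp in all_rows.groupby("condition"):
        recs.append(
            {
                "condition": cond,
                "n_series": len(grp),
                "W_ALL_mean": grp["W"].mean(),
                "W_ALL_sd": grp["W"].std(ddof=1),
                "t_ALL_mean": grp["t"].mean(),
                "t_ALL_sd": grp["t"].std(ddof=1),
                "n_t_above": int((grp["t"] > T_CRITICAL).sum()),
                "n_t_below": int((grp["t"] < -T_CRITICAL).sum()),
            }
        )
    return pd.DataFrame(recs)
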