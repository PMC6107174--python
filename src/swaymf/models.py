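"""Mixed-effects models of the block-wise cohort measures.

Two linear mixed models, each with a random intercept per subject and 16
fixed-effect terms (intercept + 15):

* ``fit_w_block`` — W_BLOCK regressed on Condition, three orthogonal
  polynomials of Block (linear, quadratic, cubic: smooth change over the
  four 20-s blocks), the whole-series covariate W_ALL, and all two- and
  three-way interactions among them.
* ``fit_t_block`` — t_BLOCK regressed on Condition, Block coded as a
  class variable (separate intercept shifts for Blocks 2-4 relative to
  Block 1), the covariate t_ALL, and the same interaction structure.

Estimation is by REML.  Fixed-effect p-values use t tests on the
residual degrees of freedom (observations minus fixed terms); the df
method is recorded in the fit so values can be compared against
Satterthwaite-based output from other tools.  Covariates enter
uncentered, on their raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "orthogonal_poly",
    "build_design",
    "ModelFit",
    "fit_w_block",
    "fit_t_block",
]

BlockCoding = Literal["orthogonal_poly_3", "categorical"]


def orthogonal_poly(x: np.ndarray, degree: int = 3) -> np.ndarray:
    """Orthonormal polynomial contrasts of x over the observed design.

    Columns are mutually orthogonal with unit norm over the data vector
    (the convention of R's ``poly``), signed so the linear column
    increases with x.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size <= degree:
        raise ValueError(
            f"need more than {degree} distinct x values for degree {degree}"
        )
    X = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(X)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Z = (Q * signs)[:, 1:]
    return Z / np.linalg.norm(Z, axis=0)


def _block_columns(block: np.ndarray, coding: BlockCoding):
    if coding == "orthogonal_poly_3":
        cols = orthogonal_poly(block.astype(float), 3)
        names = ["Block(Linear)", "Block(Quadratic)", "Block(Cubic)"]
    elif coding == "categorical":
        names = ["Block2", "Block3", "Block4"]
        cols = np.column_stack([(block == b).astype(float) for b in (2, 3, 4)])
    else:
        raise ValueError(f"unknown block coding {coding!r}")
    return cols, names


def build_design(
    condition: np.ndarray,
    block: np.ndarray,
    covariate: np.ndarray,
    coding: BlockCoding,
    covariate_name: str,
) -> tuple[np.ndarray, list[str]]:
    """Full 16-column fixed-effect design: Condition x Block terms x covariate."""
    cond = np.asarray(condition, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    bcols, bnames = _block_columns(np.asarray(block), coding)
    n = cond.size
    cols = [np.ones(n), cond]
    names = ["Intercept", "Condition"]
    for j, bn in enumerate(bnames):
        cols.append(bcols[:, j])
        names.append(bn)
    cols.append(cov)
    names.append(covariate_name)
    for j, bn in enumerate(bnames):
        cols.append(cond * bcols[:, j])
        names.append(f"Condition:{bn}")
    cols.append(cond * cov)
    names.append(f"Condition:{covariate_name}")
    for j, bn in enumerate(bnames):
        cols.append(bcols[:, j] * cov)
        names.append(f"{bn}:{covariate_name}")
    for j, bn in enumerate(bnames):
        cols.append(cond * bcols[:, j] * cov)
        names.append(f"Condition:{bn}:{covariate_name}")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class ModelFit:
    """Fixed-effect estimates plus variance components for one model."""

    terms: pd.DataFrame          # columns: term, B, SE, p
    random_intercept_var: float
    residual_var: float
    df_method: str
    df_resid: float
    response: str
    coding: str
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return self.terms.copy()


def _find_aliased(X: np.ndarray, names: list[str]) -> str:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    j = int(np.argmin(diag / max(diag.max(), 1e-300)))
    return names[j]


def _fit_mixed(
    table: pd.DataFrame,
    response: str,
    covariate: str,
    coding: BlockCoding,
) -> ModelFit:
    blocks = table[table["block"] != "ALL"].copy()
    if blocks.empty:
        raise ValueError("cohort table contains no block rows")
    for col in ("W", "t", covariate):
        if blocks[col].isna().any():
            bad = blocks.loc[blocks[col].isna(), ["subject_id", "condition", "block"]]
            raise ValueError(f"missing {col} values in block rows:\n{bad}")
    counts = blocks.groupby(["subject_id", "condition"]).size()
    if (counts != counts.iloc[0]).any():
        raise ValueError("unbalanced block counts across subject x condition")

    y = blocks["W" if response == "W_BLOCK" else "t"].to_numpy(dtype=float)
    X, names = build_design(
        blocks["condition"].to_numpy(),
        blocks["block"].astype(int).to_numpy(),
        blocks[covariate].to_numpy(),
        coding,
        covariate,
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design is rank deficient; aliased term: {_find_aliased(X, names)}"
        )
    exog = pd.DataFrame(X, columns=names)
    groups = blocks["subject_id"].to_numpy()
    # boundary variance estimates can stall the default optimizer;
    # derivative-free refits recover those cases
    res = None
    for method in (None, "powell", "nm"):
        model = sm.MixedLM(y, exog, groups=groups)
        try:
            cand = model.fit(reml=True) if method is None else model.fit(
                reml=True, method=method
            )
        except np.linalg.LinAlgError:
            continue
        res = cand
        if cand.converged and np.all(np.isfinite(cand.bse_fe)):
            break
    if res is None:
        raise RuntimeError("mixed-model fit failed under all optimizers")
    df_resid = y.size - X.shape[1]
    tvals = res.fe_params / res.bse_fe
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    terms = pd.DataFrame(
        {
            "term": names,
            "B": res.fe_params.to_numpy(),
            "SE": res.bse_fe.to_numpy(),
            "p": pvals,
        }
    )
    return ModelFit(
        terms=terms,
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        residual_var=float(res.scale),
        df_method="residual-t",
        df_resid=float(df_resid),
        response=response,
        coding=coding,
        converged=bool(res.converged),
    )


def fit_w_block(table: pd.DataFrame) -> ModelFit:
    """Smooth-change model: W_BLOCK on Condition x orthogonal Block
    polynomials x W_ALL, random intercept per subject."""
    return _fit_mixed(table, "W_BLOCK", "W_ALL", "orthogonal_poly_3")


def fit_t_block(table: pd.DataFrame) -> ModelFit:
    """Categorical-block model: t_BLOCK on Condition x Block(2-4 dummies)
    x t_ALL, random intercept per subject."""
    return _fit_mixed(table, "t_BLOCK", "t_ALL", "categorical")
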