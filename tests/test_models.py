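"""Mixed-effects models of the block-wise measures."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swaymf import build_design, fit_t_block, fit_w_block, orthogonal_poly

N_FIXED_TERMS = 16


def make_block_table(
    n_subjects=21,
    beta=None,
    coding="orthogonal_poly_3",
    covariate="W_ALL",
    sigma_subject=0.3,
    sigma_resid=1.0,
    seed=0,
):
    """Construct a cohort block table directly from a known fixed-effect
    vector plus a subject random intercept — the recovery oracle."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        subj = f"S{i:02d}"
        intercept = rng.normal(0, sigma_subject)
        for cond in (0, 1):
            cov = rng.normal(1.0, 0.5)
            for block in (1, 2, 3, 4):
                rows.append(
                    dict(subject_id=subj, condition=cond, block=str(block),
                         cov=cov, rand=intercept)
                )
    df = pd.DataFrame(rows)
    X, names = build_design(
        df["condition"].to_numpy(), df["block"].astype(int).to_numpy(),
        df["cov"].to_numpy(), coding, covariate,
    )
    beta = np.zeros(N_FIXED_TERMS) if beta is None else np.asarray(beta, float)
    y = X @ beta + df["rand"].to_numpy() + rng.normal(0, sigma_resid, len(df))
    out = df[["subject_id", "condition", "block"]].copy()
    if covariate == "W_ALL":
        out["W"] = y
        out["t"] = 0.0
    else:
        out["t"] = y
        out["W"] = 0.0
    out[covariate] = df["cov"]
    other = "t_ALL" if covariate == "W_ALL" else "W_ALL"
    out[other] = 0.0
    return out, names


class TestOrthogonalPoly:
    def test_columns_orthonormal_over_design(self):
        x = np.tile([1.0, 2.0, 3.0, 4.0], 42)
        Z = orthogonal_poly(x, 3)
        np.testing.assert_allclose(Z.T @ Z, np.eye(3), atol=1e-10)

    def test_linear_column_increases_with_x(self):
        Z = orthogonal_poly(np.array([1.0, 2.0, 3.0, 4.0]), 3)
        assert np.all(np.diff(Z[:, 0]) > 0)

    def test_requires_enough_distinct_values(self):
        with pytest.raises(ValueError):
            orthogonal_poly(np.array([1.0, 1.0, 2.0, 2.0]), 3)


class TestDesign:
    @pytest.mark.parametrize("coding", ["orthogonal_poly_3", "categorical"])
    def test_sixteen_fixed_columns(self, coding):
        table, names = make_block_table(n_subjects=4, coding=coding)
        assert len(names) == N_FIXED_TERMS

    def test_codings_span_identical_model_space(self):
        # balanced design: the polynomial and categorical codings are
        # reparameterizations, so OLS predictions must coincide
        table, _ = make_block_table(n_subjects=6, seed=3)
        cond = table["condition"].to_numpy()
        block = table["block"].astype(int).to_numpy()
        cov = table["W_ALL"].to_numpy()
        y = table["W"].to_numpy()
        preds = []
        for coding in ("orthogonal_poly_3", "categorical"):
            X, _ = build_design(cond, block, cov, coding, "W_ALL")
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            preds.append(X @ coef)
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-8)


class TestFitWBlock:
    def test_recovers_injected_effects_within_two_se(self):
        beta = np.zeros(N_FIXED_TERMS)
        beta[0] = 0.1    # intercept
        beta[1] = 0.6    # Condition
        beta[4] = -0.8   # Block(Cubic)
        beta[5] = 0.5    # covariate W_ALL
        table, names = make_block_table(beta=beta, sigma_resid=0.4, seed=11)
        fit = fit_w_block(table)
        assert len(fit.terms) == N_FIXED_TERMS
        for term, true in (("Condition", 0.6), ("Block(Cubic)", -0.8),
                           ("W_ALL", 0.5)):
            row = fit.terms.set_index("term").loc[term]
            assert abs(row["B"] - true) < 2 * row["SE"]

    def test_null_pvalues_roughly_uniform(self):
        # pooled fixed-effect p-values under a pure-noise generator
        pvals = []
        for rep in range(40):
            table, _ = make_block_table(n_subjects=12, seed=1000 + rep)
            fit = fit_w_block(table)
            pvals.extend(fit.terms["p"].tolist())
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_rank_deficient_design_names_aliased_term(self):
        table, _ = make_block_table(n_subjects=6, seed=2)
        single = table[table["condition"] == 1]
        with pytest.raises(ValueError, match="Condition"):
            fit_w_block(single)


class TestFitTBlock:
    def test_recovers_injected_interaction_within_two_se(self):
        beta = np.zeros(N_FIXED_TERMS)
        beta[0] = -2.0   # intercept
        beta[13] = 1.2   # Condition:Block2:t_ALL
        table, names = make_block_table(
            beta=beta, coding="categorical", covariate="t_ALL",
            sigma_resid=0.8, seed=21,
        )
        assert names[13] == "Condition:Block2:t_ALL"
        fit = fit_t_block(table)
        assert len(fit.terms) == N_FIXED_TERMS
        row = fit.terms.set_index("term").loc["Condition:Block2:t_ALL"]
        assert abs(row["B"] - 1.2) < 2 * row["SE"]

    def test_condition_terms_vanish_under_within_subject_permutation(self):
        # permuting condition labels within subjects destroys any real
        # condition effect; significant condition terms should be rare
        beta = np.zeros(N_FIXED_TERMS)
        beta[5] = 0.5  # t_ALL main effect survives permutation
        rng = np.random.default_rng(5)
        n_sig = 0
        n_perm = 30
        for rep in range(n_perm):
            table, _ = make_block_table(
                beta=beta, coding="categorical", covariate="t_ALL",
                seed=3000 + rep,
            )
            flip = {
                s: rng.integers(2) for s in table["subject_id"].unique()
            }
            swap = table["subject_id"].map(flip) == 1
            table.loc[swap, "condition"] = 1 - table.loc[swap, "condition"]
            fit = fit_t_block(table)
            cond_terms = fit.terms[fit.terms["term"].str.contains("Condition")]
            n_sig += int((cond_terms["p"] < 0.05).any())
        assert n_sig <= 0.1 * n_perm + 2

    def test_missing_covariate_rejected(self):
        table, _ = make_block_table(coding="categorical", covariate="t_ALL")
        table.loc[3, "t_ALL"] = np.nan
        with pytest.raises(ValueError, match="t_ALL"):
            fit_t_block(table)


@pytest.mark.parametrize("response", ["W_BLOCK", "t_BLOCK"])
def test_agrees_with_lmer_reference(response, tmp_path):
    """Independent cross-check: lme4/lmerTest fitting the identical design."""
    covariate = "W_ALL" if response == "W_BLOCK" else "t_ALL"
    coding = "orthogonal_poly_3" if response == "W_BLOCK" else "categorical"
    beta = np.zeros(N_FIXED_TERMS)
    beta[1] = 0.4
    table, names = make_block_table(
        n_subjects=10, beta=beta, coding=coding, covariate=covariate, seed=8
    )
    fit = fit_w_block(table) if response == "W_BLOCK" else fit_t_block(table)

    X, _ = build_design(
        table["condition"].to_numpy(), table["block"].astype(int).to_numpy(),
        table[covariate].to_numpy(), coding, covariate,
    )
    df = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(1, 16)])
    df["y"] = table["W" if response == "W_BLOCK" else "t"].to_numpy()
    df["subject"] = table["subject_id"].to_numpy()
    csv = tmp_path / "design.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(textwrap.dedent(f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        f <- y ~ {' + '.join(f'x{i}' for i in range(1, 16))} + (1 | subject)
        m <- lmer(f, data = d, REML = TRUE)
        s <- summary(m)$coefficients
        write.csv(data.frame(B = s[, "Estimate"], SE = s[, "Std. Error"]),
                  "{tmp_path}/ref.csv", row.names = FALSE)
    """))
    try:
        subprocess.run(
            ["Rscript", "--vanilla", str(rscript)], check=True,
            capture_output=True, timeout=300,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        pytest.skip(f"R/lmerTest unavailable: {exc}")
    ref = pd.read_csv(tmp_path / "ref.csv")
    np.testing.assert_allclose(fit.terms["B"].to_numpy(), ref["B"], atol=1e-4)
    np.testing.assert_allclose(fit.terms["SE"].to_numpy(), ref["SE"], rtol=2e-2)
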