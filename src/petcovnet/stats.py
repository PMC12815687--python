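"""Group-level inference.

The headline test is a label-permutation test on pooled edge deviation
scores: each participant contributes one flat vector of z-scores, the
observed statistic is the difference of pooled-edge means between two groups,
and the null distribution is built by shuffling participant group labels
(participant-level exchangeability — vectors travel with their labels).
Effect sizes are Cohen's d on the pooled edge values.

Also provided: the conventional battery used around the network analysis —
one-way ANCOVA, mixed (split-plot) ANOVA with Greenhouse-Geisser correction
and generalised eta squared, chi-square independence, Pearson/partial
correlations and Holm/Bonferroni p adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "AnovaResult",
    "permutation_test",
    "cohens_d",
    "oneway_ancova",
    "mixed_anova_gg",
    "chisq_independence",
    "correlate",
    "p_adjust",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    cohens_d: float
    seed: int | None = None
    mode: str | None = None
    groups: tuple[str, str] | None = None
    exact: bool = False


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    ges: float
    p_gg: float | None = None
    epsilon: float | None = None
    p_adjusted: float | None = None


def cohens_d(values_a, values_b) -> float:
    """d = (mean_a - mean_b) / pooled SD, pooled with n_a + n_b - 2."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if pooled_var <= 0:
        raise ValueError("pooled SD is zero; Cohen's d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _stack_vectors(z_vectors_by_participant, labels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    ids = list(z_vectors_by_participant)
    mat = np.vstack([np.asarray(z_vectors_by_participant[i], dtype=float).ravel() for i in ids])
    lab = np.array([labels[i] for i in ids])
    return mat, lab, ids


def permutation_test(
    z_vectors_by_participant,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    groups: tuple[str, str] | None = None,
    mode: str | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Two-group permutation test on pooled edge values.

    ``z_vectors_by_participant`` maps participant id -> flat vector of equal
    length; ``labels`` maps id -> group.  Observed statistic: pooled-edge mean
    of group a minus group b.  Monte-Carlo p is (1 + #{|T*| >= |T|})/(n_perm
    + 1); with ``exact`` every distinct label assignment is enumerated
    instead and p is the exact proportion.
    """
    mat, lab, _ = _stack_vectors(z_vectors_by_participant, labels)
    uniq = sorted(set(lab)) if groups is None else list(groups)
    if len(uniq) != 2 or set(lab) != set(uniq):
        raise ValueError(f"need exactly two groups; got labels {sorted(set(lab))}, groups {uniq}")
    mask_a = lab == uniq[0]
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 participants")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    # the pooled-edge mean difference equals the difference of participant
    # row-mean averages because every vector has the same length
    row_means = mat.mean(axis=1)
    total = row_means.sum()
    n = row_means.size

    def stat(a_idx_sum: float) -> float:
        return a_idx_sum / n_a - (total - a_idx_sum) / n_b

    t_obs = stat(row_means[mask_a].sum())
    d = cohens_d(mat[mask_a].ravel(), mat[~mask_a].ravel())

    if exact:
        null = np.array([
            stat(row_means[list(idx)].sum())
            for idx in itertools.combinations(range(n), n_a)
        ])
        p = float(np.mean(np.abs(null) >= np.abs(t_obs) - 1e-12))
        return PermutationResult(float(t_obs), p, comb(n, n_a), d, seed=None,
                                 mode=mode, groups=(uniq[0], uniq[1]), exact=True)

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
    null = row_means[perms].sum(axis=1) / n_a - (total - row_means[perms].sum(axis=1)) / n_b
    hits = int(np.sum(np.abs(null) >= np.abs(t_obs) - 1e-12))
    p = (1 + hits) / (n_perm + 1)
    return PermutationResult(float(t_obs), float(p), n_perm, d, seed=seed,
                             mode=mode, groups=(uniq[0], uniq[1]), exact=False)


# ---------------------------------------------------------------------------
# conventional battery
# ---------------------------------------------------------------------------

def oneway_ancova(values, groups, covariates: pd.DataFrame | None = None) -> AnovaResult:
    """One-way ANOVA of ``values`` on group with covariates of no interest
    (Type II sums of squares); df_den = N - g - c."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "group": np.asarray(groups)})
    terms = []
    if covariates is not None:
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)
            terms.append(c)
    if df["group"].nunique() < 2 or (df.groupby("group").size() < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    formula = "y ~ " + " + ".join(terms + ["C(group)"]) if terms else "y ~ C(group)"
    fit = ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    row = tab.loc["C(group)"]
    resid = tab.loc["Residual"]
    ges = float(row["sum_sq"] / (row["sum_sq"] + resid["sum_sq"]))
    return AnovaResult(
        effect="group",
        F=float(row["F"]),
        df_num=float(row["df"]),
        df_den=float(resid["df"]),
        p=float(row["PR(>F)"]),
        ges=ges,
    )


def _effects_coding(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(groups))
    g = len(levels)
    x = np.zeros((groups.size, g - 1))
    for j, lev in enumerate(levels[:-1]):
        x[groups == lev, j] = 1.0
    x[groups == levels[-1], :] = -1.0
    return x, levels


def _hypothesis_ssp(beta: np.ndarray, xtx_inv: np.ndarray, cols: list[int]) -> np.ndarray:
    """SSP for H0: beta[cols] = 0 in a multivariate OLS (extra-sum-of-squares)."""
    lb = beta[cols, :]
    linv = np.linalg.inv(xtx_inv[np.ix_(cols, cols)])
    return lb.T @ linv @ lb


def mixed_anova_gg(
    table: pd.DataFrame,
    groups,
    covariates: pd.DataFrame | None = None,
) -> list[AnovaResult]:
    """Split-plot ANOVA: between-group factor, within-subject region factor,
    optional between-subject covariates of no interest.

    ``table`` is participants x regions (complete).  Returns results for the
    'group' (between), 'region' (within) and 'group:region' (interaction)
    effects.  Within-subject effects carry a Greenhouse-Geisser corrected
    p (``p_gg``) computed from the epsilon of the residual covariance of the
    orthonormalised within-subject contrasts.  Effect sizes are generalised
    eta squared (effect SS over effect SS plus *all* error SS).
    """
    y = table.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("table contains missing cells; impute upstream")
    n, r = y.shape
    if r < 2:
        raise ValueError("need at least 2 within-subject levels")
    grp = np.asarray(groups)
    if grp.size != n:
        raise ValueError("groups must align with the table rows")
    gx, levels = _effects_coding(grp)
    g = len(levels)
    c = 0
    x = [np.ones((n, 1)), gx]
    if covariates is not None and covariates.shape[1]:
        cov = covariates.to_numpy(dtype=float)
        cov = cov - cov.mean(axis=0)
        c = cov.shape[1]
        x.append(cov)
    x = np.column_stack(x)
    p_rank = x.shape[1]  # 1 + (g-1) + c
    df_err = n - g - c
    if df_err <= 0:
        raise ValueError("not enough participants for the design")
    if np.linalg.matrix_rank(x) < p_rank:
        raise np.linalg.LinAlgError("rank-deficient between-subject design")

    # orthonormal transform: first column = subject average direction,
    # remaining r-1 = within-subject contrasts
    q, _ = np.linalg.qr(np.column_stack([np.full((r, 1), 1.0 / np.sqrt(r)), np.eye(r)[:, : r - 1]]))
    m_within = q[:, 1:]
    u_b = y @ q[:, 0]  # +/- sqrt(r) * subject means; sign is irrelevant to the F tests
    u_w = y @ m_within

    xtx_inv = np.linalg.inv(x.T @ x)
    beta_b = xtx_inv @ x.T @ u_b
    beta_w = xtx_inv @ x.T @ u_w
    group_cols = list(range(1, g))
    int_cols = [0]

    # between-subject: group effect on subject averages
    resid_b = u_b - x @ beta_b
    sse_b = float(resid_b @ resid_b)
    ss_group = float(_hypothesis_ssp(beta_b[:, None], xtx_inv, group_cols).item())
    f_group = (ss_group / (g - 1)) / (sse_b / df_err)

    # within-subject: multivariate residual SSP + trace F tests
    resid_w = u_w - x @ beta_w
    e = resid_w.T @ resid_w
    sse_w = float(np.trace(e))
    h_region = _hypothesis_ssp(beta_w, xtx_inv, int_cols)
    h_inter = _hypothesis_ssp(beta_w, xtx_inv, group_cols)
    df_w_err = df_err * (r - 1)
    mse_w = sse_w / df_w_err
    f_region = (float(np.trace(h_region)) / (r - 1)) / mse_w
    f_inter = (float(np.trace(h_inter)) / ((g - 1) * (r - 1))) / mse_w

    # Greenhouse-Geisser epsilon from the within-contrast residual SSP
    eps = float(np.trace(e) ** 2 / ((r - 1) * np.trace(e @ e)))
    eps = min(max(eps, 1.0 / (r - 1)), 1.0)

    all_err = sse_b + sse_w

    def _res(effect, ss_eff, df1, df2, f, within):
        pval = float(sps.f.sf(f, df1, df2))
        out = AnovaResult(
            effect=effect, F=float(f), df_num=float(df1), df_den=float(df2), p=pval,
            ges=float(ss_eff / (ss_eff + all_err)),
            p_gg=float(sps.f.sf(f, eps * df1, eps * df2)) if within else None,
            epsilon=eps if within else None,
        )
        return out

    return [
        _res("group", ss_group, g - 1, df_err, f_group, within=False),
        _res("region", float(np.trace(h_region)), r - 1, df_w_err, f_region, within=True),
        _res("group:region", float(np.trace(h_inter)), (g - 1) * (r - 1), df_w_err, f_inter, within=True),
    ]


def chisq_independence(counts) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on a 2-D count table, no
    continuity correction.  Returns (X^2, p, df)."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("counts must be a 2-D table with >= 2 rows and columns")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in the count table")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def correlate(x, y, covariates: pd.DataFrame | np.ndarray | None = None) -> tuple[float, float]:
    """Pearson (or partial, via residualisation) correlation with a two-sided
    t-based p-value.  Pairs with missing values are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = None if covariates is None else np.asarray(covariates, dtype=float)
    if c is not None and c.ndim == 1:
        c = c[:, None]
    keep = np.isfinite(x) & np.isfinite(y)
    if c is not None:
        keep &= np.all(np.isfinite(c), axis=1)
        c = c[keep]
    x, y = x[keep], y[keep]
    k = 0 if c is None else c.shape[1]
    n = x.size
    if n < 4 + k:
        raise ValueError(f"need at least {4 + k} complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    if c is None:
        r, p = sps.pearsonr(x, y)
        return float(r), float(p)
    design = np.column_stack([np.ones(n), c])
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    rx, ry = (np.column_stack([x, y]) - design @ beta).T
    if rx.std() < 1e-10 * max(x.std(), 1.0) or ry.std() < 1e-10 * max(y.std(), 1.0):
        raise ValueError("a covariate explains x or y exactly; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    return r, float(2.0 * sps.t.sf(abs(t), df))


def p_adjust(p_values, method: str = "holm") -> np.ndarray:
    """Holm step-down or Bonferroni adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown method {method!r}; use 'holm' or 'bonferroni'")
    return multipletests(p, method=method)[1]
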