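"""Cohort-level statistics: windowed mixed models, component scores,
composites and outcome correlations.

The windowed mean amplitudes are modelled per contrast and region with a
linear mixed model: fixed factors Age (5, 10 months), Group (TD, NF1),
Site (left, central, right) and Time (eight 50-ms windows), a
compound-symmetry within-subject covariance (realised as a per-subject
random intercept), and maximum-likelihood estimation.  Follow-up
pairwise comparisons of the Age x Group marginal means use a Bonferroni
family correction.

For the outcome stage, the eight 100-500 ms mean-amplitude variables are
reduced by principal components with a direct oblimin rotation,
components retained by the eigenvalue > 1 rule, and regression-method
factor scores correlated (and partially correlated) with developmental
outcome scores.  Language composites average MSEL and CDI z-scores
referenced to the TD group's mean and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.multivariate.factor_rotation import rotate_factors
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FACTOR_COLUMNS = ("age", "group", "site", "window")


# ---------------------------------------------------------------------------
# windowed mixed models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One model: a contrast waveform's window means in one region."""

    contrast: str
    region: str
    factors: tuple[str, ...] = FACTOR_COLUMNS
    # default fixed-effects structure: all main effects plus the Age x Group
    # interaction (the developmental question); the saturated factorial is
    # available but ill-conditioned for mixed fits at these cell counts
    interactions: tuple[tuple[str, str], ...] = (("age", "group"),)
    full_factorial: bool = False
    covariate: str | None = None     # e.g. retained-trial count column
    alpha: float = 0.05

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.factors]
        if self.full_factorial:
            rhs = "*".join(terms)
        else:
            rhs = "+".join(terms)
            for a, b in self.interactions:
                rhs += f" + C({a}):C({b})"
        if self.covariate:
            rhs += f" + {self.covariate}"
        return f"amplitude ~ {rhs}"


@dataclass
class ModelFit:
    """Omnibus tests, marginal means and machinery for follow-ups."""

    effects: pd.DataFrame            # term, F, df_num, df_den, p, partial_eta_sq
    emm: pd.DataFrame                # age, group, mean, se
    n_obs: int
    df_denom: int
    spec: ModelSpec
    converged: bool
    degenerate: bool                 # zero residual variance -> OLS limit
    _params: np.ndarray = field(repr=False, default=None)
    _cov: np.ndarray = field(repr=False, default=None)
    _emm_rows: dict = field(repr=False, default_factory=dict)

    def cell_mean(self, age, group) -> float:
        row = self.emm[(self.emm["age"] == age) & (self.emm["group"] == group)]
        return float(row["mean"].iloc[0])


def _check_levels(data: pd.DataFrame, spec: ModelSpec) -> None:
    for f in spec.factors:
        n_lev = data[f].nunique()
        if n_lev < 2:
            raise ValueError(
                f"factor {f!r} has {n_lev} level(s) in the data; "
                "every model factor needs at least 2"
            )


def fit_window_lmm(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the compound-symmetry mixed model for one contrast x region.

    Compound symmetry (equal variances, equal covariances across a
    subject's repeated windows/sites) is induced by a per-subject random
    intercept; estimation is maximum likelihood.  Omnibus tests per
    fixed term are Wald tests converted to F with a residual denominator
    df (n_obs - fixed-effect rank).  On degenerate noiseless data the
    ML problem is unbounded and the fit falls back to the OLS limit,
    flagged via ``degenerate``.
    """
    data = table[
        (table["contrast"] == spec.contrast) & (table["region"] == spec.region)
    ].dropna(subset=["amplitude"]).copy()
    if data.empty:
        raise ValueError(f"no rows for contrast {spec.contrast!r} region {spec.region!r}")
    _check_levels(data, spec)
    formula = spec.formula()

    ols = smf.ols(formula, data).fit()
    degenerate = ols.ssr / max(ols.df_resid, 1) < 1e-12
    converged = True
    if degenerate:
        res = ols
    else:
        model = smf.mixedlm(formula, data, groups=data["subject"])
        res = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    res = model.fit(reml=False, method=method)
                if res.converged:
                    break
            except np.linalg.LinAlgError as exc:
                last_exc = exc
                res = None
        if res is None or not res.converged:
            raise RuntimeError(
                f"mixed model failed to converge for {spec.contrast}/"
                f"{spec.region} (formula {formula!r})"
            ) from last_exc

    fe_names = [n for n in res.params.index if n != "Group Var"]
    k_fe = len(fe_names)
    n_obs = len(data)
    df_denom = n_obs - k_fe

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.wald_test_terms(scalar=True).table
    rows = []
    for term, r in wt.iterrows():
        if term == "Intercept":
            continue
        q = int(r["df_constraint"])
        chi2 = float(r["statistic"])
        if not degenerate:
            fstat = chi2 / q
        else:  # OLS wald_test_terms reports F directly
            fstat = chi2
        p = float(sps.f.sf(fstat, q, df_denom))
        eta = (fstat * q) / (fstat * q + df_denom)
        rows.append((term, fstat, q, df_denom, p, eta))
    effects = pd.DataFrame(
        rows, columns=["term", "F", "df_num", "df_den", "p", "partial_eta_sq"]
    )

    # estimated marginal means per Age x Group, averaging the fixed-effect
    # prediction over the levels of the remaining factors
    design_info = res.model.data.design_info
    from patsy import dmatrix

    other = [f for f in spec.factors if f not in ("age", "group")]
    params = np.asarray(res.params[fe_names], dtype=float)
    cov = np.asarray(res.cov_params().loc[fe_names, fe_names], dtype=float)
    emm_rows = {}
    recs = []
    ages = sorted(data["age"].unique())
    groups = sorted(data["group"].unique())
    grids = [sorted(data[f].unique()) for f in other]
    cov_mean = float(data[spec.covariate].mean()) if spec.covariate else None
    for age in ages:
        for grp in groups:
            combos = [{}]
            for f, levels in zip(other, grids):
                combos = [{**c, f: lev} for c in combos for lev in levels]
            grid = pd.DataFrame(
                [{"age": age, "group": grp, **c} for c in combos]
            )
            if spec.covariate:
                grid[spec.covariate] = cov_mean
            X = np.asarray(dmatrix(design_info, grid, return_type="matrix"))
            L = X.mean(axis=0)
            emm_rows[(age, grp)] = L
            mean = float(L @ params)
            se = float(np.sqrt(max(L @ cov @ L, 0.0)))
            recs.append((age, grp, mean, se))
    emm = pd.DataFrame(recs, columns=["age", "group", "mean", "se"])

    return ModelFit(
        effects=effects,
        emm=emm,
        n_obs=n_obs,
        df_denom=df_denom,
        spec=spec,
        converged=converged,
        degenerate=degenerate,
        _params=params,
        _cov=cov,
        _emm_rows=emm_rows,
    )


def bonferroni_alpha(alpha: float, family_size: int) -> float:
    """Adjusted alpha = alpha / family, rounded half-up to 3 decimals
    for reporting (0.05 over a family of 4 prints as .013)."""
    if family_size < 1:
        raise ValueError("family size must be at least 1")
    adj = Decimal(alpha) / Decimal(family_size)
    return float(adj.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def pairwise_followup(
    fit: ModelFit, family_size: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Bonferroni-adjusted pairwise contrasts of the Age x Group means.

    The family comprises the within-group age contrasts and within-age
    group contrasts (4 for a 2 x 2 design).  Adjusted p values are
    min(1, raw p x family); the adjusted alpha is also reported.
    """
    cells = list(fit._emm_rows)
    ages = sorted({a for a, _ in cells})
    groups = sorted({g for _, g in cells})
    pairs = []
    for g in groups:  # within-group, across age
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                pairs.append(((ages[i], g), (ages[j], g)))
    for a in ages:  # within-age, across group
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pairs.append(((a, groups[i]), (a, groups[j])))
    if family_size is None:
        family_size = len(pairs)
    if family_size < 1:
        raise ValueError("family size must be at least 1")

    recs = []
    for c1, c2 in pairs:
        L = fit._emm_rows[c1] - fit._emm_rows[c2]
        diff = float(L @ fit._params)
        se = float(np.sqrt(max(L @ fit._cov @ L, 0.0)))
        tval = diff / se if se > 0 else np.inf * np.sign(diff)
        df = fit.df_denom
        p = float(2 * sps.t.sf(abs(tval), df))
        p_adj = min(1.0, p * family_size)
        half = float(sps.t.ppf(0.975, df)) * se
        recs.append(
            (f"{c1[0]}m/{c1[1]}", f"{c2[0]}m/{c2[1]}", diff, se, df, p, p_adj,
             diff - half, diff + half)
        )
    table = pd.DataFrame(
        recs,
        columns=["cell_a", "cell_b", "diff", "se", "df", "p", "p_bonferroni",
                 "ci_low", "ci_high"],
    )
    return table, bonferroni_alpha(fit.spec.alpha, family_size)


# ---------------------------------------------------------------------------
# principal components with oblimin rotation
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    loadings: pd.DataFrame           # variables x components (pattern matrix)
    phi: np.ndarray                  # component correlations
    eigenvalues: np.ndarray          # all eigenvalues of the correlation matrix
    variance_explained_pct: np.ndarray
    communalities: pd.Series
    scores: pd.DataFrame             # id columns + one column per component
    component_names: list[str]
    n_complete: int


def pca_oblimin(
    table: pd.DataFrame,
    variables: list[str],
    id_columns: tuple[str, ...] = ("subject", "group", "age"),
    gamma: float = 0.0,
    deviant_variables: tuple[str, ...] | None = None,
) -> FactorSolution:
    """Principal components of the correlation matrix, direct-oblimin
    rotated, components kept by the eigenvalue > 1 rule (strict).

    Complete-case on ``variables`` (rows for different age points enter
    as separate observations).  Scores use the regression method:
    Z R^-1 S with S the structure matrix.  Component signs are oriented
    so each component's dominant variable block loads positively; the
    component dominated by the deviant contrasts is listed first and
    named ``deviant_response``, the other ``standard_response``.
    """
    complete = table.dropna(subset=list(variables))
    X = complete[list(variables)].to_numpy(dtype=float)
    n = X.shape[0]
    if n < len(variables) + 2:
        raise ValueError(f"only {n} complete rows for {len(variables)} variables")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix undefined (constant variable?)")
    if np.linalg.matrix_rank(R, tol=1e-10) < R.shape[0]:
        raise ValueError(
            "rank-deficient correlation matrix; drop collinear variables "
            f"(rank {np.linalg.matrix_rank(R, tol=1e-10)} < {R.shape[0]})"
        )
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # strict "> 1" with a float-tie guard (exactly-unit eigenvalues stay out)
    k = int(np.sum(eigvals > 1.0 + 1e-10))

    if k == 0:
        empty = pd.DataFrame(index=list(variables))
        return FactorSolution(
            loadings=empty,
            phi=np.empty((0, 0)),
            eigenvalues=eigvals,
            variance_explained_pct=np.empty(0),
            communalities=pd.Series(0.0, index=list(variables)),
            scores=complete[list(id_columns)].reset_index(drop=True),
            component_names=[],
            n_complete=n,
        )

    A = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    if k == 1:
        L, phi = A.copy(), np.ones((1, 1))
    else:
        L, T = rotate_factors(A, "oblimin", gamma, "oblique")
        phi = T.T @ T

    # orient signs: dominant variable block of each component loads positively
    if deviant_variables is None:
        deviant_variables = tuple(v for v in variables if "Dev" in v)
    dev_idx = [i for i, v in enumerate(variables) if v in deviant_variables]
    std_idx = [i for i, v in enumerate(variables) if v not in deviant_variables]
    names = []
    for j in range(k):
        dev_mass = np.abs(L[dev_idx, j]).sum() if dev_idx else 0.0
        std_mass = np.abs(L[std_idx, j]).sum() if std_idx else 0.0
        block = dev_idx if dev_mass >= std_mass else std_idx
        if L[block, j].sum() < 0:
            L[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
        names.append("deviant_response" if dev_mass >= std_mass else "standard_response")
    # resolve duplicate names deterministically
    seen: dict[str, int] = {}
    uniq = []
    for nm in names:
        seen[nm] = seen.get(nm, 0)
        uniq.append(nm if seen[nm] == 0 else f"{nm}_{seen[nm] + 1}")
        seen[nm] += 1
    names = uniq
    order2 = np.argsort([0 if nm.startswith("deviant") else 1 for nm in names], kind="stable")
    L = L[:, order2]
    phi = phi[np.ix_(order2, order2)]
    names = [names[i] for i in order2]

    communal = pd.Series(np.diag(L @ phi @ L.T), index=list(variables))
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    Z = (X - mu) / sd
    S = L @ phi  # structure matrix
    W = np.linalg.solve(R, S)
    score_vals = Z @ W
    scores = complete[list(id_columns)].reset_index(drop=True).copy()
    for j, nm in enumerate(names):
        scores[nm] = score_vals[:, j]

    return FactorSolution(
        loadings=pd.DataFrame(L, index=list(variables), columns=names),
        phi=phi,
        eigenvalues=eigvals,
        variance_explained_pct=eigvals[:k][order2] / len(variables) * 100.0,
        communalities=communal,
        scores=scores,
        component_names=names,
        n_complete=n,
    )


# ---------------------------------------------------------------------------
# outcome composites and correlations
# ---------------------------------------------------------------------------

COMPOSITES = {
    "language_comprehension": ("msel_receptive_raw", "cdi_words_understood"),
    "language_production": ("msel_expressive_raw", "cdi_words_understands_says"),
}
IBQR_MISSING_LIMIT = 0.2


def score_composites(
    outcomes: pd.DataFrame, reference_group: str = "TD"
) -> pd.DataFrame:
    """TD-referenced z composites and IBQ-R missing-data blanking.

    Each raw score is z-scored against the reference (TD) group's mean
    and SD; a composite is the mean of its two z-scores and exists only
    when both constituents are present.  The IBQ-R Activity score is
    blanked for subjects with more than 20% missing items.
    """
    out = outcomes.copy()
    ref = out[out["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    for comp, (s1, s2) in COMPOSITES.items():
        zcols = []
        for s in (s1, s2):
            mu = ref[s].mean()
            sd = ref[s].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"reference group SD of {s!r} is zero or undefined")
            z = (out[s] - mu) / sd
            out[f"z_{s}"] = z
            zcols.append(f"z_{s}")
        both = out[zcols].notna().all(axis=1)
        out[comp] = np.where(both, out[zcols].mean(axis=1), np.nan)
    if "ibqr_missing_frac" in out.columns and "ibqr_activity" in out.columns:
        out.loc[out["ibqr_missing_frac"] > IBQR_MISSING_LIMIT, "ibqr_activity"] = np.nan
    return out


def correlate_outcomes(
    table: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson correlations with pairwise-complete deletion.

    Reports r, df = n - 2 and the two-tailed p per requested pair;
    pairs with fewer than 3 complete observations are marked
    unavailable (NaN statistics).
    """
    recs = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            recs.append((x, y, n, np.nan, np.nan, np.nan, False))
            continue
        r, p = sps.pearsonr(sub[x], sub[y])
        recs.append((x, y, n, n - 2, float(r), float(p), True))
    return pd.DataFrame(
        recs, columns=["x", "y", "n", "df", "r", "p", "available"]
    )


def partial_correlate(
    table: pd.DataFrame, x: str, y: str, control: str
) -> tuple[float, int, float]:
    """First-order partial correlation of x and y controlling for one
    variable: (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); df = n-3."""
    sub = table[[x, y, control]].dropna()
    n = len(sub)
    if n < 5:
        raise ValueError(f"need at least 5 complete triples, got {n}")
    r_xy = float(np.corrcoef(sub[x], sub[y])[0, 1])
    r_xz = float(np.corrcoef(sub[x], sub[control])[0, 1])
    r_yz = float(np.corrcoef(sub[y], sub[control])[0, 1])
    if min(1.0 - r_xz**2, 1.0 - r_yz**2) < 1e-12:
        raise ValueError("control variable is collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    df = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return r, df, p
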