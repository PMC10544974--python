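"""Variance components and broad-sense heritability.

The phenotype of genotype *i* in environment *j* is modelled with independent
Gaussian random effects,

    y = mu + G_i + E_j + GE_ij + rep_jk + block_jkl + eps,

with variances sigma_G^2, sigma_E^2, sigma_GE^2, sigma_rep^2, sigma_block^2
and sigma_eps^2. Broad-sense heritability on an entry-mean basis over ``x``
environments and ``r`` replications is

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_GE^2 / x + sigma_eps^2 / (x * r)).

Two estimators are provided. The REML fit maximizes the restricted
likelihood directly; the covariance V = sigma_e^2 I + U D U' is handled
through its low-rank structure (U stacks the indicator matrices of all random
terms), so one likelihood evaluation costs a single q x q Cholesky
factorization with q the total number of effect levels. Components are floored
at zero. ``anova_moments`` is the classical expected-mean-squares estimator
for balanced genotype x environment x replicate layouts; on such data the two
agree closely and the moments estimator serves as a fast cross-check.

Model terms absent from a design are dropped automatically: a single
environment collapses G x E into error (a warning is emitted), a single
replicate drops the replicate term, and blocks that coincide with replicates
drop the block term. In unreplicated augmented trials genotype variance is
identified through the repeated checks; convention for ``r`` in the H^2
formula is then the caller's choice (``r=1`` by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp

from .errors import ConvergenceError, UndefinedHeritabilityError

REML = "reml"
ANOVA_MOMENTS = "anova_moments"


@dataclass
class VarianceComponents:
    sigma_G2: float
    sigma_GE2: float
    sigma_eps2: float
    sigma_env2: float = 0.0
    sigma_rep2: float = 0.0
    sigma_block2: float = 0.0
    method: str = REML
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    terms: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "sigma_G2": self.sigma_G2,
            "sigma_GE2": self.sigma_GE2,
            "sigma_eps2": self.sigma_eps2,
            "sigma_env2": self.sigma_env2,
            "sigma_rep2": self.sigma_rep2,
            "sigma_block2": self.sigma_block2,
            "method": self.method,
            "converged": self.converged,
        }


@dataclass
class HeritabilityResult:
    H2: float
    x: int
    r: int
    trait: str = ""
    components: VarianceComponents | None = None


# --------------------------------------------------------------------------
# model terms
# --------------------------------------------------------------------------

def _random_terms(
    table: pd.DataFrame, genotype: str, environment: str, replicate: str, block: str
) -> dict[str, pd.Series]:
    terms: dict[str, pd.Series] = {"genotype": table[genotype].astype(str)}
    env = table[environment].astype(str)
    n_env = env.nunique()
    if n_env >= 2:
        terms["environment"] = env
        terms["gxe"] = table[genotype].astype(str) + "@" + env
    if replicate in table.columns:
        rep = env + "@" + table[replicate].astype(str)
        if rep.nunique() > n_env:
            terms["replicate"] = rep
            if block in table.columns:
                blk = rep + "@" + table[block].astype(str)
                if blk.nunique() > rep.nunique():
                    terms["block"] = blk
        elif block in table.columns:
            blk = env + "@" + table[block].astype(str)
            if blk.nunique() > n_env:
                terms["block"] = blk
    return terms


class _RemlProblem:
    """Restricted log-likelihood of the low-rank random-effects model."""

    def __init__(self, y: np.ndarray, term_labels: dict[str, pd.Series]):
        self.n = len(y)
        self.term_names = list(term_labels)
        cols = []
        self.term_slices: dict[str, slice] = {}
        start = 0
        for name, labels in term_labels.items():
            codes, levels = pd.factorize(labels)
            z = sp.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), codes)),
                shape=(self.n, len(levels)),
            )
            cols.append(z)
            self.term_slices[name] = slice(start, start + len(levels))
            start += len(levels)
        U = sp.hstack(cols, format="csr")
        self.q = U.shape[1]
        X = np.ones((self.n, 1))
        self.p = 1
        self.UtU = (U.T @ U).toarray()
        self.Uty = U.T @ y
        self.UtX = U.T @ X
        self.yty = float(y @ y)
        self.Xty = X.T @ y
        self.XtX = X.T @ X

    def neg2_restricted_loglik(self, variances: np.ndarray, sigma_e2: float) -> float:
        d = np.empty(self.q)
        for name, v in zip(self.term_names, variances):
            d[self.term_slices[name]] = max(v, 1e-300)
        A = self.UtU + np.diag(sigma_e2 / d)
        try:
            c, low = sla.cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
        logdet_V = (self.n - self.q) * np.log(sigma_e2) + float(np.sum(np.log(d))) + logdet_A

        def vinv_quad(Ua, Ub, atb):
            # a' V^-1 b via Woodbury given U'a, U'b and a'b
            s = sla.cho_solve((c, low), Ub, check_finite=False)
            return (atb - Ua.T @ s) / sigma_e2

        yVy = float(vinv_quad(self.Uty, self.Uty, self.yty))
        XVX = vinv_quad(self.UtX, self.UtX, self.XtX)
        XVy = vinv_quad(self.UtX, self.Uty, self.Xty.ravel())
        XVX = np.atleast_2d(XVX)
        sign, logdet_XVX = np.linalg.slogdet(XVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XVX, np.atleast_1d(XVy))
        yPy = yVy - float(np.atleast_1d(XVy) @ beta)
        return logdet_V + logdet_XVX + yPy


def estimate_variance_components(
    plot_table: pd.DataFrame,
    trait: str,
    *,
    genotype: str = "genotype",
    environment: str = "environment",
    replicate: str = "replicate",
    block: str = "block",
    method: str = REML,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Estimate variance components of the random-effects decomposition.

    Parameters
    ----------
    plot_table : DataFrame
        One row per plot with the trait and the design factor columns.
    trait : str
        Column to analyse. Rows with a missing trait value are dropped.
    method : str
        ``"reml"`` (default) or ``"anova_moments"`` (balanced designs).

    Raises
    ------
    ConvergenceError
        If the REML optimizer fails; the optimizer trace is attached.
    """
    table = plot_table.dropna(subset=[trait])
    if table[genotype].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    y = table[trait].to_numpy(dtype=float)
    n_env = table[environment].nunique()
    if n_env == 1:
        warnings.warn(
            "single environment: genotype-by-environment variance is not "
            "estimable and is reported as 0"
        )
    if method == ANOVA_MOMENTS:
        return _anova_moments(table, trait, genotype, environment)
    if method != REML:
        raise ValueError(f"unknown method {method!r}")

    vary = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
    terms = _random_terms(table, genotype, environment, replicate, block)
    if vary == 0.0:
        return VarianceComponents(
            0.0, 0.0, 0.0, method=REML, converged=True, terms=tuple(terms)
        )

    prob = _RemlProblem(y, terms)
    k = len(terms)
    lo, hi = np.log(vary * 1e-10), np.log(vary * 1e4)
    start = dict.fromkeys(list(terms) + ["residual"], vary / (k + 1))
    try:  # warm start from the moments estimator on balanced data
        mom = _anova_moments(table, trait, genotype, environment)
        start["genotype"] = mom.sigma_G2
        if "gxe" in start:
            start["gxe"] = mom.sigma_GE2
        start["residual"] = mom.sigma_eps2
    except ValueError:
        pass
    x0 = np.log(np.clip([start[t] for t in list(terms) + ["residual"]],
                        vary * 1e-6, None))

    def objective(logv):
        v = np.exp(np.clip(logv, lo, hi))
        return prob.neg2_restricted_loglik(v[:-1], v[-1])

    res = scipy.optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * (k + 1),
        options={"maxiter": max_iter, "ftol": tol},
    )
    n_iter = int(res.nit)
    if not res.success:
        res2 = scipy.optimize.minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": max_iter * (k + 1), "fatol": 1e-10, "xatol": 1e-8},
        )
        n_iter += int(res2.nit)
        if res2.fun <= res.fun:
            res = res2
        if not res.success and not res2.success:
            raise ConvergenceError(
                "REML did not converge", trace={"lbfgsb": res, "nelder_mead": res2}
            )
    v = np.exp(res.x)
    floor = vary * 1e-8
    v = np.where(v < floor, 0.0, v)
    got = dict(zip(list(terms) + ["residual"], v))
    return VarianceComponents(
        sigma_G2=got.get("genotype", 0.0),
        sigma_GE2=got.get("gxe", 0.0),
        sigma_eps2=got.get("residual", 0.0),
        sigma_env2=got.get("environment", 0.0),
        sigma_rep2=got.get("replicate", 0.0),
        sigma_block2=got.get("block", 0.0),
        method=REML,
        converged=True,
        n_iter=n_iter,
        loglik=-0.5 * float(res.fun),
        terms=tuple(terms),
    )


def _anova_moments(table, trait, genotype, environment) -> VarianceComponents:
    """Expected-mean-squares estimator for balanced g x e x r layouts."""
    y = table[trait].astype(float)
    g = table[genotype].astype(str)
    e = table[environment].astype(str)
    cell_counts = table.groupby([g, e], observed=True).size()
    r = int(cell_counts.iloc[0])
    n_g = g.nunique()
    n_e = e.nunique()
    if cell_counts.nunique() != 1 or len(cell_counts) != n_g * n_e:
        raise ValueError(
            "anova_moments requires a balanced design: every genotype in "
            "every environment with equal replication"
        )
    grand = y.mean()
    gm = y.groupby(g).mean()
    em = y.groupby(e).mean()
    cm = y.groupby([g, e]).mean()

    if n_e > 1 and r > 1:
        ms_g = n_e * r * float(((gm - grand) ** 2).sum()) / (n_g - 1)
        resid_cell = cm - gm.reindex(cm.index.get_level_values(0)).to_numpy() - em.reindex(
            cm.index.get_level_values(1)
        ).to_numpy() + grand
        ms_ge = r * float((resid_cell**2).sum()) / ((n_g - 1) * (n_e - 1))
        within = y - cm.reindex(pd.MultiIndex.from_arrays([g, e])).to_numpy()
        ms_err = float((within**2).sum()) / (n_g * n_e * (r - 1))
        s_eps = ms_err
        s_ge = max(0.0, (ms_ge - ms_err) / r)
        s_g = max(0.0, (ms_g - ms_ge) / (n_e * r))
    elif n_e == 1:
        if r < 2:
            raise ValueError("nothing is separable with x = 1 and r = 1")
        ms_g = r * float(((gm - grand) ** 2).sum()) / (n_g - 1)
        within = y - gm.reindex(g).to_numpy()
        ms_err = float((within**2).sum()) / (n_g * (r - 1))
        s_eps = ms_err
        s_ge = 0.0
        s_g = max(0.0, (ms_g - ms_err) / r)
    else:  # n_e > 1, r == 1: GE and error are confounded
        ms_g = n_e * float(((gm - grand) ** 2).sum()) / (n_g - 1)
        resid_cell = cm - gm.reindex(cm.index.get_level_values(0)).to_numpy() - em.reindex(
            cm.index.get_level_values(1)
        ).to_numpy() + grand
        ms_ge = float((resid_cell**2).sum()) / ((n_g - 1) * (n_e - 1))
        s_eps = ms_ge
        s_ge = 0.0
        s_g = max(0.0, (ms_g - ms_ge) / n_e)
    return VarianceComponents(
        sigma_G2=s_g,
        sigma_GE2=s_ge,
        sigma_eps2=s_eps,
        method=ANOVA_MOMENTS,
        converged=True,
        terms=("genotype", "gxe", "residual"),
    )


def broad_sense_heritability(
    components: VarianceComponents,
    x: int,
    r: int,
    trait: str = "",
) -> HeritabilityResult:
    """Entry-mean broad-sense heritability.

    ``H^2 = sigma_G^2 / (sigma_G^2 + sigma_GE^2/x + sigma_eps^2/(x*r))``
    with ``x`` environments and ``r`` replications. Nonnegative inputs keep
    the result in [0, 1] without any post-hoc clamp.
    """
    if x < 1 or r < 1:
        raise ValueError("x and r must be >= 1")
    denom = components.sigma_G2 + components.sigma_GE2 / x + components.sigma_eps2 / (x * r)
    if denom <= 0:
        raise UndefinedHeritabilityError(
            "all variance components are zero; H2 undefined"
        )
    return HeritabilityResult(
        H2=components.sigma_G2 / denom, x=x, r=r, trait=trait, components=components
    )


def adjusted_entry_means(
    plot_table: pd.DataFrame,
    trait: str,
    *,
    genotype: str = "genotype",
    environment: str = "environment",
    replicate: str = "replicate",
    block: str = "block",
) -> pd.DataFrame:
    """Per-genotype means adjusted for replicate and block effects.

    Within each environment a fixed-genotype companion model is fit by
    ordinary least squares with sum-to-zero replicate and block contrasts;
    the genotype coefficients are its adjusted means (BLUEs). Environments
    are then averaged. In a design without replicate or block structure the
    result equals the raw genotype means. Genotypes absent from an
    environment are missing there and excluded from the average.
    """
    import statsmodels.formula.api as smf

    frames = []
    for env, sub in plot_table.groupby(environment):
        sub = sub.dropna(subset=[trait]).copy()
        sub["_g"] = sub[genotype].astype(str)
        sub["_rep"] = sub[replicate].astype(str) if replicate in sub else "r1"
        sub["_blk"] = sub["_rep"] + "@" + (
            sub[block].astype(str) if block in sub else "b1"
        )
        rhs = "0 + C(_g)"
        if sub["_rep"].nunique() > 1:
            rhs += " + C(_rep, Sum)"
        if sub["_blk"].nunique() > sub["_rep"].nunique():
            rhs += " + C(_blk, Sum)"
        fit = smf.ols(f"{trait} ~ {rhs}", data=sub).fit()
        means = {
            name[len("C(_g)[") : -1]: val
            for name, val in fit.params.items()
            if name.startswith("C(_g)[")
        }
        frames.append(
            pd.DataFrame(
                {
                    genotype: list(means),
                    environment: env,
                    "adjusted_mean": list(means.values()),
                }
            )
        )
    per_env = pd.concat(frames, ignore_index=True)
    overall = (
        per_env.groupby(genotype)["adjusted_mean"].mean().rename("adjusted_mean")
    ).reset_index()
    overall["n_environments"] = per_env.groupby(genotype).size().values
    return overall
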