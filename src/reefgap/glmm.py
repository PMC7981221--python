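"""Binomial (logit) mixed model with crossed random intercepts.

The response is the binary movement label; fixed effects come from a term
set over {species, sex, log_size, diel, season} plus species interactions;
random intercepts are crossed (independent) over individual tag and
receiver.  Estimation is maximum likelihood under the Laplace
approximation: for candidate random-effect SDs, a penalized Newton
iteration finds the joint mode of (beta, u), and the profiled Laplace
log-likelihood

    ll(sigma) = pen_ll(beta_hat, u_hat)
                - 1/2 * sum_f q_f log sigma_f^2
                - 1/2 * log det(H_uu)

is maximized over log-SDs with Nelder--Mead.  With both SDs fixed at zero
the model reduces exactly to ordinary logistic regression.

Standard errors are Wald (conditional on the estimated variance
components, from the joint Hessian); conditional modes and their SDs come
from the u-block of the inverse Hessian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Baseline level of each categorical covariate (treatment coding).
BASELINES = {"species": "gray_reef", "sex": "F", "diel": "day", "season": "dry"}
CATEGORICAL = ("species", "sex", "diel", "season")
MAIN_ORDER = ("species", "sex", "log_size", "diel", "season")

DEFAULT_GLOBAL_TERMS = (
    "species", "sex", "log_size", "diel", "season",
    "species:sex", "species:log_size", "species:diel", "species:season",
)

__all__ = [
    "BASELINES",
    "MAIN_ORDER",
    "DEFAULT_GLOBAL_TERMS",
    "DesignInfo",
    "build_design",
    "FittedModel",
    "fit_glmm",
    "predict_proba",
    "canonical_terms",
]


def canonical_terms(terms) -> tuple[str, ...]:
    """Sort a term set into the fixed canonical order (mains, then interactions)."""
    terms = set(terms)
    order = list(MAIN_ORDER) + [f"species:{t}" for t in MAIN_ORDER if t != "species"]
    unknown = terms - set(order)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            if a not in terms or b not in terms:
                raise ValueError(f"interaction {t} violates marginality")
    return tuple(t for t in order if t in terms)


@dataclass(frozen=True)
class DesignInfo:
    """Fixed-effect design: term set plus frozen categorical level orders."""

    terms: tuple[str, ...]
    levels: dict = field(hash=False)
    columns: tuple[str, ...] = ()

    def matrix(self, table: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(table))]
        for term in self.terms:
            for block in self._term_blocks(term, table):
                cols.append(block)
        return np.column_stack(cols)

    def _var_block(self, var: str, table: pd.DataFrame):
        """Columns (and names) for one variable: dummies or the numeric itself."""
        if var in CATEGORICAL:
            lv = self.levels[var]
            seen = set(table[var].unique()) - set(lv)
            if seen:
                raise ValueError(f"unseen {var} levels: {sorted(seen)}")
            return [
                (f"{var}[{l}]", (table[var] == l).to_numpy(dtype=float)) for l in lv[1:]
            ]
        return [(var, table[var].to_numpy(dtype=float))]

    def _term_blocks(self, term: str, table: pd.DataFrame):
        if ":" not in term:
            return [c for _, c in self._var_block(term, table)]
        a, b = term.split(":")
        return [
            ca * cb
            for _, ca in self._var_block(a, table)
            for _, cb in self._var_block(b, table)
        ]

    def column_names(self) -> tuple[str, ...]:
        names = ["Intercept"]
        for term in self.terms:
            if ":" not in term:
                names += [n for n, _ in self._names_of(term)]
            else:
                a, b = term.split(":")
                names += [
                    f"{na}:{nb}" for na, _ in self._names_of(a) for nb, _ in self._names_of(b)
                ]
        return tuple(names)

    def _names_of(self, var):
        if var in CATEGORICAL:
            return [(f"{var}[{l}]", None) for l in self.levels[var][1:]]
        return [(var, None)]


def build_design(table: pd.DataFrame, terms) -> DesignInfo:
    """Freeze a design from data: canonical terms, baseline-first levels."""
    terms = canonical_terms(terms)
    levels = {}
    need = set()
    for t in terms:
        need.update(t.split(":"))
    for var in need & set(CATEGORICAL):
        lv = sorted(table[var].unique())
        base = BASELINES.get(var)
        if base in lv:
            lv.remove(base)
            lv.insert(0, base)
        if len(lv) < 2:
            raise ValueError(f"categorical {var!r} has a single level {lv}")
        levels[var] = lv
    return DesignInfo(terms=terms, levels=levels)


# ---------------------------------------------------------------------------
# Laplace machinery


def _pen_ll(y, eta, us, sig2):
    ll = float(y @ eta - np.logaddexp(0, eta).sum())
    for u, s2 in zip(us, sig2):
        ll -= 0.5 * float(u @ u) / s2
    return ll


def _hessian(X, w, codes, qs, sig2):
    p = X.shape[1]
    q = int(sum(qs))
    H = np.zeros((p + q, p + q))
    Xw = X * w[:, None]
    H[:p, :p] = Xw.T @ X
    offs = p + np.concatenate([[0], np.cumsum(qs)]).astype(int)
    for f, (c, qf) in enumerate(zip(codes, qs)):
        a, b = offs[f], offs[f + 1]
        dg = np.bincount(c, weights=w, minlength=qf)
        H[a:b, a:b] = np.diag(dg + 1.0 / sig2[f])
        XtWZ = np.vstack([np.bincount(c, weights=w * X[:, j], minlength=qf) for j in range(p)])
        H[:p, a:b] = XtWZ
        H[a:b, :p] = XtWZ.T
    for f in range(len(codes)):
        for g in range(f + 1, len(codes)):
            M = np.zeros((qs[f], qs[g]))
            np.add.at(M, (codes[f], codes[g]), w)
            H[offs[f]:offs[f + 1], offs[g]:offs[g + 1]] = M
            H[offs[g]:offs[g + 1], offs[f]:offs[f + 1]] = M.T
    return H


def _joint_mode(y, X, codes, qs, sig2, theta0, tol=1e-8, max_iter=60):
    """Penalized Newton to the joint (beta, u) mode. Returns (theta, pen_ll, ok)."""
    p = X.shape[1]
    offs = p + np.concatenate([[0], np.cumsum(qs)]).astype(int)

    def eta_of(th):
        eta = X @ th[:p]
        for f, c in enumerate(codes):
            eta = eta + th[offs[f]:offs[f + 1]][c]
        return eta

    th = theta0.copy()
    eta = eta_of(th)
    us = [th[offs[f]:offs[f + 1]] for f in range(len(codes))]
    pll = _pen_ll(y, eta, us, sig2)
    ok = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        r = y - mu
        grad = np.empty(th.size)
        grad[:p] = X.T @ r
        for f, (c, qf) in enumerate(zip(codes, qs)):
            grad[offs[f]:offs[f + 1]] = (
                np.bincount(c, weights=r, minlength=qf) - th[offs[f]:offs[f + 1]] / sig2[f]
            )
        if np.max(np.abs(grad)) < tol * max(1.0, len(y) / 1000.0):
            ok = True
            break
        H = _hessian(X, w, codes, qs, sig2)
        try:
            delta = cho_solve(cho_factor(H, lower=True), grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = 1.0
        while step > 1e-6:
            cand = th + step * delta
            eta_c = eta_of(cand)
            pll_c = _pen_ll(y, eta_c, [cand[offs[f]:offs[f + 1]] for f in range(len(codes))], sig2)
            if pll_c >= pll - 1e-10:
                th, eta, pll = cand, eta_c, pll_c
                break
            step *= 0.5
        else:
            break
    return th, pll, ok


def _laplace_nll(y, X, codes, qs, sig2, theta0):
    th, pll, ok = _joint_mode(y, X, codes, qs, sig2, theta0)
    p = X.shape[1]
    mu = expit(
        X @ th[:p]
        + sum(
            th[p + int(sum(qs[:f])):p + int(sum(qs[: f + 1]))][codes[f]]
            for f in range(len(codes))
        )
    )
    w = np.maximum(mu * (1 - mu), 1e-10)
    H = _hessian(X, w, codes, qs, sig2)
    ll = pll
    if sum(qs):
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        ll -= 0.5 * logdet
        for qf, s2 in zip(qs, sig2):
            ll -= 0.5 * qf * np.log(s2)
    return -ll, th, H, ok


@dataclass
class FittedModel:
    """A fitted binomial mixed model.

    ``sigma2`` maps factor name to the variance component (logit scale);
    ``cond_modes`` maps factor name to a DataFrame of per-level empirical-
    Bayes modes and conditional SDs.
    """

    terms: tuple[str, ...]
    design: DesignInfo
    coef: pd.DataFrame  # index: coefficient name; Estimate, SE, ci_lo, ci_hi, z, p
    factors: tuple[str, ...]
    sigma2: dict
    cond_modes: dict
    loglik: float
    k: int
    n: int
    converged: bool
    flags: tuple[str, ...] = ()
    fitted_prob: np.ndarray | None = None
    y: np.ndarray | None = None
    var_fixed: float = float("nan")

    @property
    def aicc(self) -> float:
        k, n = self.k, self.n
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def beta(self) -> pd.Series:
        return self.coef["Estimate"]


def fit_glmm(
    table: pd.DataFrame,
    terms=DEFAULT_GLOBAL_TERMS,
    re_factors=("tag_id", "receiver_id"),
    response: str = "label",
    design: DesignInfo | None = None,
    sigma0=None,
    fix_sigma: dict | None = None,
    ci_z: float = 1.96,
) -> FittedModel:
    """Fit the binomial-logit mixed model by Laplace maximum likelihood.

    Parameters
    ----------
    table : modelling table (one row per movement).
    terms : fixed-effect term set; the intercept is always included.
    re_factors : grouping columns receiving independent random intercepts.
    design : optional frozen design (reused across dredge candidates).
    sigma0 : optional starting SD per random factor (warm start).
    fix_sigma : map factor -> fixed SD; a factor fixed at 0 is dropped,
        so ``{"tag_id": 0, "receiver_id": 0}`` reproduces plain logistic
        regression.
    """
    if design is None:
        design = build_design(table, terms)
    y = table[response].to_numpy(dtype=float)
    flags = []
    fix_sigma = fix_sigma or {}
    active = [f for f in re_factors if fix_sigma.get(f, None) != 0]
    X = design.matrix(table)
    names = list(design.column_names())
    p = X.shape[1]
    n = len(y)

    levels = {f: np.unique(table[f].to_numpy()) for f in active}
    codes = [pd.Categorical(table[f], categories=levels[f]).codes.astype(np.int64) for f in active]
    qs = [len(levels[f]) for f in active]
    for f, qf in zip(active, qs):
        if qf < 2:
            raise ValueError(f"random factor {f!r} has fewer than 2 levels")

    if y.min() == y.max():
        logger.warning("response is single-class: complete separation, fit flagged degenerate")
        nanrow = np.full(p, np.nan)
        coef = pd.DataFrame(
            {"Estimate": nanrow, "SE": nanrow, "ci_lo": nanrow, "ci_hi": nanrow,
             "z": nanrow, "p": nanrow}, index=names)
        return FittedModel(design.terms, design, coef, tuple(active),
                           {f: np.nan for f in active}, {}, float("nan"),
                           p + len(active), n, False, ("separation",))

    theta0 = np.zeros(p + int(sum(qs)))
    theta0[0] = np.log(y.mean() / (1 - y.mean()))

    free = [f for f in active if f not in fix_sigma]
    fixed_vals = {f: float(fix_sigma[f]) for f in active if f in fix_sigma}

    state = {"theta": theta0}

    def sig2_of(x):
        s = []
        i = 0
        for f in active:
            if f in fixed_vals:
                s.append(max(fixed_vals[f], 1e-6) ** 2)
            else:
                s.append(float(np.exp(2 * np.clip(x[i], -8, 4))))
                i += 1
        return s

    if free:
        if sigma0 is None:
            x0 = np.full(len(free), np.log(0.5))
        else:
            x0 = np.log(np.maximum([sigma0[f] for f in free], 1e-3))

        def obj(x):
            nll, th, _, _ = _laplace_nll(y, X, codes, qs, sig2_of(x), state["theta"])
            state["theta"] = th
            return nll

        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxfev": 250})
        xhat = res.x
        if not res.success:
            flags.append("outer-nonconverged")
    else:
        xhat = np.empty(0)

    sig2 = sig2_of(xhat)
    nll, th, H, ok = _laplace_nll(y, X, codes, qs, sig2, state["theta"])
    if not ok:
        flags.append("inner-nonconverged")
    loglik = -nll

    try:
        cov = cho_solve(cho_factor(H, lower=True), np.eye(H.shape[0]))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        flags.append("singular-hessian")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    beta = th[:p]
    zval = np.divide(beta, se[:p], out=np.full(p, np.nan), where=se[:p] > 0)
    pval = 2 * norm.sf(np.abs(zval))
    coef = pd.DataFrame(
        {
            "Estimate": beta,
            "SE": se[:p],
            "ci_lo": beta - ci_z * se[:p],
            "ci_hi": beta + ci_z * se[:p],
            "z": zval,
            "p": pval,
        },
        index=names,
    )

    sigma2 = {}
    cond = {}
    off = p
    for f, qf in zip(active, qs):
        sigma2[f] = sig2[active.index(f)]
        cond[f] = pd.DataFrame(
            {"level": levels[f], "mode": th[off:off + qf], "sd": se[off:off + qf]}
        )
        off += qf

    eta = X @ beta
    var_fixed = float(np.var(eta, ddof=0))
    for f, c in zip(range(len(codes)), codes):
        eta = eta + th[p + int(sum(qs[:f])):p + int(sum(qs[:f + 1]))][c]

    k = p + len(free)  # fixed coefficients + estimated variance components
    converged = not any("nonconverged" in fl for fl in flags)
    return FittedModel(
        terms=design.terms,
        design=design,
        coef=coef,
        factors=tuple(active),
        sigma2=sigma2,
        cond_modes=cond,
        loglik=loglik,
        k=k,
        n=n,
        converged=converged,
        flags=tuple(flags),
        fitted_prob=expit(eta),
        y=y,
        var_fixed=var_fixed,
    )


def predict_proba(fitted: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Predicted out-of-range probability for new rows.

    Grouping levels unseen in training contribute zero random effect
    (population-level prediction).
    """
    X = fitted.design.matrix(table)
    eta = X @ fitted.beta.to_numpy()
    for f in fitted.factors:
        cm = fitted.cond_modes[f]
        lut = dict(zip(cm["level"], cm["mode"]))
        eta = eta + table[f].map(lut).fillna(0.0).to_numpy()
    return expit(eta)
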