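"""Multimodel inference on the drivers of out-of-range movement.

The global binomial GLMM is dredged: every marginality-respecting subset
of its fixed-effect terms is fitted (random intercepts always retained),
candidates are ranked by AICc, models that are more complex versions of a
better-scoring model are removed, and the survivor is reported — or, if
several survive and the best Akaike weight is below 0.9, coefficients are
model-averaged (full, zero-substitution averaging with unconditional
standard errors).  Supporting statistics: VIF collinearity gate,
Nakagawa marginal/conditional R², conditional modes of the random
intercepts, cross-validated AUC, and a numeric residual report.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.tsa.stattools import acf as _acf

from .glmm import (
    BASELINES,
    DEFAULT_GLOBAL_TERMS,
    FittedModel,
    canonical_terms,
    fit_glmm,
    predict_proba,
)

logger = logging.getLogger(__name__)

VIF_GATE = 5.0

__all__ = [
    "vif",
    "enumerate_term_sets",
    "ModelSet",
    "dredge",
    "remove_nested",
    "SelectionResult",
    "select_or_average",
    "nakagawa_r2",
    "conditional_modes",
    "crossval_auc",
    "residual_diagnostics",
]


def vif(table: pd.DataFrame, predictors=("species", "sex", "log_size", "diel", "season")) -> pd.DataFrame:
    """Variance inflation factor per fixed-effect predictor column.

    Categorical predictors enter as treatment-coded indicators.  VIF_j =
    1/(1-R²_j), R²_j from regressing column j on the others plus an
    intercept.  The ``gate`` column flags columns exceeding the critical
    threshold of 5.0; perfect collinearity reports ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    cols, names = [], []
    for pvar in predictors:
        s = table[pvar]
        if s.dtype.kind in "ifu":
            names.append(pvar)
            cols.append(s.to_numpy(dtype=float))
        else:
            lv = sorted(s.unique())
            base = BASELINES.get(pvar)
            if base in lv:
                lv.remove(base)
                lv.insert(0, base)
            for level in lv[1:]:
                names.append(f"{pvar}[{level}]")
                cols.append((s == level).to_numpy(dtype=float))
    M = np.column_stack(cols)
    rows = []
    for j, name in enumerate(names):
        yj = M[:, j]
        others = np.column_stack([np.ones(len(yj)), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 0.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
        v = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append((name, v, v > VIF_GATE))
    out = pd.DataFrame(rows, columns=["predictor", "vif", "gate"])
    if out["gate"].any():
        logger.warning("VIF gate failed for: %s", out.loc[out["gate"], "predictor"].tolist())
    return out


def enumerate_term_sets(global_terms=DEFAULT_GLOBAL_TERMS) -> list[tuple[str, ...]]:
    """All marginality-respecting subsets of the global fixed-effect terms.

    An interaction may only appear together with both of its main effects.
    The intercept-only model (empty tuple) is always included.
    """
    terms = list(canonical_terms(global_terms))
    subsets = []
    for r in range(len(terms) + 1):
        for comb in itertools.combinations(terms, r):
            s = set(comb)
            if all(set(t.split(":")) <= s for t in comb if ":" in t):
                subsets.append(canonical_terms(comb))
    return subsets


@dataclass
class ModelSet:
    """Fitted candidates with their AICc ranking.

    ``table`` columns: terms, k, loglik, AICc, delta, weight — sorted by
    AICc ascending; ``models`` aligns with ``table`` rows.
    """

    models: list[FittedModel]
    table: pd.DataFrame

    @classmethod
    def from_models(cls, models: list[FittedModel]) -> "ModelSet":
        rows = pd.DataFrame(
            {
                "terms": [" + ".join(m.terms) if m.terms else "1" for m in models],
                "k": [m.k for m in models],
                "loglik": [m.loglik for m in models],
                "AICc": [m.aicc for m in models],
            }
        )
        order = np.argsort(rows["AICc"].to_numpy(), kind="stable")
        rows = rows.iloc[order].reset_index(drop=True)
        models = [models[i] for i in order]
        rows["delta"] = rows["AICc"] - rows["AICc"].iloc[0]
        w = np.exp(-0.5 * rows["delta"].to_numpy())
        rows["weight"] = w / w.sum()
        return cls(models=models, table=rows)


def dredge(
    table: pd.DataFrame,
    global_terms=DEFAULT_GLOBAL_TERMS,
    re_factors=("tag_id", "receiver_id"),
    global_fit: FittedModel | None = None,
) -> ModelSet:
    """Fit every marginality-respecting subset of the global model.

    Random intercepts are always retained.  Non-converged candidates are
    excluded from the ranking with a warning.  Variance components of the
    global fit warm-start each candidate.
    """
    if global_fit is None:
        global_fit = fit_glmm(table, global_terms, re_factors)
    if not global_fit.converged:
        raise RuntimeError("global model did not converge")
    sigma0 = {f: float(np.sqrt(s2)) for f, s2 in global_fit.sigma2.items()}
    fits = []
    for terms in enumerate_term_sets(global_terms):
        if terms == global_fit.terms:
            m = global_fit
        else:
            m = fit_glmm(table, terms, re_factors, sigma0=sigma0)
        if m.converged:
            fits.append(m)
        else:
            logger.warning("dredge: dropping non-converged candidate %s (%s)", terms, m.flags)
    return ModelSet.from_models(fits)


def remove_nested(model_set: ModelSet) -> ModelSet:
    """Drop models whose terms strictly contain a better-ranked model's terms."""
    keep = []
    for i, mi in enumerate(model_set.models):
        ti = set(mi.terms)
        ai = model_set.table["AICc"].iloc[i]
        nested = any(
            set(mj.terms) < ti and model_set.table["AICc"].iloc[j] < ai
            for j, mj in enumerate(model_set.models)
        )
        if not nested:
            keep.append(mi)
    return ModelSet.from_models(keep)


@dataclass
class SelectionResult:
    """Outcome of the selection rule.

    ``kind`` is "single" (one survivor), "best" (top weight >= threshold)
    or "averaged" (full model averaging); ``coef`` mirrors the coefficient
    table; ``model`` is the reported fit (best model when averaging, for
    variance components / prediction).
    """

    kind: str
    model: FittedModel
    coef: pd.DataFrame
    model_set: ModelSet


def select_or_average(model_set: ModelSet, weight_threshold: float = 0.9,
                      ci_z: float = 1.96) -> SelectionResult:
    """Apply the selection rule to a nested-pruned model set."""
    if not model_set.models:
        raise ValueError("empty model set")
    best = model_set.models[0]
    if len(model_set.models) == 1:
        return SelectionResult("single", best, best.coef, model_set)
    if model_set.table["weight"].iloc[0] >= weight_threshold:
        return SelectionResult("best", best, best.coef, model_set)
    # full (zero-substitution) averaging with unconditional SEs
    names: list[str] = []
    for m in model_set.models:
        for nm in m.coef.index:
            if nm not in names:
                names.append(nm)
    w = model_set.table["weight"].to_numpy()
    est = np.zeros(len(names))
    se = np.zeros(len(names))
    B = np.zeros((len(model_set.models), len(names)))
    S = np.zeros_like(B)
    for i, m in enumerate(model_set.models):
        for nm in m.coef.index:
            j = names.index(nm)
            B[i, j] = m.coef.at[nm, "Estimate"]
            S[i, j] = m.coef.at[nm, "SE"]
    est = w @ B
    se = np.sqrt(w @ (S**2 + (B - est) ** 2))
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    coef = pd.DataFrame(
        {
            "Estimate": est,
            "SE": se,
            "ci_lo": est - ci_z * se,
            "ci_hi": est + ci_z * se,
            "z": z,
            "p": 2 * norm.sf(np.abs(z)),
        },
        index=names,
    )
    return SelectionResult("averaged", best, coef, model_set)


def nakagawa_r2(fitted: FittedModel) -> tuple[float, float]:
    """Marginal and conditional R² for the binomial-logit mixed model.

    R²m = σ²_f / (σ²_f + Σσ²_re + π²/3); R²c adds the random-intercept
    variances to the numerator.  σ²_f is the variance of the fixed-effect
    linear predictor over the modelled data.
    """
    s_f = fitted.var_fixed
    s_re = float(sum(fitted.sigma2.values()))
    denom = s_f + s_re + np.pi**2 / 3
    return s_f / denom, (s_f + s_re) / denom


def conditional_modes(
    fitted: FittedModel,
    individuals: pd.DataFrame | None = None,
    ci_z: float = 1.96,
) -> dict:
    """Per-level empirical-Bayes modes with CIs and significance fractions.

    Returns ``{"modes": {factor: DataFrame}, "fraction_significant":
    {...}}``; a level is significant when its CI (mode ± 1.96 SD) excludes
    zero.  When ``individuals`` is given, tag-level fractions are reported
    per species.
    """
    modes = {}
    frac = {}
    for f, cm in fitted.cond_modes.items():
        df = cm.copy()
        df["ci_lo"] = df["mode"] - ci_z * df["sd"]
        df["ci_hi"] = df["mode"] + ci_z * df["sd"]
        df["significant"] = (df["ci_lo"] > 0) | (df["ci_hi"] < 0)
        modes[f] = df
        frac[f] = float(df["significant"].mean())
    out = {"modes": modes, "fraction_significant": frac}
    if individuals is not None and "tag_id" in modes:
        sp = individuals.set_index("tag_id")["species"]
        df = modes["tag_id"].copy()
        df["species"] = df["level"].map(sp)
        out["fraction_significant_by_species"] = (
            df.groupby("species")["significant"].mean().to_dict()
        )
    return out


def crossval_auc(
    table: pd.DataFrame,
    terms,
    re_factors=("tag_id", "receiver_id"),
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: str = "species",
) -> float:
    """AUC of held-out predicted probabilities under a seeded 80/20 split.

    The split is movement-level, stratified by species; the model is
    refitted on the training fraction and evaluated on the held-out rows
    (unseen grouping levels predict at the population level).
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    test_mask = np.zeros(n, dtype=bool)
    if stratify in table.columns:
        groups = table.groupby(stratify, sort=True).indices.values()
    else:
        groups = [np.arange(n)]
    for idx in groups:
        idx = np.asarray(idx)
        perm = rng.permutation(idx)
        n_test = int(round(len(idx) * (1 - train_fraction)))
        test_mask[perm[:n_test]] = True
    train, test = table[~test_mask], table[test_mask]
    if test["label"].nunique() < 2:
        raise ValueError("held-out split lacks both classes; cannot compute AUC")
    fit = fit_glmm(train, terms, re_factors)
    prob = predict_proba(fit, test)
    return float(roc_auc_score(test["label"].to_numpy(), prob))


def residual_diagnostics(fitted: FittedModel, n_lags: int = 20, n_bins: int = 10) -> dict:
    """Numeric residual report: autocorrelation and spread vs fitted.

    Pearson residuals in data order; ``acf`` gives lags 1..n_lags with the
    2/sqrt(n) white-noise band; ``spread`` summarises residual SD across
    fitted-probability bins (max/min ratio as a heteroscedasticity hint).
    Advisory only — never gates the pipeline.
    """
    mu = fitted.fitted_prob
    y = fitted.y
    resid = (y - mu) / np.sqrt(np.maximum(mu * (1 - mu), 1e-12))
    ac = _acf(resid, nlags=n_lags, fft=True)[1:]
    band = 2.0 / np.sqrt(len(resid))
    bins = np.quantile(mu, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(bins, mu, side="right") - 1, 0, n_bins - 1)
    sds = np.array([resid[which == b].std() for b in range(n_bins) if (which == b).sum() > 1])
    return {
        "acf": ac,
        "white_noise_band": band,
        "frac_acf_within_band": float(np.mean(np.abs(ac) < band)),
        "lag1_acf": float(ac[0]),
        "spread_sd_by_fitted_bin": sds,
        "spread_ratio": float(sds.max() / sds.min()) if len(sds) else float("nan"),
    }
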