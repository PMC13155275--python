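"""Phenotypic association battery between smoking and striatal iron.

The stage order mirrors the study procedure: impute missing covariates
(group mean / mode), exclude brain-trait outliers beyond k = 5 unscaled
median absolute deviations, log-transform skewed variables (pack-years,
deprivation index), residualise brain traits and smoking variables on the
covariates ("de-confounding"), rank-based inverse-normal transform the
continuous variables, then fit the 6 smoking contrasts x 12 brain traits
OLS grid with Benjamini-Hochberg FDR across the 72 tests.  A one-sided
z-test compares left and right hemisphere coefficients, and robustness of
sensitivity re-runs is summarised by the Pearson correlation of betas and
the Jaccard index of the significant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import BRAIN_TRAITS

log = logging.getLogger("ironsmoke")

SMOKING_VARS = [
    "ever_smoked", "currently_smoking", "current_vs_never",
    "current_vs_former", "former_vs_never", "pack_years",
]

DEFAULT_COVARIATES = [
    "age", "sex", "townsend", "income", "education", "alcohol",
    "sbp", "dbp", "bmi",
]

CATEGORICAL_COVARIATES = {"income", "education", "alcohol", "sex"}


@dataclass
class AssociationResult:
    trait: str
    predictor: str
    beta: float
    se: float
    pval: float
    n_used: int
    qval: float = np.nan


@dataclass
class RobustnessMetrics:
    beta_correlation: float
    jaccard: float


# ---------------------------------------------------------------------------
# cleaning / transforms
# ---------------------------------------------------------------------------

def impute_missing(table: pd.DataFrame, columns: list[str],
                   categorical: set[str] | None = None) -> pd.DataFrame:
    """Replace missing values with the group mean (continuous) or mode
    (categorical, ties broken by first level in sorted order)."""
    categorical = CATEGORICAL_COVARIATES if categorical is None else categorical
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in table")
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        n_miss = int(vals.isna().sum())
        if n_miss == 0:
            continue
        if col in categorical or vals.dtype == object:
            counts = vals.dropna().value_counts()
            top = counts[counts == counts.max()].index
            fill = sorted(top)[0]
        else:
            fill = vals.mean()
        out[col] = vals.fillna(fill)
        log.info("impute_missing: %s <- %r (%d values)", col, fill, n_miss)
    return out


def mad_filter(values: np.ndarray | pd.Series, k: float = 5.0) -> np.ndarray:
    """Keep mask: |x - median| <= k * MAD with raw (unscaled) MAD.

    When MAD = 0 only exact-median values are kept.  Missing values are
    kept (they carry no outlier information).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    keep = np.ones_like(x, dtype=bool)
    if mad == 0:
        keep[finite] = x[finite] == med
    else:
        keep[finite] = np.abs(x[finite] - med) <= k * mad
    return keep


def log_transform(values: np.ndarray | pd.Series, shift: float | None = None
                  ) -> np.ndarray:
    """y = ln(x + s).

    ``shift=None`` chooses s automatically: 1 when min(x) >= 0 (pack-years
    style, zeros allowed), else 1 - min(x) (deprivation-index style with
    negative support), so the minimum maps to ln(1) = 0.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if shift is None:
        mn = x[finite].min()
        shift = 1.0 if mn >= 0 else 1.0 - mn
    y = np.full_like(x, np.nan)
    y[finite] = np.log(x[finite] + shift)
    if not np.isfinite(y[finite]).all():
        raise ValueError("non-finite values after log transform")
    return y


def pack_years(cigs_per_day, years_smoked):
    """Lifetime dose: cigarettes/day / 20 x years smoked."""
    c = np.asarray(cigs_per_day, dtype=float)
    y = np.asarray(years_smoked, dtype=float)
    if (c < 0).any() or (y < 0).any():
        raise ValueError("inputs must be non-negative")
    return c / 20.0 * y


def deconfound(y: np.ndarray | pd.Series, covariates: pd.DataFrame | np.ndarray
               ) -> np.ndarray:
    """OLS residuals of y on [1, covariates]; NaNs in y propagate.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = pd.DataFrame(covariates).copy()
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p + 1:
        raise ValueError("need more rows than covariates")
    D = np.column_stack([np.ones(n), Xv])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns via incremental QR rank
        collinear = []
        kept = [np.ones(n)]
        for j, name in enumerate(names):
            trial = np.column_stack(kept + [Xv[:, j]])
            if np.linalg.matrix_rank(trial) == len(kept):
                collinear.append(str(name))
            else:
                kept.append(Xv[:, j])
        raise ValueError(f"collinear covariate column(s): {', '.join(collinear)}")
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(yv)
    coef, *_ = np.linalg.lstsq(D[ok], yv[ok], rcond=None)
    resid = np.full_like(yv, np.nan)
    resid[ok] = yv[ok] - D[ok] @ coef
    return resid


def int_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets, then z-score.

    x -> Phi^-1((rank - 3/8) / (n + 1/4)) with average ranks for ties,
    rescaled to mean 0 and SD 1.  NaNs propagate.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    v = x[finite]
    if np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct values")
    ranks = stats.rankdata(v, method="average")
    q = stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))
    q = (q - q.mean()) / q.std()
    out = np.full_like(x, np.nan)
    out[finite] = q
    return out


# ---------------------------------------------------------------------------
# regression battery
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS with intercept; returns (coef, se, p, n) excluding the intercept row."""
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    yv, Xv = y[ok], X[ok]
    n = len(yv)
    D = np.column_stack([np.ones(n), Xv])
    p = D.shape[1]
    if n <= p:
        raise ValueError("too few observations for regression")
    coef, _, _, _ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ coef
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), df=n - p)
    return coef[1:], se[1:], pv[1:], n


def _contrast(status: pd.Series, var: str) -> tuple[np.ndarray, np.ndarray]:
    """(subset mask, 0/1 predictor) for a smoking-status contrast."""
    s = status.to_numpy()
    if var == "ever_smoked":
        return np.ones(len(s), bool), (s != "never").astype(float)
    if var == "currently_smoking":
        return np.ones(len(s), bool), (s == "current").astype(float)
    if var == "current_vs_never":
        return s != "former", (s == "current").astype(float)
    if var == "current_vs_former":
        return s != "never", (s == "current").astype(float)
    if var == "former_vs_never":
        return s != "current", (s == "former").astype(float)
    raise KeyError(f"unknown smoking contrast {var!r}")


def prepare_table(table: pd.DataFrame, covariates: list[str] | None = None,
                  mad_k: float = 5.0, traits: list[str] | None = None
                  ) -> pd.DataFrame:
    """Run imputation, outlier exclusion, transforms, de-confounding and INT.

    Returns a copy of the table with prepared analysis columns: each brain
    trait replaced by its residualised + INT version, plus ``pack_years_int``
    and ``cessation_years_int``, and smoking contrasts residualised on the
    same covariates (columns ``resid_<var>``).
    """
    covariates = covariates or [c for c in DEFAULT_COVARIATES if c in table.columns]
    covariates = covariates + [c for c in table.columns if c.startswith("img")]
    traits = traits or [t for t in BRAIN_TRAITS if t in table.columns]
    out = impute_missing(table, covariates)

    # covariate design: flat additive set plus age^2 and age x sex terms
    X = out[covariates].astype(float).copy()
    if "age" in X and "sex" in X:
        X["age2"] = X["age"] ** 2
        X["age_x_sex"] = X["age"] * X["sex"]
    if "townsend" in X:
        X["townsend"] = log_transform(X["townsend"])

    for t in traits:
        keep = mad_filter(out[t].to_numpy(), k=mad_k)
        n_out = int((~keep).sum())
        if n_out:
            log.info("prepare_table: %s: excluded %d outlier(s)", t, n_out)
            out.loc[~keep, t] = np.nan
        out[t] = int_transform(deconfound(out[t], X))

    if "pack_years" in out.columns:
        lpy = log_transform(out["pack_years"].to_numpy(), shift=1.0)
        out["pack_years_int"] = int_transform(deconfound(lpy, X))
    if "cessation_years" in out.columns and out["cessation_years"].notna().sum() >= 3:
        out["cessation_years_int"] = int_transform(
            deconfound(out["cessation_years"].to_numpy(), X))
    for var in SMOKING_VARS[:-1]:
        _, x = _contrast(out["smoking_status"], var)
        out[f"resid_{var}"] = deconfound(x, X)
    return out


def fit_association(prepared: pd.DataFrame, trait: str, smoking_var: str,
                    interaction: str | None = None) -> list[AssociationResult]:
    """OLS of a prepared brain trait on one smoking predictor.

    Binary contrasts use the de-confounded 0/1 indicator restricted to the
    contrast subset; ``pack_years`` uses the INT-transformed de-confounded
    dose among ever smokers.  ``interaction`` in {"sex", "age"} adds the
    moderator and the product term and returns its row too.
    """
    y = prepared[trait].to_numpy(float)
    if smoking_var == "pack_years":
        mask = (prepared["smoking_status"] != "never").to_numpy()
        x = prepared["pack_years_int"].to_numpy(float)
    else:
        mask, _ = _contrast(prepared["smoking_status"], smoking_var)
        x = prepared[f"resid_{smoking_var}"].to_numpy(float)
    if not mask.any():
        raise ValueError(f"empty contrast subset for {smoking_var!r}")
    y, x = y[mask], x[mask]
    if interaction is None:
        beta, se, pv, n = _ols(y, x[:, None])
        return [AssociationResult(trait, smoking_var, beta[0], se[0], pv[0], n)]
    mod = prepared.loc[mask, interaction].to_numpy(float)
    mod = mod - np.nanmean(mod)
    X = np.column_stack([x, mod, x * mod])
    beta, se, pv, n = _ols(y, X)
    return [
        AssociationResult(trait, smoking_var, beta[0], se[0], pv[0], n),
        AssociationResult(trait, f"{smoking_var}:{interaction}", beta[2], se[2], pv[2], n),
    ]


def former_smoker_model(prepared: pd.DataFrame, trait: str) -> list[AssociationResult]:
    """Cessation-years + pack-years + interaction model among former smokers."""
    mask = (prepared["smoking_status"] == "former").to_numpy()
    if mask.sum() < 50:
        log.warning("former_smoker_model: only %d former smokers", int(mask.sum()))
    y = prepared.loc[mask, trait].to_numpy(float)
    c = prepared.loc[mask, "cessation_years_int"].to_numpy(float)
    p = prepared.loc[mask, "pack_years_int"].to_numpy(float)
    X = np.column_stack([c, p, c * p])
    beta, se, pv, n = _ols(y, X)
    names = ["cessation_years", "pack_years", "cessation_years:pack_years"]
    return [AssociationResult(trait, nm, beta[i], se[i], pv[i], n)
            for i, nm in enumerate(names)]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def asymmetry_z(beta_l: float, se_l: float, beta_r: float, se_r: float
                ) -> tuple[float, float]:
    """One-sided z-test comparing left and right hemisphere coefficients.

    z = (bL - bR)/sqrt(seL^2 + seR^2); p is the upper-tail normal
    probability.  The L-R error covariance is ignored (not available from
    summary output); see the methods note for the implied limitation.
    """
    if se_l <= 0 or se_r <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_l - beta_r) / np.sqrt(se_l ** 2 + se_r ** 2)
    return float(z), float(stats.norm.sf(z))


def association_battery(table: pd.DataFrame, mad_k: float = 5.0,
                        alpha: float = 0.05,
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """Full 6 x 12 battery with FDR over the 72 main-effect tests."""
    prepared = prepare_table(table, covariates=covariates, mad_k=mad_k)
    traits = [t for t in BRAIN_TRAITS if t in table.columns]
    rows = []
    for trait in traits:
        for var in SMOKING_VARS:
            res = fit_association(prepared, trait, var)[0]
            rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["qval"] = bh_fdr(df["pval"])
    df["significant"] = df["qval"] < alpha
    return df


def robustness(res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05
               ) -> RobustnessMetrics:
    """Pearson r of betas + Jaccard of the q<alpha sets between two runs."""
    key = ["trait", "predictor"]
    a = res_a.set_index(key).sort_index()
    b = res_b.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("result tables are not aligned on (trait, predictor)")
    r = float(np.corrcoef(a["beta"], b["beta"])[0, 1])
    sig_a = set(a.index[a["qval"] < alpha])
    sig_b = set(b.index[b["qval"] < alpha])
    union = sig_a | sig_b
    jac = np.nan if not union else len(sig_a & sig_b) / len(union)
    return RobustnessMetrics(beta_correlation=r, jaccard=jac)
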