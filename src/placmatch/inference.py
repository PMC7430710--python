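"""Statistical layer: exact binomial CI, RFM logistic model, group tests.

The central model is a binomial logistic regression of RFM status on the
MHC compatibility categories, with the incompatible (NC) category of each
class as the referent and MC and FC collapsed into a single "MC + FC"
indicator per class (five parameters in all: intercept + 2 x 2 indicators).
The fit is maximum likelihood by IRLS (statsmodels GLM/Binomial), standard
errors come from the observed information, and confidence intervals are
Wald intervals exponentiated onto the odds-ratio scale. The result object
carries the usual deviance-based summary statistics and four pseudo-R^2
measures (McFadden, Cox-Snell, Nagelkerke, Tjur).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import SeparationError, ValidationError

__all__ = [
    "BinomialCI",
    "LogisticModelResult",
    "TTestResult",
    "MWUResult",
    "clopper_pearson",
    "fit_logistic",
    "fit_rfm_logistic",
    "pseudo_r2_from_deviances",
    "students_t_test",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class BinomialCI:
    """Exact (Clopper-Pearson) binomial proportion confidence interval."""

    successes: int
    n: int
    point: float
    lower: float
    upper: float
    level: float


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Clopper-Pearson interval from Beta distribution quantiles.

    lower = Beta(x, n-x+1) quantile at (1-level)/2 (0 when x = 0);
    upper = Beta(x+1, n-x) quantile at 1-(1-level)/2 (1 when x = n).
    """
    if not (0 < level < 1):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if n < 1 or not (0 <= x <= n):
        raise ValidationError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(st.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(st.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCI(x, n, x / n, lower, upper, level)


@dataclass
class LogisticModelResult:
    """Fitted logistic model: per-term estimates plus deviance-based summary."""

    terms: pd.DataFrame  # index term; columns estimate, se, OR, ci_lower, ci_upper, p
    n: int
    loglik: float
    loglik_null: float
    deviance_model: float
    deviance_null: float
    df_residual: int
    df_null: int
    aic: float
    bic: float
    lr_chi2: float
    lr_p: float
    mcfadden_r2: float
    cox_snell_r2: float
    nagelkerke_r2: float
    tjur_r: float
    fitted: np.ndarray = field(repr=False)

    def summary(self) -> str:
        lines = ["Logistic regression of RFM status", ""]
        lines.append(
            self.terms.to_string(
                float_format=lambda v: f"{v:.4f}", columns=list(self.terms.columns)
            )
        )
        lines.append("")
        lines.append(
            f"n = {self.n}; deviance {self.deviance_model:.2f} (null {self.deviance_null:.2f}); "
            f"df {self.df_residual} (null {self.df_null}); AIC {self.aic:.2f}; BIC {self.bic:.2f}"
        )
        lines.append(
            f"LR chi2 = {self.lr_chi2:.2f} (p = {self.lr_p:.3f}); "
            f"McFadden R2 {self.mcfadden_r2:.3f}; Cox-Snell R2 {self.cox_snell_r2:.3f}; "
            f"Nagelkerke R2 {self.nagelkerke_r2:.3f}; Tjur R {self.tjur_r:.3f}"
        )
        return "\n".join(lines)


def fit_logistic(y: np.ndarray, X: pd.DataFrame, level: float = 0.95) -> LogisticModelResult:
    """Maximum-likelihood binomial logistic fit with Wald odds-ratio CIs.

    ``X`` must contain an intercept column. Degenerate outcomes (one class
    only) and diverging estimates raise ``SeparationError``; a rank-deficient
    design raises ``ValidationError``.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    n = len(y)
    if n != len(X):
        raise ValidationError("outcome and design lengths differ")
    if y.sum() == 0 or y.sum() == n:
        raise SeparationError("degenerate outcome: only one class observed")
    Xm = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValidationError("collinear design matrix (rank deficient)")

    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.GLM(y, Xm, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
        raise SeparationError("diverging estimates: complete or quasi-separation")

    se = np.asarray(fit.bse, dtype=float)
    z = st.norm.ppf(0.5 + level / 2)
    terms = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "OR": np.exp(params),
            "ci_lower": np.exp(params - z * se),
            "ci_upper": np.exp(params + z * se),
            "p": 2 * st.norm.sf(np.abs(params / se)),
        },
        index=list(X.columns),
    )

    k = Xm.shape[1]
    ll = float(fit.llf)
    null_fit = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
    ll0 = float(null_fit.llf)
    dev, dev0 = -2.0 * ll, -2.0 * ll0
    lr = dev0 - dev
    lr_p = float(st.chi2.sf(lr, k - 1)) if k > 1 else float("nan")
    cox_snell = 1.0 - math.exp(-lr / n)
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    return LogisticModelResult(
        terms=terms,
        n=n,
        loglik=ll,
        loglik_null=ll0,
        deviance_model=dev,
        deviance_null=dev0,
        df_residual=n - k,
        df_null=n - 1,
        aic=dev + 2 * k,
        bic=dev + k * math.log(n),
        lr_chi2=lr,
        lr_p=lr_p,
        mcfadden_r2=1.0 - ll / ll0,
        cox_snell_r2=cox_snell,
        nagelkerke_r2=cox_snell / (1.0 - math.exp(2.0 * ll0 / n)),
        tjur_r=float(fitted[y == 1].mean() - fitted[y == 0].mean()),
        fitted=fitted,
    )


#: Term names of the RFM compatibility model, in design order.
RFM_TERMS = ["Intercept", "MHC I MC+FC", "MHC I MFC", "MHC II MC+FC", "MHC II MFC"]


def rfm_design(calls: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Outcome vector and design matrix from a tidy per-(pair, class) call frame.

    NC is the referent for each class; MC and FC are collapsed into one
    indicator per class, MFC gets its own, matching five parameters in all.
    """
    wide = calls.pivot_table(
        index=["mare_id", "foal_id", "rfm"],
        columns="mhc_class",
        values="category",
        aggfunc="first",
    ).reset_index()
    for mhc_class in ("I", "II"):
        if mhc_class not in wide.columns or wide[mhc_class].isna().any():
            raise ValidationError(f"every pair needs an MHC {mhc_class} category")
    y = wide["rfm"].astype(float).to_numpy()
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "MHC I MC+FC": wide["I"].isin(["MC", "FC"]).astype(float),
            "MHC I MFC": (wide["I"] == "MFC").astype(float),
            "MHC II MC+FC": wide["II"].isin(["MC", "FC"]).astype(float),
            "MHC II MFC": (wide["II"] == "MFC").astype(float),
        }
    )
    return y, X


def fit_rfm_logistic(calls: pd.DataFrame, level: float = 0.95) -> LogisticModelResult:
    """Fit the RFM-on-compatibility logistic model (NC referents, MC+FC collapsed)."""
    y, X = rfm_design(calls)
    return fit_logistic(y, X, level=level)


def pseudo_r2_from_deviances(
    deviance_null: float, deviance_model: float, n: int
) -> dict[str, float]:
    """Pseudo-R^2 measures from the two deviances alone.

    McFadden = 1 - D1/D0; Cox-Snell = 1 - exp(-(D0-D1)/n);
    Nagelkerke = Cox-Snell / (1 - exp(-D0/n)).
    """
    if deviance_model > deviance_null:
        raise ValidationError("model deviance exceeds null deviance")
    lr = deviance_null - deviance_model
    cox_snell = 1.0 - math.exp(-lr / n)
    return {
        "mcfadden": 1.0 - deviance_model / deviance_null,
        "cox_snell": cox_snell,
        "nagelkerke": cox_snell / (1.0 - math.exp(-deviance_null / n)),
        "lr_chi2": lr,
    }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def students_t_test(sample_a, sample_b) -> TTestResult:
    """Two-sided pooled-variance Student's t-test.

    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means it gives an infinite t (p = 0), flagged by the inf value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least 2 values")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), df, 0.0)
    res = st.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


@dataclass(frozen=True)
class MWUResult:
    u: float
    p: float
    method: str  # "exact" | "normal_approx"


def mann_whitney_u(sample_a, sample_b, mode: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test, reporting U = min(U_a, U_b).

    ``auto`` uses the exact null distribution when n_a * n_b <= 400 and
    there are no ties, else the normal approximation with tie and
    continuity corrections; ``exact`` / ``normal_approx`` force a method
    (exact with ties falls back to the approximation with a warning).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("samples must be non-empty")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = {
        "auto": not has_ties and len(a) * len(b) <= 400,
        "exact": not has_ties,
        "normal_approx": False,
    }[mode]
    if mode == "exact" and has_ties:
        warnings.warn("ties present: falling back to the normal approximation", stacklevel=2)
    method = "exact" if use_exact else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, len(a) * len(b) - u_a)
    return MWUResult(u, float(res.pvalue), "exact" if use_exact else "normal_approx")
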