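"""Case-control logistic association and model diagnostics.

The logistic fitter is written here from first principles (iteratively
reweighted least squares with observed-information standard errors), so
the downstream odds ratios, forward-Wald selection, Hosmer-Lemeshow
calibration and collinearity diagnostics share one transparent numerical
core.  Confidence intervals are Wald-type exp(beta +/- 1.96 SE)
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

Z975 = 1.959963984540054  # norm.ppf(0.975)

#: Named covariate-adjustment sets for the quantile risk-gradient model.
#: "age_sex" is the minimal matched-design adjustment; "trf4" the four
#: classical risk factors; "extended7"/"extended8" the wider confounder
#: sets (the two differ by alcohol intake, reflecting two common
#: conventions for the "7 covariates" extended adjustment).
ADJUSTMENT_PRESETS: dict[str, list[str]] = {
    "none": [],
    "age_sex": ["age", "sex_male"],
    "trf4": ["smoking", "diabetes", "hypertension", "dyslipidemia"],
    "extended7": ["sex_male", "age", "heart_rate", "pwv", "low_exercise",
                  "bmi", "family_history"],
    "extended8": ["sex_male", "age", "heart_rate", "pwv", "low_exercise",
                  "alcohol", "bmi", "family_history"],
}


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style scan
        offending = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                offending.append(names[j])
        raise ValueError(f"design matrix not full column rank; offending "
                         f"columns: {offending}")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression results.

    ``params`` are coefficients on the log-odds scale; ``or_`` and the CI
    bounds are their exponentials.  ``converged`` is False under
    separation or iteration exhaustion, in which case estimates are
    reported only through :meth:`summary_frame` with a warning column.
    """

    exog_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    n_obs: int
    converged: bool
    n_iter: int
    fittedvalues: np.ndarray  # predicted probabilities
    diverging: list[str] = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self) -> np.ndarray:
        lo = np.exp(self.params - Z975 * self.bse)
        hi = np.exp(self.params + Z975 * self.bse)
        return np.column_stack([lo, hi])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.exog_names, "beta": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues, "or": self.or_,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1],
        })

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.params)


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    Converges when the largest coefficient update falls below ``tol``.
    Complete separation surfaces as ``converged = False`` with the
    diverging coefficients named — estimates are never silently trusted.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["const"] + names
    if len(Xm) != len(y):
        raise ValueError("X and y lengths differ")
    _check_full_rank(Xm, names)

    beta = np.zeros(Xm.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = Xm * w[:, None]
        beta_new = np.linalg.solve(Xm.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = Xm @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = Xm.T @ (Xm * w[:, None])
    with np.errstate(all="ignore"):
        cov = np.linalg.inv(info)
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(all="ignore"):
        llf = float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                           + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
    diverging = [n for n, b in zip(names, beta) if abs(b) > 25.0]
    if diverging:
        converged = False
    return LogisticFit(names, beta, bse, llf, len(y), converged, it, mu,
                       diverging)


# -- 2x2 contingency ---------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    """2x2 association: cross-product OR with Woolf CI, and a chi-square
    or Fisher exact p (Fisher auto-selected when any expected cell < 5)."""

    table: np.ndarray
    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    test: str  # "chi2" | "fisher"


def contingency_2x2(table, continuity: bool = False) -> ContingencyResult:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c) if b * c > 0 else np.inf
    if min(a, b, c, d) > 0:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (or_ * np.exp(-Z975 * se), or_ * np.exp(Z975 * se))
    else:
        ci = (0.0, np.inf)
    n = t.sum()
    expected = np.outer(t.sum(1), t.sum(0)) / n
    if (expected < 5).any():
        from scipy.stats import fisher_exact

        _, p = fisher_exact(t.astype(int))
        test = "fisher"
    else:
        from scipy.stats import chi2_contingency

        _, p, _, _ = chi2_contingency(t, correction=continuity)
        test = "chi2"
    return ContingencyResult(t, float(or_), ci, float(p), test)


# -- quantile risk gradient --------------------------------------------

@dataclass
class QuantileOrResult:
    """Per-bin odds ratios versus the first quantile (the reference)."""

    fit: LogisticFit
    k: int
    adjusted_for: list[str]
    table: pd.DataFrame  # bin, or, ci_low, ci_high, p (reference row OR = 1)


def quartile_or(
    cohort,
    assignment,
    adjust: str | list[str] | None = None,
    ref: int = 1,
) -> QuantileOrResult:
    """Logistic model of case status on quantile-bin indicators.

    Bins other than ``ref`` (the first quantile by default; e.g. the 5th
    decile for a decile gradient) are indicator-coded against it;
    ``adjust`` may be a preset name from :data:`ADJUSTMENT_PRESETS` or an
    explicit covariate list.  Subjects without a bin (unscorable) are
    dropped.
    """
    if adjust is None:
        covars: list[str] = []
    elif isinstance(adjust, str):
        if adjust not in ADJUSTMENT_PRESETS:
            raise KeyError(f"unknown adjustment preset {adjust!r}; "
                           f"have {sorted(ADJUSTMENT_PRESETS)}")
        covars = ADJUSTMENT_PRESETS[adjust]
    else:
        covars = list(adjust)
    bins = assignment.bins
    ok = bins.to_numpy() > 0
    bins_ok = bins.to_numpy()[ok]
    y = cohort.phenotype.to_numpy()[ok]
    k = assignment.k
    if not (1 <= ref <= k):
        raise ValueError(f"reference bin {ref} outside 1..{k}")
    for b in range(1, k + 1):
        if not (bins_ok == b).any():
            raise ValueError(f"quantile bin {b} is empty")
    nonref = [b for b in range(1, k + 1) if b != ref]
    cols = {f"q{b}": (bins_ok == b).astype(float) for b in nonref}
    X = pd.DataFrame(cols)
    for c in covars:
        X[c] = cohort.covariates[c].to_numpy()[ok]
    fit = fit_logistic(X, y)
    sf = fit.summary_frame().set_index("term")
    rows = []
    for b in range(1, k + 1):
        if b == ref:
            rows.append({"bin": b, "or": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                         "p": np.nan})
        else:
            r = sf.loc[f"q{b}"]
            rows.append({"bin": b, "or": r["or"], "ci_low": r["ci_low"],
                         "ci_high": r["ci_high"], "p": r["p"]})
    return QuantileOrResult(fit, k, covars, pd.DataFrame(rows))


# -- forward Wald selection --------------------------------------------

@dataclass
class ForwardSelectionResult:
    fit: LogisticFit | None
    selected: list[str]
    trace: list[dict]  # per step: candidate p-values and the entrant


def forward_wald_selection(
    candidates: pd.DataFrame,
    y: np.ndarray,
    entry_p: float = 0.05,
) -> ForwardSelectionResult:
    """Forward stepwise selection by the Wald statistic.

    Each round refits the current model plus each remaining candidate
    and admits the one with the smallest Wald p below ``entry_p``; ties
    break deterministically by candidate order.  Returns the final fit
    (None if nothing enters) and the full inclusion trace.
    """
    if not (0.0 < entry_p <= 1.0):
        raise ValueError("entry_p must be in (0, 1]")
    remaining = list(candidates.columns)
    selected: list[str] = []
    trace: list[dict] = []
    while remaining:
        pvals = {}
        for cand in remaining:
            fit = fit_logistic(candidates[selected + [cand]], y)
            pvals[cand] = float(fit.pvalues[-1])
        best = min(remaining, key=lambda c: (pvals[c], remaining.index(c)))
        if pvals[best] < entry_p or (entry_p >= 1.0):
            selected.append(best)
            remaining.remove(best)
            trace.append({"entered": best, "p": pvals[best],
                          "candidate_p": dict(pvals)})
        else:
            trace.append({"entered": None, "candidate_p": dict(pvals)})
            break
    fit = fit_logistic(candidates[selected], y) if selected else None
    return ForwardSelectionResult(fit, selected, trace)


# -- calibration -------------------------------------------------------

@dataclass(frozen=True)
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    n_groups: int
    merged: bool  # True when empty risk-decile bins were merged
    table: pd.DataFrame  # per group: n, observed, expected


def hosmer_lemeshow(probs: np.ndarray, y: np.ndarray,
                    groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit over quantile groups of predicted
    risk: sum over groups of (O - E)^2 / (n pi (1 - pi)), df = g - 2."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups < 3:
        raise ValueError("groups must be >= 3")
    edges = np.quantile(probs, np.arange(1, groups) / groups)
    edges = np.unique(edges)
    merged = len(edges) < groups - 1
    bin_id = np.searchsorted(edges, probs, side="right")
    rows = []
    stat = 0.0
    for g in np.unique(bin_id):
        sel = bin_id == g
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(probs[sel].sum())
        pbar = exp / n_g
        denom = n_g * pbar * (1.0 - pbar)
        if denom > 0:
            stat += (obs - exp) ** 2 / denom
        rows.append({"group": int(g), "n": n_g, "observed": obs,
                     "expected": exp})
    n_groups = len(rows)
    df = max(n_groups - 2, 1)
    return HosmerLemeshowResult(float(stat), df, float(chi2.sf(stat, df)),
                                n_groups, merged, pd.DataFrame(rows))


# -- collinearity ------------------------------------------------------

@dataclass(frozen=True)
class CollinearityReport:
    """Tolerance (1 - R^2 of each predictor on the rest) and VIF."""

    table: pd.DataFrame  # predictor, tolerance, vif, perfectly_collinear

    def max_vif(self) -> float:
        return float(self.table.vif.max())


def collinearity(X: pd.DataFrame) -> CollinearityReport:
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors for collinearity diagnostics")
    Xm = X.to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(X.columns):
        target = Xm[:, j]
        others = np.column_stack([np.ones(len(Xm)),
                                  np.delete(Xm, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        perfect = r2 > 1.0 - 1e-10
        tol = max(1.0 - r2, 0.0)
        vif = np.inf if perfect else 1.0 / tol
        rows.append({"predictor": name, "tolerance": tol, "vif": vif,
                     "perfectly_collinear": perfect})
    return CollinearityReport(pd.DataFrame(rows))
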