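"""Statistical kernel for candidate-biomarker discovery.

Univariate side: pooled-variance Student t-tests with a Bonferroni-style
threshold of 0.05/sqrt(n) over the number of measured variables, and Šidák
adjustment for post-hoc contrast families.  Multivariate side: PCA-based
sample-outlier exclusion (Hotelling T² ellipse on the first two components)
and sparse PLS-DA feature selection (NIPALS with a hard keepX constraint per
component).  A fixed-effects two-way ANOVA with Šidák post-hoc serves the
grouped (class-level) comparisons, and pairwise-complete Pearson matrices
serve gene-panel correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# univariate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    direction: str  # 'up' | 'down' | 'zero' : how b compares with a


def student_t(a, b, *, welch: bool = False) -> TestResult:
    """Two-tailed two-sample t-test of ``b`` against ``a``.

    Pooled-variance (classic Student) by default; ``welch=True`` uses the
    unequal-variance form.  Missing values (NaN) are dropped per vector
    (complete-case).  Direction is the sign of mean(b) − mean(a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    diff = b.mean() - a.mean()
    direction = "up" if diff > 0 else ("down" if diff < 0 else "zero")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # both groups constant: identical -> null exactly, else infinite evidence
        if diff == 0:
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "zero")
        return TestResult(np.inf if diff > 0 else -np.inf,
                          float(a.size + b.size - 2), 0.0, direction)
    res = sps.ttest_ind(b, a, equal_var=not welch)
    df = (a.size + b.size - 2) if not welch else res.df
    return TestResult(float(res.statistic), float(df), float(res.pvalue), direction)


def ttest_matrix(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised complete-case pooled t-tests, one per column.

    Returns (t, p, mean_diff) arrays; columns with fewer than 2 non-missing
    values in either group yield NaN.  Equivalent to :func:`student_t` column
    by column (NaN-aware), but runs in a few matrix operations.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    na = np.sum(~np.isnan(xa), axis=0).astype(float)
    nb = np.sum(~np.isnan(xb), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(xa, axis=0)
        mb = np.nanmean(xb, axis=0)
        va = np.nanvar(xa, axis=0, ddof=1)
        vb = np.nanvar(xb, axis=0, ddof=1)
    ok = (na >= 2) & (nb >= 2)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = np.full(t.shape, np.nan)
    finite = ok & np.isfinite(t)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df[finite])
    # constant-and-equal groups: t = 0/0 -> define as the exact null
    degenerate = ok & ~np.isfinite(t) & (sp2 == 0)
    p[degenerate & (diff == 0)] = 1.0
    t[degenerate & (diff == 0)] = 0.0
    p[degenerate & (diff != 0)] = 0.0
    t[~ok] = np.nan
    return t, p, diff


def bonferroni_sqrt_threshold(n_variables: int) -> float:
    """Significance threshold 0.05 / sqrt(n) over ``n_variables`` tests.

    This square-root Bonferroni variant deliberately under-corrects relative
    to the full 0.05/n bound; it is paired downstream with a multivariate
    selection step and a cross-comparison replication requirement.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    return 0.05 / float(np.sqrt(n_variables))


def sidak_adjust(p: float, m: int) -> float:
    """Šidák family-wise adjustment 1 − (1 − p)^m, capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m == 1:
        return float(p)
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


# --------------------------------------------------------------------------
# two-way ANOVA with Šidák post-hoc
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_condition: float
    p_condition: float
    f_category: float
    p_category: float
    f_interaction: float | None
    p_interaction: float | None
    contrasts: pd.DataFrame  # condition contrast within each category level
    warnings: list[str] = field(default_factory=list)


def two_way_anova(values, factor_condition, factor_category) -> AnovaResult:
    """Fixed-effects two-way layout with interaction and Šidák post-hoc.

    Type III sums of squares with sum-to-zero coding (robust to imbalance).
    The post-hoc family is every pairwise condition contrast within each
    category level, tested against the full-model residual mean square and
    Šidák-adjusted for the family size.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "cond": pd.Categorical(factor_condition),
        "cat": pd.Categorical(factor_category),
    }).dropna(subset=["value"])
    if df["cond"].nunique() < 2 or df["cat"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")

    warns: list[str] = []
    cells = df.groupby(["cond", "cat"], observed=True).size()
    full_grid = df["cond"].nunique() * df["cat"].nunique()
    with_interaction = len(cells) == full_grid and (cells >= 1).all()
    if not with_interaction:
        warns.append("empty cell(s): interaction term dropped")

    formula = ("value ~ C(cond, Sum) * C(cat, Sum)" if with_interaction
               else "value ~ C(cond, Sum) + C(cat, Sum)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols(formula, data=df).fit()
        table = sm.stats.anova_lm(model, typ=3)

    f_cond, p_cond = float(table.loc["C(cond, Sum)", "F"]), float(table.loc["C(cond, Sum)", "PR(>F)"])
    f_cat, p_cat = float(table.loc["C(cat, Sum)", "F"]), float(table.loc["C(cat, Sum)", "PR(>F)"])
    inter = "C(cond, Sum):C(cat, Sum)"
    f_int = float(table.loc[inter, "F"]) if with_interaction else None
    p_int = float(table.loc[inter, "PR(>F)"]) if with_interaction else None

    # identical data everywhere: statsmodels yields 0/0 -> the exact null
    if np.allclose(df["value"].var(ddof=0), 0.0):
        f_cond = f_cat = 0.0
        p_cond = p_cat = 1.0
        if with_interaction:
            f_int, p_int = 0.0, 1.0

    mse = model.mse_resid
    dfr = model.df_resid
    conds = list(df["cond"].cat.categories)
    rows = []
    for cat_level, sub in df.groupby("cat", observed=True):
        means = sub.groupby("cond", observed=True)["value"].agg(["mean", "size"])
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                ci, cj = conds[i], conds[j]
                if ci not in means.index or cj not in means.index:
                    continue
                d = means.loc[cj, "mean"] - means.loc[ci, "mean"]
                se = np.sqrt(mse * (1.0 / means.loc[ci, "size"] + 1.0 / means.loc[cj, "size"]))
                t = d / se if se > 0 else (0.0 if d == 0 else np.inf * np.sign(d))
                p = 2.0 * sps.t.sf(abs(t), dfr) if np.isfinite(t) else (1.0 if d == 0 else 0.0)
                rows.append({"category": cat_level, "contrast": f"{ci} vs {cj}",
                             "estimate": d, "t": t, "p_raw": p})
    contrasts = pd.DataFrame(rows)
    if not contrasts.empty:
        m = len(contrasts)
        contrasts["p_sidak"] = [sidak_adjust(p, m) for p in contrasts["p_raw"]]
    return AnovaResult(f_cond, p_cond, f_cat, p_cat, f_int, p_int, contrasts, warns)


# --------------------------------------------------------------------------
# PCA outlier exclusion
# --------------------------------------------------------------------------

def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance scaling per column; constant columns are dropped.

    Returns (scaled matrix, boolean mask of kept columns).
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xs, keep


def pca_outlier_exclusion(X, sample_ids=None, confidence: float = 0.95) -> list:
    """Samples outside the Hotelling T² ellipse of the first two PCs.

    Variables are autoscaled, the data projected onto two principal
    components, and each sample's T² statistic compared against the
    F-based control limit 2(n−1)/(n−2)·F(confidence; 2, n−2).  With fewer
    than 4 samples no exclusion is attempted.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    if n < 4:
        warnings.warn("fewer than 4 samples: skipping PCA outlier exclusion")
        return []
    Xs, _ = autoscale(X)
    k = min(2, Xs.shape[1])
    scores = PCA(n_components=k, svd_solver="full").fit_transform(Xs)
    lam = scores.var(axis=0, ddof=1)
    lam[lam == 0] = np.inf  # degenerate direction carries no distance
    t2 = np.sum(scores**2 / lam, axis=1)
    crit = k * (n - 1) / (n - k) * sps.f.ppf(confidence, k, n - k)
    return [sid for sid, v in zip(sample_ids, t2) if v > crit]


# --------------------------------------------------------------------------
# sparse PLS-DA
# --------------------------------------------------------------------------

@dataclass
class SplsdaModel:
    n_components: int
    keepx: list[int]
    loadings: pd.DataFrame          # variables × components (sparse weights)
    scores: pd.DataFrame            # samples × components
    selected_variables: list[str]
    dropped_constant: list[str] = field(default_factory=list)


def _soft_keep(w: np.ndarray, keepx: int) -> np.ndarray:
    """Keep the ``keepx`` largest |entries| of w, zero the rest, renormalise."""
    if keepx < w.size:
        cut = np.partition(np.abs(w), w.size - keepx)[w.size - keepx]
        mask = np.abs(w) >= cut
        # ties at the threshold could keep more than keepx; break by index order
        if mask.sum() > keepx:
            order = np.lexsort((np.arange(w.size), -np.abs(w)))
            mask = np.zeros_like(mask)
            mask[order[:keepx]] = True
        w = np.where(mask, w, 0.0)
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else w


def splsda_select(X, y, n_components: int = 2, keepx=10) -> SplsdaModel:
    """Sparse PLS-DA on a two-class problem, used as a feature selector.

    NIPALS-style PLS1 on autoscaled X against a centred class indicator.
    Per component, the weight vector is hard-thresholded so at most ``keepx``
    entries remain nonzero (largest absolute weights), renormalised, and X is
    deflated by the component's loading before the next iteration.  The
    selected set is the union of nonzero supports across components.  Each
    component is oriented so the mean score of the second class is positive.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    var_names = [str(c) for c in Xdf.columns]
    sample_ids = list(Xdf.index)
    Xm = Xdf.to_numpy(dtype=float)

    classes = pd.unique(pd.Series(y))
    if len(classes) != 2:
        raise ValueError("splsda_select requires exactly two classes")
    yvec = np.asarray([1.0 if v == classes[1] else 0.0 for v in y])
    if min((yvec == 0).sum(), (yvec == 1).sum()) < 2:
        raise ValueError("each class needs at least 2 samples")

    if isinstance(keepx, int):
        keepx = [keepx] * n_components
    keepx = [min(int(k), Xm.shape[1]) for k in keepx]
    if len(keepx) != n_components:
        raise ValueError("keepx must have one entry per component")

    Xs, keep_mask = autoscale(Xm)
    dropped = [v for v, k in zip(var_names, keep_mask) if not k]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant variable(s) before autoscaling")
    kept_names = [v for v, k in zip(var_names, keep_mask) if k]
    keepx = [min(k, Xs.shape[1]) for k in keepx]

    u = yvec - yvec.mean()
    Xc = Xs.copy()
    W = np.zeros((Xs.shape[1], n_components))
    T = np.zeros((Xs.shape[0], n_components))
    is_b = yvec == 1.0
    for h in range(n_components):
        w = Xc.T @ u
        nrm = np.linalg.norm(w)
        if nrm == 0:
            break
        w = _soft_keep(w / nrm, keepx[h])
        t = Xc @ w
        tt = t @ t
        if tt == 0:
            break
        # orient: second-listed class scores positive on average
        if t[is_b].mean() < 0:
            w, t = -w, -t
        p_load = Xc.T @ t / tt
        c = u @ t / tt
        Xc = Xc - np.outer(t, p_load)
        u = u - c * t
        W[:, h] = w
        T[:, h] = t

    loadings = pd.DataFrame(W, index=kept_names,
                            columns=[f"comp{h+1}" for h in range(n_components)])
    scores = pd.DataFrame(T, index=sample_ids,
                          columns=[f"comp{h+1}" for h in range(n_components)])
    selected = [v for v in kept_names if np.any(loadings.loc[v].to_numpy() != 0.0)]
    return SplsdaModel(n_components, keepx, loadings, scores, selected, dropped)


# --------------------------------------------------------------------------
# Pearson correlation matrices
# --------------------------------------------------------------------------

def pearson_matrix(expression: pd.DataFrame, threshold: float = 0.0045):
    """Pairwise-complete Pearson correlations over a genes × samples matrix.

    Returns (r, p, significant) DataFrames.  p-values come from the exact
    t-transform t = r·sqrt((n−2)/(1−r²)) on the pairwise-complete sample
    count n; pairs with fewer than 3 complete observations are undetermined
    (NaN everywhere, never significant).
    """
    if not isinstance(expression, pd.DataFrame):
        expression = pd.DataFrame(np.asarray(expression, dtype=float))
    data = expression.T  # samples × genes for pandas corr
    r = data.corr(method="pearson", min_periods=3)
    notna = data.notna().to_numpy(dtype=float)
    n_pairs = pd.DataFrame(notna.T @ notna, index=r.index, columns=r.columns)
    rv = r.to_numpy()
    nv = n_pairs.to_numpy()
    p = np.full_like(rv, np.nan)
    ok = (~np.isnan(rv)) & (nv >= 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((nv - 2) / (1.0 - rv**2))
    exact = ok & (np.abs(rv) >= 1.0)
    p[exact] = 0.0
    rest = ok & ~exact
    p[rest] = 2.0 * sps.t.sf(np.abs(t[rest]), nv[rest] - 2)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    significant = (p < threshold) & r.notna()
    # self-correlation is not a finding
    np.fill_diagonal(significant.values, False)
    return r, p, significant
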