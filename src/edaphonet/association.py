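"""Statistics relating multifunctionality to diversity, networks and soil.

Ordinary least-squares regression (MF ~ diversity / network metrics),
Pearson correlation matrices (diversity ~ soil properties), Kruskal-Wallis
tests of erosion effects within site, two-way ANOVA (site x erosion with a
transect blocking factor, Tukey post hoc) and redundancy analysis of taxon
abundances on soil variables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

__all__ = [
    "linear_regression",
    "RegressionResult",
    "pearson_matrix",
    "kruskal_wallis",
    "two_way_anova",
    "GroupTestResult",
    "rda",
    "RdaResult",
    "letter_display",
]


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(
    x, y, predictor: str = "x", response: str = "y"
) -> RegressionResult:
    """Simple OLS of y on x; p-value from the slope t-statistic (n-2 df)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValidationError("x and y must have equal length")
    if xv.size < 3:
        raise ValidationError("regression needs at least 3 points")
    if np.ptp(xv) == 0:
        raise ValidationError("constant predictor")
    res = stats.linregress(xv, yv)
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 0.0
        p = 1.0
    else:
        fitted = res.intercept + res.slope * xv
        r2 = 1.0 - float(((yv - fitted) ** 2).sum()) / ss_tot
        p = float(res.pvalue)
    return RegressionResult(
        predictor=predictor, response=response, slope=float(res.slope),
        intercept=float(res.intercept), r_squared=r2, p_value=p, n=int(xv.size),
    )


def pearson_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and two-sided p for every (a-column, b-column).

    Returns a long-format frame with columns ``var_a, var_b, r, p, flag``;
    pairs involving a constant column get NaN with flag ``"constant"``.
    """
    if a.shape[0] != b.shape[0]:
        raise ValidationError("tables must have the same number of rows")
    if not a.index.equals(b.index):
        raise ValidationError("tables must be indexed by the same samples")
    if a.shape[0] < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    rows = []
    for ca in a.columns:
        xa = a[ca].to_numpy(dtype=float)
        for cb in b.columns:
            xb = b[cb].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rows.append({"var_a": ca, "var_b": cb, "r": np.nan,
                             "p": np.nan, "flag": "constant"})
                continue
            r, p = stats.pearsonr(xa, xb)
            rows.append({"var_a": ca, "var_b": cb, "r": float(r),
                         "p": float(p), "flag": "ok"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group tests with compact letter display


def letter_display(groups: list[str], sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``sig[(a, b)]`` is True when groups a and b differ significantly.
    Groups sharing at least one letter are not significantly different.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not sig.get((a, b), sig.get((b, a), False)):
            continue
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb sets contained in others
        letter_sets = [
            s for s in new_sets
            if not any(s < t for t in new_sets)
        ]
        # deduplicate
        uniq = []
        for s in letter_sets:
            if s not in uniq:
                uniq.append(s)
        letter_sets = uniq
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    letters: dict[str, str]
    table: pd.DataFrame | None = None  # per-term or pairwise detail


def kruskal_wallis(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """Kruskal-Wallis H test with pairwise rank-sum post hoc letters.

    H uses midranks with the standard tie correction; post hoc pairwise
    two-sided Mann-Whitney tests are Holm-adjusted before building the
    compact letter display.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(pd.Series(list(groups)).astype(str))
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    samples = [v[g == lev] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("Kruskal-Wallis groups need at least 2 members")
    if np.ptp(v) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa, xb = v[g == a], v[g == b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            pp = 1.0
        else:
            pp = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"group_a": a, "group_b": b, "p": pp})
    detail = pd.DataFrame(rows)
    if len(detail):
        order = np.argsort(detail["p"].to_numpy())
        adj = np.empty(len(detail))
        running = 0.0
        mm = len(detail)
        for rank, idx in enumerate(order):  # Holm step-down
            running = max(running, (mm - rank) * detail["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        detail["p_holm"] = adj
    sig = {(r["group_a"], r["group_b"]): r["p_holm"] < alpha
           for _, r in detail.iterrows()}
    letters = letter_display(levels, sig)
    return GroupTestResult("kruskal_wallis", float(h), float(p), letters, detail)


def two_way_anova(
    response, site, erosion, block=None, alpha: float = 0.05
) -> GroupTestResult:
    """Fixed-effects two-way ANOVA: site, erosion, site x erosion (+ block).

    The transect/slope blocking factor enters additively.  Post hoc Tukey
    HSD letters are computed on erosion levels within each site.  Returns
    the erosion main effect as the headline statistic; the full term table
    is attached.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({
        "y": np.asarray(response, dtype=float),
        "site": pd.Series(list(site)).astype(str).to_numpy(),
        "erosion": pd.Series(list(erosion)).astype(str).to_numpy(),
    })
    if block is not None:
        df["block"] = pd.Series(list(block)).astype(str).to_numpy()
    if np.ptp(df["y"].to_numpy()) == 0:
        raise ValidationError("constant response: zero residual variance")
    formula = "y ~ C(site) * C(erosion)"
    if block is not None:
        formula += " + C(block)"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise ValidationError("design leaves no residual degrees of freedom")
    try:
        anova = sm.stats.anova_lm(model, typ=2)
    except Exception as exc:  # rank deficiency
        raise ValidationError(f"rank-deficient design: {exc}") from exc

    letters: dict[str, str] = {}
    for s in df["site"].unique():
        sub = df[df["site"] == s]
        if sub["erosion"].nunique() < 2:
            continue
        tuk = pairwise_tukeyhsd(sub["y"], sub["erosion"], alpha=alpha)
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        sig = {(str(r["group1"]), str(r["group2"])): bool(r["reject"])
               for _, r in res.iterrows()}
        site_letters = letter_display(list(pd.unique(sub["erosion"])), sig)
        letters.update({f"{s}:{k}": v for k, v in site_letters.items()})

    erosion_row = [ix for ix in anova.index if "erosion" in ix and ":" not in ix]
    stat = float(anova.loc[erosion_row[0], "F"]) if erosion_row else np.nan
    p = float(anova.loc[erosion_row[0], "PR(>F)"]) if erosion_row else np.nan
    return GroupTestResult("two_way_anova", stat, p, letters, anova)


# ---------------------------------------------------------------------------
# Redundancy analysis


@dataclass(frozen=True)
class RdaResult:
    constrained_proportion: float
    eigenvalues: np.ndarray
    p_value: float
    n_permutations: int


def rda(
    response_matrix,
    explanatory_matrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> RdaResult:
    """Redundancy analysis of a response matrix on explanatory variables.

    Both matrices are column-centered; the constrained proportion is the
    trace of the fitted (projected) response over the total trace.  The
    permutation test permutes rows of the explanatory matrix.
    """
    y = np.asarray(response_matrix, dtype=float)
    x = np.asarray(explanatory_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim == 1:
        x = x[:, None]
    if y.shape[0] != x.shape[0]:
        raise ValidationError("response and explanatory row counts differ")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        raise ValidationError("explanatory matrix is rank deficient (collinear)")
    qx, _ = np.linalg.qr(xc)
    total = float((yc ** 2).sum())
    if total == 0:
        raise ValidationError("response matrix has zero variance")

    def constrained_ss(perm_rows: np.ndarray | None = None) -> float:
        q = qx if perm_rows is None else qx[perm_rows]
        fitted = q @ (q.T @ yc)
        return float((fitted ** 2).sum())

    ss_obs = constrained_ss()
    fitted = qx @ (qx.T @ yc)
    s = np.linalg.svd(fitted, compute_uv=False)
    eigs = (s ** 2)[: xc.shape[1]]

    rng = np.random.default_rng(seed)
    ge = 0
    nrow = yc.shape[0]
    for _ in range(n_permutations):
        if constrained_ss(rng.permutation(nrow)) >= ss_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return RdaResult(
        constrained_proportion=ss_obs / total,
        eigenvalues=eigs,
        p_value=float(p),
        n_permutations=n_permutations,
    )
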