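"""Alpha diversity, Bray-Curtis beta diversity, ANOSIM and constrained PCoA.

Alpha diversity covers the Shannon index (natural log), observed species and
the abundance-based coverage estimator (ACE).  Beta diversity is Bray-Curtis
dissimilarity, compared across erosion levels with ANOSIM (rank-based
permutation test) and ordinated with a constrained principal coordinate
analysis (PCoA embedding followed by redundancy analysis on the group
indicator matrix, i.e. the distance-based RDA behind vegan's ``capscale``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix

from .datatypes import OtuTable, ValidationError

__all__ = [
    "shannon",
    "observed_species",
    "ace",
    "alpha_diversity_table",
    "bray_curtis_matrix",
    "anosim",
    "AnosimResult",
    "cpcoa",
    "OrdinationResult",
]


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i in nats; zero counts are ignored."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValidationError("Shannon index undefined for an all-zero sample")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def observed_species(counts) -> int:
    c = np.asarray(counts, dtype=float)
    return int((c > 0).sum())


@dataclass(frozen=True)
class AceResult:
    value: float
    flag: str  # "ok", "no_rare", or "chao1_fallback"


def ace(counts, rare_threshold: int = 10) -> AceResult:
    """Abundance-based coverage estimator of richness (Chao & Lee).

    Taxa with count <= ``rare_threshold`` form the rare group; sample
    coverage C_ace = 1 - F1/N_rare, and

        ACE = S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2

    with the squared coefficient of variation gamma^2 floored at zero.  When
    every rare individual is a singleton C_ace = 0 and ACE is undefined; the
    bias-corrected Chao1 estimate is reported instead with flag
    ``"chao1_fallback"`` so per-sample tables stay complete.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0].astype(int)
    if c.size == 0:
        raise ValidationError("ACE undefined for an all-zero sample")
    rare = c[c <= rare_threshold]
    s_abund = int((c > rare_threshold).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return AceResult(float(s_abund), "no_rare")
    n_rare = int(rare.sum())
    f = np.bincount(rare, minlength=rare_threshold + 1)  # f[i] = #taxa with count i
    f1 = int(f[1])
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare individuals are singletons: report bias-corrected Chao1
        f2 = int(f[2]) if f.size > 2 else 0
        s_obs = int(c.size)
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        return AceResult(float(chao1), "chao1_fallback")
    i = np.arange(1, rare_threshold + 1)
    sum_term = float((i * (i - 1) * f[1:]).sum())
    gamma2 = (s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    value = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return AceResult(float(value), "ok")


def alpha_diversity_table(table: OtuTable, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample alpha diversity: shannon, observed_species, ace, ace_flag."""
    rows = []
    for sid in table.sample_ids:
        c = table.counts.loc[sid].to_numpy()
        a = ace(c, rare_threshold=rare_threshold)
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(c),
                "observed_species": observed_species(c),
                "ace": a.value,
                "ace_flag": a.flag,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def bray_curtis_matrix(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix over all samples."""
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    counts = table.counts.to_numpy(dtype=float)
    if np.any(counts.sum(axis=1) == 0):
        bad = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
        raise ValidationError(f"all-zero samples: {bad}")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass(frozen=True)
class AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    computed on midranks of all pairwise dissimilarities.  The permutation
    p-value is (1 + #{R_perm >= R_obs}) / (1 + n_permutations); the exact
    variant enumerates all distinct label assignments instead.
    """

    R: float
    p_value: float
    n_permutations: int
    method: str
    pairwise: pd.DataFrame | None = None


def _anosim_r(ranks_condensed: np.ndarray, labels: np.ndarray, n: int) -> float:
    # within pairs: same label at the two ends of the condensed pair index
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    r_within = ranks_condensed[same].mean()
    r_between = ranks_condensed[~same].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
    pairwise: bool = False,
) -> AnosimResult:
    """ANOSIM of a distance matrix against a grouping factor.

    Parameters
    ----------
    method : {"permutation", "exact"}
        ``"exact"`` enumerates every distinct assignment of the multiset of
        group labels (feasible only for small n).
    pairwise : bool
        Also run all two-group comparisons, Bonferroni-adjusting their
        p-values by the number of comparisons.
    """
    labels = np.asarray(pd.Series(list(groups)).astype(str))
    n = len(dist.ids)
    if labels.shape[0] != n:
        raise ValidationError("groups length must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        singles = uniq[counts < 2].tolist()
        raise ValidationError(f"ANOSIM groups with fewer than 2 samples: {singles}")

    condensed = dist.condensed_form()
    ranks = rankdata(condensed)  # midranks
    r_obs = _anosim_r(ranks, labels, n)

    if method == "exact":
        from sympy.utilities.iterables import multiset_permutations

        total = 0
        ge = 0
        for perm in multiset_permutations(list(labels)):
            r = _anosim_r(ranks, np.asarray(perm), n)
            total += 1
            if r >= r_obs - 1e-12:
                ge += 1
        p = ge / total
        n_used = total
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_permutations):
            r = _anosim_r(ranks, rng.permutation(labels), n)
            if r >= r_obs - 1e-12:
                ge += 1
        p = (1 + ge) / (1 + n_permutations)
        n_used = n_permutations
    else:  # pragma: no cover - guarded usage error
        raise ValueError(f"unknown method {method!r}")

    pw = None
    if pairwise:
        combos = list(itertools.combinations(uniq, 2))
        rows = []
        ids = np.asarray(dist.ids)
        for a, b in combos:
            mask = (labels == a) | (labels == b)
            sub = dist.filter(ids[mask])
            res = anosim(
                sub, labels[mask], n_permutations=n_permutations, seed=seed,
                method=method, pairwise=False,
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "R": res.R,
                    "p_value": res.p_value,
                    "p_bonferroni": min(1.0, res.p_value * len(combos)),
                }
            )
        pw = pd.DataFrame(rows)

    return AnosimResult(R=r_obs, p_value=float(p), n_permutations=n_used,
                        method=method, pairwise=pw)


# ---------------------------------------------------------------------------
# Constrained PCoA (distance-based RDA)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x constrained axes
    proportion_explained: float
    eigenvalues: np.ndarray
    p_value: float
    n_permutations: int


def _pcoa_embedding(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Classical MDS; returns coordinates for positive eigenvalues only."""
    d = dist.data
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(vals.max(), 0) * 1e-10
    vals, vecs = vals[keep], vecs[:, keep]
    return vecs * np.sqrt(vals), vals


def _constrained_ss(coords: np.ndarray, labels: np.ndarray) -> float:
    """Between-group sum of squares of the (already centered) coordinates."""
    ss = 0.0
    for g in np.unique(labels):
        sub = coords[labels == g]
        ss += sub.shape[0] * float((sub.mean(axis=0) ** 2).sum())
    return ss


def cpcoa(
    dist: DistanceMatrix,
    constraint,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> OrdinationResult:
    """Constrained principal coordinate analysis of a distance matrix.

    The distance matrix is embedded by classical PCoA (negative eigenvalues
    dropped), the embedded coordinates are regressed on the constraint's
    indicator matrix, and the proportion explained is the fitted (between-
    group) sum of squares over the total positive-eigenvalue inertia.
    Significance is assessed by permuting the constraint labels.
    """
    labels = np.asarray(pd.Series(list(constraint)).astype(str))
    if labels.shape[0] != len(dist.ids):
        raise ValidationError("constraint length must match distance matrix size")
    if np.unique(labels).size < 2:
        raise ValidationError("constraint must have at least 2 levels")

    coords, eigvals = _pcoa_embedding(dist)
    total = float(eigvals.sum())
    if total <= 0:
        raise ValidationError("degenerate distance matrix: no positive inertia")

    ss_obs = _constrained_ss(coords, labels)
    proportion = ss_obs / total

    # constrained axes: eigen-decompose the fitted values (group means)
    fitted = np.empty_like(coords)
    for g in np.unique(labels):
        mask = labels == g
        fitted[mask] = coords[mask].mean(axis=0)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    k = min(np.unique(labels).size - 1, coords.shape[1])
    axes = u[:, :k] * s[:k]
    axis_eigs = (s[:k] ** 2)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        ss = _constrained_ss(coords, rng.permutation(labels))
        if ss >= ss_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)

    coord_df = pd.DataFrame(
        axes, index=list(dist.ids),
        columns=[f"CAP{i + 1}" for i in range(axes.shape[1])],
    )
    return OrdinationResult(
        coordinates=coord_df,
        proportion_explained=float(proportion),
        eigenvalues=axis_eigs,
        p_value=float(p),
        n_permutations=n_permutations,
    )
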