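"""Spearman co-occurrence networks with RMT thresholding and FDR filtering.

The network stage mirrors the standard molecular-ecological-network recipe:

1. keep OTUs whose mean relative abundance exceeds 0.01%;
2. compute the pairwise Spearman correlation matrix with two-sided p-values
   and Benjamini-Hochberg q-values over the upper triangle;
3. pick the correlation cutoff by random-matrix theory: scan a threshold
   grid and find where the nearest-neighbour spacing distribution of the
   thresholded matrix's (unfolded) eigenvalues transitions from the
   Gaussian-orthogonal-ensemble law to Poisson statistics, which marks the
   onset of non-random modular structure;
4. connect OTU pairs with |rho| >= threshold and q < alpha;
5. summarize global and per-sample (induced-subgraph) topology and flag
   keystone OTUs by fixed centrality cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OtuTable, ValidationError

__all__ = [
    "filter_otus",
    "spearman_matrix",
    "bh_fdr",
    "CorrelationResult",
    "rmt_select_threshold",
    "RmtScan",
    "RmtSelectionError",
    "build_network",
    "global_topology",
    "TopologySummary",
    "sample_subgraph_topology",
    "identify_keystones",
    "KeystoneThresholds",
]


def filter_otus(
    table: OtuTable, min_rel_abundance: float = 1e-4, pooled: bool = False
) -> OtuTable:
    """Keep OTUs with mean relative abundance strictly above the cutoff.

    ``pooled=True`` uses total reads across all samples instead of the mean
    of per-sample relative abundances.  The default 1e-4 is the usual
    0.01% prevalence filter applied before network construction.
    """
    if table.n_otus == 0:
        raise ValidationError("empty OTU table")
    if pooled:
        totals = table.counts.sum(axis=0)
        rel = totals / totals.sum()
    else:
        rel = table.relative_abundance().mean(axis=0)
    if min_rel_abundance <= 0:
        keep = table.counts.columns[(table.counts.sum(axis=0) > 0)]
    else:
        keep = rel.index[rel > min_rel_abundance]
    if len(keep) == 0:
        raise ValidationError(
            f"no OTUs above relative abundance {min_rel_abundance}; "
            "lower min_rel_abundance"
        )
    return table.subset_otus(list(keep))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in the original order.
    NaN entries are passed through and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    pv = flat[valid]
    if pv.size and (np.any(pv < 0) or np.any(pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if pv.size:
        m = pv.size
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[valid] = qv
    return q.reshape(p.shape)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation matrix with p- and BH q-values over OTU pairs."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    @property
    def otu_ids(self) -> list[str]:
        return list(self.rho.index)


def spearman_matrix(table: OtuTable) -> CorrelationResult:
    """All-pairs Spearman rho (midranks) with two-sided t-approximation p.

    Pairs involving a constant OTU vector have undefined correlation and are
    recorded as NaN; they can never become edges.  q-values are BH-adjusted
    over the defined upper-triangle p-values.
    """
    if table.n_samples < 4:
        raise ValidationError("Spearman matrix needs at least 4 samples")
    x = table.counts.to_numpy(dtype=float)
    n, m = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    constant = np.ptp(x, axis=0) == 0
    z = ranks - ranks.mean(axis=0)
    norm = np.sqrt((z ** 2).sum(axis=0))
    norm[constant] = np.nan
    rho = (z.T @ z) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan

    # two-sided p via t = r sqrt((n-2)/(1-r^2)) with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(m, k=1)
    q_flat = bh_fdr(p[iu])
    q = np.full((m, m), np.nan)
    q[iu] = q_flat
    q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(q, 0.0)

    ids = table.otu_ids
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        q=pd.DataFrame(q, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# RMT threshold selection


class RmtSelectionError(RuntimeError):
    """No threshold on the grid passed the Poisson spacing test."""


@dataclass(frozen=True)
class RmtScan:
    thresholds: np.ndarray
    poisson_chi2_p: np.ndarray
    goe_chi2_p: np.ndarray
    n_spacings: np.ndarray
    selected: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "poisson_p": self.poisson_chi2_p,
                "goe_p": self.goe_chi2_p,
                "n_spacings": self.n_spacings,
            }
        )


def _spacing_pvalues(eigvals: np.ndarray) -> tuple[float, float, int]:
    """Chi-square goodness of fit of unfolded eigenvalue spacings.

    Returns (poisson_p, goe_p, n_spacings).  The spectrum is unfolded by a
    cubic polynomial fit to the empirical cumulative spectral density;
    exactly degenerate eigenvalues are deduplicated beforehand because the
    zeroed-out matrix blocks create large null eigenspaces whose zero
    spacings would swamp the spacing law.  Each law is binned into
    equal-probability cells (expected count >= ~5, so the chi-square
    approximation and its power hold at the few dozen spacings a
    correlation matrix of this size yields).
    """
    lam = np.sort(eigvals)
    # collapse exact degeneracies (relative tolerance on the spectral span)
    span = lam[-1] - lam[0]
    if span <= 0:
        return np.nan, np.nan, 0
    tol = span * 1e-10
    keep = np.concatenate([[True], np.diff(lam) > tol])
    lam = lam[keep]
    # trim spectral outliers (module eigenvalues far outside the bulk) so a
    # cubic polynomial can represent the cumulative density of the bulk
    if lam.size >= 30:
        q1, q3 = np.percentile(lam, [25, 75])
        iqr = q3 - q1
        if iqr > 0:
            inside = (lam > q1 - 3 * iqr) & (lam < q3 + 3 * iqr)
            if inside.sum() >= 20:
                lam = lam[inside]
    n = lam.size
    if n < 20:
        return np.nan, np.nan, max(n - 1, 0)
    # unfold: cubic fit of rank ~ eigenvalue, spacings of mapped values
    ranks = np.arange(1, n + 1, dtype=float)
    coeffs = np.polyfit(lam, ranks, deg=3)
    unfolded = np.polyval(coeffs, lam)
    d = np.diff(unfolded)
    d = d[d > 0]
    if d.size < 20:
        return np.nan, np.nan, int(d.size)
    d = d / d.mean()
    n_d = d.size
    n_bins = int(np.clip(n_d // 8, 5, 10))
    quantiles = np.arange(1, n_bins) / n_bins

    def chi2_p(inner_edges: np.ndarray) -> float:
        edges = np.concatenate([[0.0], inner_edges, [np.inf]])
        obs, _ = np.histogram(d, bins=edges)
        exp = n_d / n_bins
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, n_bins - 1))

    # Poisson law P(d) = exp(-d): quantile d = -ln(1 - q)
    p_pois = chi2_p(-np.log1p(-quantiles))
    # Wigner surmise (GOE): CDF = 1 - exp(-pi d^2/4): d = sqrt(-4 ln(1-q)/pi)
    p_goe = chi2_p(np.sqrt(-4.0 * np.log1p(-quantiles) / np.pi))
    return p_pois, p_goe, int(n_d)


def rmt_select_threshold(
    corr: CorrelationResult | pd.DataFrame | np.ndarray,
    grid=None,
    alpha: float = 0.05,
    min_run: int = 5,
) -> RmtScan:
    """Scan correlation thresholds and select by the RMT spacing transition.

    For each candidate threshold entries with |rho| below it are zeroed
    (diagonal kept) and the nearest-neighbour spacing distribution of the
    unfolded eigenvalues is tested against the Poisson law exp(-d) and the
    GOE Wigner surmise.  The selected threshold is the smallest grid point
    where the transition out of the random regime is complete — the Poisson
    fit accepted (p > ``alpha``) and the GOE fit rejected (p < ``alpha``) —
    sustained over >= ``min_run`` consecutive grid points.  The sustained-run
    requirement guards against isolated spurious acceptances in the dense
    (random-dominated) regime, where the chi-square statistic on a few dozen
    spacings is noisy.
    """
    if isinstance(corr, CorrelationResult):
        rho = corr.rho.to_numpy(dtype=float)
    elif isinstance(corr, pd.DataFrame):
        rho = corr.to_numpy(dtype=float)
    else:
        rho = np.asarray(corr, dtype=float)
    if rho.shape[0] != rho.shape[1]:
        raise ValidationError("correlation matrix must be square")
    m = rho.shape[0]
    if m < 20:
        raise ValidationError(
            "RMT spacing statistics need at least 20 retained OTUs"
        )
    rho = np.where(np.isnan(rho), 0.0, rho)
    off = rho[~np.eye(m, dtype=bool)]
    if np.ptp(off) == 0 and np.ptp(np.diag(rho)) == 0:
        raise RmtSelectionError(
            "insufficient spectral variation (degenerate correlation matrix)"
        )
    if grid is None:
        grid = np.round(np.arange(0.30, 0.99 + 1e-9, 0.01), 2)
    grid = np.asarray(grid, dtype=float)

    pois = np.full(grid.shape, np.nan)
    goe = np.full(grid.shape, np.nan)
    nsp = np.zeros(grid.shape, dtype=int)
    for k, st in enumerate(grid):
        a = np.where(np.abs(rho) >= st, rho, 0.0)
        np.fill_diagonal(a, 1.0)
        eig = np.linalg.eigvalsh(a)
        pois[k], goe[k], nsp[k] = _spacing_pvalues(eig)

    accepted = (np.nan_to_num(pois, nan=-1.0) > alpha) & (
        np.nan_to_num(goe, nan=1.0) < alpha
    )
    selected = None
    for k in range(len(grid) - (min_run - 1)):
        if accepted[k : k + min_run].all():
            selected = float(grid[k])
            break
    if selected is None:
        raise RmtSelectionError(
            "no threshold on the grid passed the Poisson spacing test; "
            "set the threshold manually"
        )
    return RmtScan(
        thresholds=grid, poisson_chi2_p=pois, goe_chi2_p=goe,
        n_spacings=nsp, selected=selected,
    )


# ---------------------------------------------------------------------------
# Network construction and topology


def build_network(
    corr: CorrelationResult,
    threshold: float,
    fdr_alpha: float = 0.05,
    positive_only: bool = False,
    site: str | None = None,
) -> nx.Graph:
    """Connect OTU pairs with |rho| >= threshold AND q < fdr_alpha.

    Returns an undirected :class:`networkx.Graph` whose nodes are the OTUs
    with at least one edge; edge attributes ``rho``, ``q`` and ``weight``
    (signed rho).  Graph attributes record the threshold and site label.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    rho = corr.rho.to_numpy(dtype=float)
    q = corr.q.to_numpy(dtype=float)
    ids = corr.otu_ids
    m = len(ids)
    g = nx.Graph(threshold=float(threshold), fdr_alpha=float(fdr_alpha),
                 site=site or "")
    iu, ju = np.triu_indices(m, k=1)
    strength = np.abs(rho[iu, ju])
    ok = (~np.isnan(strength)) & (strength >= threshold) & (q[iu, ju] < fdr_alpha)
    if positive_only:
        ok &= rho[iu, ju] > 0
    for i, j in zip(iu[ok], ju[ok]):
        r = float(rho[i, j])
        g.add_edge(ids[i], ids[j], rho=r, q=float(q[i, j]), weight=r)
    return g


@dataclass(frozen=True)
class TopologySummary:
    node_number: int
    edge_number: int
    betweenness: float  # mean normalized node betweenness
    assortativity: float  # NaN when undefined (degree-regular graph)
    transitivity: float
    degree: float  # mean degree
    modularity: float | None = None

    def as_dict(self) -> dict:
        return {
            "node_number": self.node_number,
            "edge_number": self.edge_number,
            "betweenness": self.betweenness,
            "assortativity": self.assortativity,
            "transitivity": self.transitivity,
            "degree": self.degree,
            "modularity": self.modularity,
        }


def global_topology(net: nx.Graph, modularity: bool = False) -> TopologySummary:
    """Whole-network topology summary.

    Betweenness uses unweighted shortest paths with the standard
    (n-1)(n-2)/2 normalization and is averaged over nodes; assortativity is
    Newman's degree assortativity (NaN on degree-regular graphs);
    transitivity is 3 x triangles / connected triples.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, np.nan, np.nan, np.nan, np.nan, None)
    bet = float(np.mean(list(nx.betweenness_centrality(net, normalized=True).values())))
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    if e == 0 or np.ptp(degrees) == 0:
        assort = np.nan
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = float(nx.degree_assortativity_coefficient(net))
    trans = float(nx.transitivity(net))
    mod = None
    if modularity and e > 0:
        communities = nx.community.greedy_modularity_communities(net)
        mod = float(nx.community.modularity(net, communities))
    return TopologySummary(n, e, bet, assort, trans, float(degrees.mean()), mod)


def sample_subgraph_topology(net: nx.Graph, table: OtuTable) -> pd.DataFrame:
    """Per-sample topology of the subgraph induced by OTUs present (>0).

    Samples whose induced subgraph is empty get a row of NaNs.  Columns are
    the four per-sample complexity metrics (node_number, edge_number,
    betweenness, assortativity) plus transitivity and mean degree.
    """
    nodes = [o for o in net.nodes if o in table.counts.columns]
    rows = []
    for sid in table.sample_ids:
        present = [o for o in nodes if table.counts.at[sid, o] > 0]
        sub = net.subgraph(present)
        if sub.number_of_nodes() == 0:
            rows.append({"sample_id": sid, "node_number": np.nan,
                         "edge_number": np.nan, "betweenness": np.nan,
                         "assortativity": np.nan, "transitivity": np.nan,
                         "degree": np.nan})
            continue
        topo = global_topology(sub)
        rows.append({"sample_id": sid, **{k: v for k, v in topo.as_dict().items()
                                          if k != "modularity"}})
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


@dataclass(frozen=True)
class KeystoneThresholds:
    """Fixed centrality cutoffs defining potential keystone OTUs."""

    degree_min: float = 6.0  # strict >
    weighted_degree_min: float = 6.0  # strict >
    closeness_min: float = 0.14  # strict >
    betweenness_max: float = 0.05  # strict <
    transitivity_min: float = 0.09  # strict >


def identify_keystones(
    net: nx.Graph, thresholds: KeystoneThresholds = KeystoneThresholds()
) -> pd.DataFrame:
    """Per-node centralities and the keystone flag.

    A node is flagged keystone when degree > 6, weighted degree (sum of
    |rho| over incident edges) > 6, closeness centrality > 0.14,
    betweenness centrality < 0.05 and local transitivity (clustering
    coefficient) > 0.09 (all strict, defaults).  Closeness is harmonic
    closeness normalized by n-1 so it is defined on disconnected graphs;
    betweenness is normalized by (n-1)(n-2)/2.
    """
    nodes = list(net.nodes)
    if not nodes:
        return pd.DataFrame(
            columns=["otu_id", "degree", "weighted_degree", "closeness",
                     "betweenness_centrality", "transitivity", "keystone"]
        ).set_index(pd.Index([], name="otu_id"))
    n = len(nodes)
    degree = dict(net.degree())
    wdeg = {
        u: float(sum(abs(d.get("rho", d.get("weight", 1.0)))
                     for _, _, d in net.edges(u, data=True)))
        for u in nodes
    }
    harmonic = nx.harmonic_centrality(net)
    closeness = {u: harmonic[u] / (n - 1) if n > 1 else 0.0 for u in nodes}
    betw = nx.betweenness_centrality(net, normalized=True)
    clust = nx.clustering(net)
    t = thresholds
    rows = []
    for u in nodes:
        flag = (
            degree[u] > t.degree_min
            and wdeg[u] > t.weighted_degree_min
            and closeness[u] > t.closeness_min
            and betw[u] < t.betweenness_max
            and clust[u] > t.transitivity_min
        )
        rows.append({
            "otu_id": u, "degree": degree[u], "weighted_degree": wdeg[u],
            "closeness": closeness[u], "betweenness_centrality": betw[u],
            "transitivity": clust[u], "keystone": bool(flag),
        })
    return pd.DataFrame(rows).set_index("otu_id", drop=False)
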