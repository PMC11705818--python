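"""Fungal–bacterial co-occurrence networks via random matrix theory.

The correlation matrix of prevalence-filtered differential taxa is
thresholded at the smallest cutoff for which the masked matrix's
nearest-neighbor eigenvalue spacing distribution (NNSD) follows the
Poisson law P(s) = e^(−s) — the random-matrix-theory signature of
uncorrelated modules, as opposed to the Wigner (GOE) spacing of dense
correlated structure. Surviving edges are pruned of indirect
(transitive) associations by network deconvolution, and the resulting
graph is summarized with the Cytoscape-style topology panel (average
neighbors, density, characteristic path length, heterogeneity, Freeman
degree centralization, hubs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .tables import AbundanceTable


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    density: float
    char_path_length: float
    heterogeneity: float
    centralization: float | None  # undefined for N < 3
    top_hubs: list[tuple[str, int, str]]  # (node, degree, kingdom)


@dataclass
class CoNetwork:
    """Thresholded, undirected association graph (each edge stored once
    with i < j)."""

    nodes: dict[str, str]  # node id -> kingdom label
    edges: list[tuple[str, str, float]]  # (i, j, weight), i < j
    threshold: float = 0.0
    metrics: TopologyMetrics | None = None

    def __post_init__(self) -> None:
        seen = set()
        norm = []
        for i, j, w in self.edges:
            if i == j:
                raise ValueError(f"self-loop on {i}")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                raise ValueError(f"duplicate edge {a}-{b}")
            seen.add((a, b))
            norm.append((a, b, float(w)))
        self.edges = sorted(norm)

    @property
    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for i, j, _ in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold)
        deg = self.degree
        for n, kingdom in self.nodes.items():
            g.add_node(n, kingdom=kingdom, degree=deg[n])
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=w, sign="+" if w >= 0 else "-")
        return g


def prevalence_filter(table: AbundanceTable, min_prev: float = 0.10) -> AbundanceTable:
    """Keep taxa detected (abundance > 0) in strictly more than
    ``min_prev`` of the samples."""
    prev = (table.data > 0).mean(axis=0)
    keep = list(prev.index[prev > min_prev])
    return table.subset_taxa(keep)


def correlation_matrix(
    table: AbundanceTable, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise taxon correlations (midranks for ties), diagonal forced
    to 1; zero-variance taxa get zero correlations with a warning."""
    if len(table.samples) < 10:
        raise ValueError("need at least 10 samples for stable correlations")
    x = table.data.to_numpy()
    if method == "spearman":
        x = stats.rankdata(x, axis=0)  # midranks for ties
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    zero_var = x.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance taxa: correlations set to 0",
            stacklevel=2,
        )
        r[zero_var, :] = 0.0
        r[:, zero_var] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=table.taxa, columns=table.taxa)


def _unfolded_spacings(eigenvalues: np.ndarray, n_knots: int | None = None) -> np.ndarray:
    """Unfold a spectrum and return spacings normalized to unit mean.

    The smooth cumulative spectral function is a monotone (PCHIP) cubic
    fit to the empirical CDF at ~n/10 evenly spaced knots, floored at 8:
    below that the fit is too stiff to absorb the global level density of
    small modular spectra and the test wrongly rejects Poisson on them.
    Eigenvalues are mapped through the fit and successive differences are
    rescaled to mean 1.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    scale = max(1.0, np.abs(lam).max())
    # duplicates removed up to numerical noise (exact multiplicities come
    # out of eigh perturbed at machine precision)
    keep = np.concatenate(([True], np.diff(lam) > 1e-9 * scale))
    lam = lam[keep]
    n = lam.size
    if n < 20:
        raise ValueError(f"only {n} distinct eigenvalues; need >= 20")
    if n_knots is None:
        n_knots = max(8, int(np.ceil(n / 10)))
    knot_idx = np.unique(np.linspace(0, n - 1, n_knots).round().astype(int))
    cdf = (np.arange(1, n + 1)) / n
    spline = PchipInterpolator(lam[knot_idx], cdf[knot_idx], extrapolate=True)
    unfolded = n * spline(lam)
    s = np.diff(np.sort(unfolded))
    s = s[s >= 0]
    mean = s.mean()
    if mean <= 0:
        raise ValueError("degenerate unfolded spectrum")
    return s / mean


def nnsd_poisson_pvalue(matrix, threshold: float) -> float:
    """Kolmogorov–Smirnov p-value of the masked matrix's NNSD against the
    Poisson law P(s) = e^(−s).

    Entries with |c| < threshold (off-diagonal) are zeroed before the
    eigendecomposition. High p ⇒ spacings exponential ⇒ remaining
    structure is modular noise; low p ⇒ level repulsion (GOE-like) ⇒ the
    threshold still admits correlated structure.
    """
    m = np.asarray(matrix, dtype=float).copy()
    mask = np.abs(m) < threshold
    np.fill_diagonal(mask, False)
    m[mask] = 0.0
    lam = np.linalg.eigvalsh((m + m.T) / 2)
    s = _unfolded_spacings(lam)
    return float(stats.kstest(s, "expon").pvalue)


def rmt_threshold(
    matrix,
    t_min: float = 0.30,
    t_max: float = 0.99,
    step: float = 0.01,
    p_cut: float = 0.05,
    stability_steps: int = 2,
) -> float:
    """Smallest threshold whose masked correlation matrix has a Poisson
    NNSD and stays Poisson for the next ``stability_steps`` scan steps.

    Falls back to ``t_max`` with a warning when no threshold in the scan
    range passes.
    """
    m = np.asarray(matrix, dtype=float)
    thresholds = np.arange(t_min, t_max + step / 2, step)
    pvals: dict[int, float | None] = {}

    def p_at(i: int) -> float | None:
        if i not in pvals:
            try:
                pvals[i] = nnsd_poisson_pvalue(m, float(thresholds[i]))
            except ValueError:
                pvals[i] = None
        return pvals[i]

    for i in range(len(thresholds)):
        p = p_at(i)
        if p is None or p < p_cut:
            continue
        stable = True
        for di in range(1, stability_steps + 1):
            if i + di >= len(thresholds):
                break
            p_next = p_at(i + di)
            if p_next is None or p_next < p_cut:
                stable = False
                break
        if stable:
            return float(thresholds[i])
    warnings.warn(
        "no threshold in scan range satisfied the Poisson criterion; "
        "returning t_max",
        stacklevel=2,
    )
    return float(thresholds[-1])


def threshold_network(
    corr: pd.DataFrame,
    threshold: float,
    kingdoms: dict[str, str] | None = None,
) -> CoNetwork:
    """Mask a correlation matrix at |r| ≥ threshold into a CoNetwork."""
    taxa = list(corr.index)
    kingdoms = kingdoms or {}
    edges = []
    r = corr.to_numpy()
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            if abs(r[a, b]) >= threshold:
                edges.append((taxa[a], taxa[b], float(r[a, b])))
    nodes = {t: kingdoms.get(t, "unknown") for t in taxa}
    return CoNetwork(nodes=nodes, edges=edges, threshold=threshold)


def remove_indirect_edges(net: CoNetwork, beta: float = 0.9) -> CoNetwork:
    """Prune spurious associations from a thresholded network.

    Three steps: (1) self-loops cannot exist by construction; (2) edges
    with |weight| ≥ 0.999 are flagged pathological and removed; (3) per
    connected component, network deconvolution S = G'·(I + G')^(−1)
    separates direct from transitive (indirect-path) contributions
    (G' = S + S·G': observed = direct + direct-through-observed paths),
    where G' = αG has its spectrum scaled into (−beta, beta) — the
    closed form diverges as the smallest eigenvalue approaches −1, which
    any dense module induces. S is rescaled so its largest off-diagonal
    magnitude matches G's (off-diagonal, because S's diagonal is not an
    edge and grows large for dense modules) and edges whose |S| falls
    below the network threshold are dropped. The output edge set is
    always a subset of the input's. A singular (I + G') falls back to
    steps 1–2.
    """
    edges = [(i, j, w) for i, j, w in net.edges if abs(w) < 0.999]
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_weighted_edges_from(edges)
    keep: list[tuple[str, str, float]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        comp_set = set(comp)
        sub_edges = [(i, j, w) for i, j, w in edges if i in comp_set]
        if len(comp) < 3:
            keep.extend(sub_edges)
            continue
        idx = {n: a for a, n in enumerate(comp)}
        gm = np.zeros((len(comp), len(comp)))
        for i, j, w in sub_edges:
            gm[idx[i], idx[j]] = w
            gm[idx[j], idx[i]] = w
        try:
            lam_abs_max = np.abs(np.linalg.eigvalsh(gm)).max()
            alpha = beta / lam_abs_max if lam_abs_max > beta else 1.0
            gs = alpha * gm
            s = gs @ np.linalg.inv(np.eye(len(comp)) + gs)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular (I+G) in deconvolution; component left unpruned",
                stacklevel=2,
            )
            keep.extend(sub_edges)
            continue
        s = (s + s.T) / 2
        off = ~np.eye(len(comp), dtype=bool)
        smax = np.abs(s[off]).max()
        if smax > 0:
            s = s * (np.abs(gm[off]).max() / smax)
        for i, j, w in sub_edges:
            # 1e-9 guards edges that sit exactly on the threshold
            if abs(s[idx[i], idx[j]]) >= net.threshold - 1e-9:
                keep.append((i, j, w))
    return CoNetwork(nodes=dict(net.nodes), edges=keep, threshold=net.threshold)


def topology(net: CoNetwork, n_hubs: int = 10) -> TopologyMetrics:
    """Whole-network topology panel.

    Characteristic path length averages unweighted shortest paths over
    connected pairs only; heterogeneity is sd(k)/mean(k) (population sd);
    centralization is Freeman degree centralization,
    (N/(N−2))·(k_max/(N−1) − density), undefined below 3 nodes.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    deg = np.array([d for _, d in g.degree()], dtype=float) if n else np.array([])
    avg_neighbors = 2 * e / n if n else 0.0
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    total, pairs = 0.0, 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, L in lengths.items():
            if dst != src:
                total += L
                pairs += 1
    cpl = total / pairs if pairs else 0.0
    het = float(deg.std() / deg.mean()) if n and deg.mean() > 0 else 0.0
    if n >= 3:
        centralization = (n / (n - 2)) * (deg.max() / (n - 1) - density)
        centralization = float(centralization)
    else:
        centralization = None
    hubs = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))[:n_hubs]
    top_hubs = [(str(node), int(k), net.nodes[node]) for node, k in hubs]
    return TopologyMetrics(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=float(avg_neighbors),
        density=float(density),
        char_path_length=float(cpl),
        heterogeneity=het,
        centralization=centralization,
        top_hubs=top_hubs,
    )


def build_network(
    table: AbundanceTable,
    diff_taxa: list[str],
    kingdoms: dict[str, str] | None = None,
    min_prev: float = 0.10,
    method: str = "spearman",
    prune_indirect: bool = True,
) -> CoNetwork:
    """Differential taxa → prevalence filter → correlations → RMT
    threshold → indirect-edge pruning → topology panel."""
    if not diff_taxa:
        raise ValueError("diff_taxa must not be empty")
    if kingdoms is None and table.kingdom is not None:
        kingdoms = table.kingdom.to_dict()
    sub = table.subset_taxa(diff_taxa)
    sub = prevalence_filter(sub, min_prev)
    if len(sub.taxa) < 20:
        raise ValueError(
            f"only {len(sub.taxa)} taxa after filters; RMT needs a spectrum "
            "(>= 20 taxa)"
        )
    corr = correlation_matrix(sub, method=method)
    thr = rmt_threshold(corr.to_numpy())
    net = threshold_network(corr, thr, kingdoms)
    if prune_indirect:
        net = remove_indirect_edges(net)
    net.metrics = topology(net)
    return net
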