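"""Co-occurrence network inference for denitrifier OTU tables.

Pipeline: prevalence filtering -> all-pairs Pearson correlation on
per-sample relative abundances -> |r| > 0.7 and parametric p < 0.05
candidate edges -> permutation and bootstrap edge validation (1,000
iterations by default) -> topology metrics, Louvain modules (labeled
I, II, III, ... by descending internal edge count) and keystone scoring
(nodes high in both degree and closeness centrality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import OtuTable

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def _roman(i: int) -> str:
    return ROMAN[i] if i < len(ROMAN) else f"M{i + 1}"


def prevalence_filter(table: OtuTable, design=None, mode: str = "strict") -> OtuTable:
    """Keep OTUs consistently present across replicates.

    ``strict``: nonzero count in every replicate of every treatment (i.e.
    every sample). ``any-treatment``: nonzero in all replicates of at least
    one treatment (requires ``design`` to map samples to treatments).
    """
    present = table.counts > 0
    if mode == "strict":
        keep = present.all(axis=1)
    elif mode == "any-treatment":
        if design is None:
            raise ValueError("any-treatment mode needs a StudyDesign")
        t_of = design.treatment_of()
        groups = present.T.groupby([t_of[s] for s in table.sample_ids]).all().T
        keep = groups.any(axis=1)
    else:
        raise ValueError(f"unknown prevalence mode {mode!r}")
    if not keep.any():
        warnings.warn("prevalence filter removed every OTU; network will be empty")
    return table.subset(table.counts.index[keep])


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def correlation_edges(table: OtuTable, r_threshold: float = 0.7,
                      alpha: float = 0.05, relative: bool = True) -> pd.DataFrame:
    """Candidate edges: all unordered OTU pairs with |r| > threshold, p < alpha.

    Correlations are computed on per-sample relative abundances by default
    (compositional convention). Zero-variance OTUs cannot be correlated and
    their pairs are skipped with a warning.
    """
    if table.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation edges")
    X = (table.relative_abundance() if relative else table.counts).to_numpy(dtype=float)
    ids = np.array(table.otu_ids)
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance OTU(s) skipped")
    ok = sd > 0
    Xv, idsv = X[ok], ids[ok]
    n = X.shape[1]
    if Xv.shape[0] < 2:
        return _empty_edges()
    r = np.corrcoef(Xv)
    p = _pearson_p(r, n)
    iu, ju = np.triu_indices(len(idsv), k=1)
    rows = pd.DataFrame({
        "otu_a": idsv[iu], "otu_b": idsv[ju],
        "r": r[iu, ju], "p_param": p[iu, ju],
    })
    cand = rows[(np.abs(rows["r"]) > r_threshold) & (rows["p_param"] < alpha)].copy()
    cand["sign"] = np.where(cand["r"] > 0, "+", "-")
    return cand.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["otu_a", "otu_b", "r", "p_param", "sign",
                                 "p_perm", "boot_support", "validated"])


def validate_edges(candidates: pd.DataFrame, table: OtuTable, n_iter: int = 1000,
                   support_threshold: float = 0.95, r_threshold: float = 0.7,
                   alpha: float = 0.05, boot_relax: float = 0.9,
                   relative: bool = True, seed: int = 0) -> pd.DataFrame:
    """Permutation + bootstrap validation of candidate edges.

    Per edge: permutation p = (1 + #{|r_perm| >= |r_obs|}) / (n_iter + 1)
    under shuffling of one OTU's sample order; bootstrap support = fraction
    of sample-resampled correlations with the observed sign and
    |r*| > boot_relax * r_threshold (the 10% relaxation keeps edges sitting
    exactly at the threshold from being penalized). An edge is validated iff
    |r| > r_threshold, p_param < alpha, p_perm <= alpha and
    support >= support_threshold.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives unstable permutation p resolution")
    out = candidates.copy()
    if out.empty:
        return _empty_edges()
    rng = np.random.default_rng(seed)
    X = (table.relative_abundance() if relative else table.counts)
    n = X.shape[1]
    p_perm = np.empty(len(out))
    support = np.empty(len(out))
    boot_bound = boot_relax * r_threshold
    for k, row in enumerate(out.itertuples()):
        a = X.loc[row.otu_a].to_numpy(dtype=float)
        b = X.loc[row.otu_b].to_numpy(dtype=float)
        r_obs = row.r
        perm_idx = np.argsort(rng.random((n_iter, n)), axis=1)
        r_perm = _row_corr(a[np.newaxis, :], b[perm_idx])
        p_perm[k] = (1 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n_iter + 1)
        boot_idx = rng.integers(0, n, size=(n_iter, n))
        with np.errstate(invalid="ignore"):
            r_boot = _row_corr(a[boot_idx], b[boot_idx])
        good = np.isfinite(r_boot) & (np.sign(r_boot) == np.sign(r_obs)) \
            & (np.abs(r_boot) > boot_bound)
        support[k] = good.mean()
    out["p_perm"] = p_perm
    out["boot_support"] = support
    out["validated"] = ((np.abs(out["r"]) > r_threshold) & (out["p_param"] < alpha)
                        & (out["p_perm"] <= alpha) & (out["boot_support"] >= support_threshold))
    return out


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between broadcastable 2-D arrays."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def build_graph(edges: pd.DataFrame, genus: pd.Series | None = None,
                validated_only: bool = True) -> nx.Graph:
    """Unweighted undirected graph from an edge frame (validated edges only
    by default); nodes are the edge endpoints, annotated with genus."""
    g = nx.Graph()
    rows = edges[edges["validated"]] if validated_only and "validated" in edges else edges
    for row in rows.itertuples():
        g.add_edge(row.otu_a, row.otu_b, r=float(row.r), p_param=float(row.p_param),
                   p_perm=float(getattr(row, "p_perm", np.nan)),
                   boot_support=float(getattr(row, "boot_support", np.nan)),
                   sign=row.sign)
    if genus is not None:
        for node in g.nodes:
            g.nodes[node]["genus"] = str(genus.get(node, "unclassified"))
    return g


def degree_centralization(graph: nx.Graph) -> float | None:
    """Freeman degree centralization: sum(dmax - d_i) / ((N-1)(N-2))."""
    n = graph.number_of_nodes()
    if n < 3:
        return None
    degrees = np.array([d for _, d in graph.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def topology(graph: nx.Graph) -> dict:
    """Topology summary of an unweighted, undirected network.

    Average path length is taken over the largest connected component;
    an empty graph reports every metric as missing.
    """
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        return {"n_nodes": 0, "n_edges": 0, "average_degree": None,
                "average_clustering": None, "average_path_length": None,
                "closeness": {}, "degree_centralization": None}
    closeness = nx.closeness_centrality(graph)
    largest_cc = max(nx.connected_components(graph), key=len)
    apl = (nx.average_shortest_path_length(graph.subgraph(largest_cc))
           if len(largest_cc) > 1 else None)
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n,
        "average_clustering": nx.average_clustering(graph),
        "average_path_length": apl,
        "closeness": closeness,
        "degree_centralization": degree_centralization(graph),
    }


def _partitions(items: list):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


def _exact_modularity_partition(graph: nx.Graph):
    best_q, best = -np.inf, None
    for part in _partitions(sorted(graph.nodes, key=str)):
        q = nx.community.modularity(graph, part)
        if q > best_q + 1e-12:
            best_q, best = q, part
    return best, best_q


def detect_modules(graph: nx.Graph, seed: int = 0, resolution: float = 1.0,
                   exact_max_nodes: int = 8) -> tuple[pd.Series, float]:
    """Modularity-maximizing modules relabeled I, II, ... by descending
    internal edge count.

    Graphs with at most ``exact_max_nodes`` nodes are solved by exhaustive
    search over all set partitions (the global modularity optimum); larger
    graphs use seeded Louvain. Ties are broken by node count (descending)
    then by the lexicographically smallest member. Disconnected singletons
    become their own trailing modules. Returns (node -> module label,
    modularity Q of the partition).
    """
    if graph.number_of_nodes() == 0:
        return pd.Series(dtype=object), float("nan")
    if graph.number_of_edges() == 0:
        labels = pd.Series({n: _roman(i) for i, n in enumerate(sorted(graph.nodes))})
        return labels, 0.0
    if graph.number_of_nodes() <= exact_max_nodes:
        comms, q = _exact_modularity_partition(graph)
    else:
        comms = nx.community.louvain_communities(graph, seed=seed, resolution=resolution)
        q = nx.community.modularity(graph, comms)

    def internal_edges(c):
        return graph.subgraph(c).number_of_edges()

    ordered = sorted(comms, key=lambda c: (-internal_edges(c), -len(c), min(map(str, c))))
    mapping = {}
    for i, c in enumerate(ordered):
        for node in c:
            mapping[node] = _roman(i)
    return pd.Series(mapping), float(q)


@dataclass
class KeystoneReport:
    """Per-node centrality with the keystone call and thresholds used."""

    scores: pd.DataFrame          # node, degree, closeness, keystone
    keystones: list[str]
    degree_quantile: float
    closeness_quantile: float
    degree_cutoff: float
    closeness_cutoff: float


def identify_keystones(graph: nx.Graph, degree_quantile: float = 0.9,
                       closeness_quantile: float = 0.9) -> KeystoneReport:
    """Potential keystone taxa: nodes at or above both the degree and the
    closeness-centrality quantile thresholds within their own network.

    Quantile comparisons use ``>=`` so ties at the cutoff pass (a regular
    graph passes every node through the degree screen).
    """
    nodes = sorted(graph.nodes)
    if len(nodes) == 0:
        empty = pd.DataFrame(columns=["node", "degree", "closeness", "keystone"])
        return KeystoneReport(empty, [], degree_quantile, closeness_quantile,
                              float("nan"), float("nan"))
    if len(nodes) < 10:
        warnings.warn("fewer than 10 nodes; keystone quantile thresholds are degenerate")
    degree = np.array([graph.degree(n) for n in nodes], dtype=float)
    clo = nx.closeness_centrality(graph)
    closeness = np.array([clo[n] for n in nodes])
    d_cut = float(np.quantile(degree, degree_quantile))
    c_cut = float(np.quantile(closeness, closeness_quantile))
    keystone = (degree >= d_cut) & (closeness >= c_cut)
    scores = pd.DataFrame({"node": nodes, "degree": degree,
                           "closeness": closeness, "keystone": keystone})
    return KeystoneReport(scores, [n for n, k in zip(nodes, keystone) if k],
                          degree_quantile, closeness_quantile, d_cut, c_cut)


@dataclass
class ValidatedNetwork:
    """A validated co-occurrence network plus its derived summaries."""

    gene_tag: str | None
    graph: nx.Graph
    edges: pd.DataFrame
    topology: dict
    modules: pd.Series
    modularity: float
    keystones: KeystoneReport | None = None

    def module_members(self, label: str) -> list[str]:
        return sorted(self.modules.index[self.modules == label])


class CooccurrenceNetwork(BaseEstimator):
    """Estimator wrapping the full per-gene network pipeline.

    ``fit`` takes an :class:`~denitnet.io.OtuTable` (optionally a
    :class:`~denitnet.design.StudyDesign` for the any-treatment prevalence
    mode) and exposes the fitted network through trailing-underscore
    attributes.

    Parameters
    ----------
    prevalence : "strict", "any-treatment" or None (no filtering).
    r_threshold, alpha : candidate-edge thresholds (|r| > 0.7, p < 0.05).
    validate : run the permutation/bootstrap edge validation.
    n_iter : resampling iterations (1,000 as in the field protocol).
    support_threshold, boot_relax : bootstrap retention rule.
    degree_quantile, closeness_quantile : keystone screen.
    seed : RNG seed for validation and module detection.

    Attributes (after fit)
    ----------------------
    filtered_table_, candidates_, edges_, graph_, topology_, modules_,
    modularity_, keystones_, network_
    """

    def __init__(self, prevalence: str | None = "strict", r_threshold: float = 0.7,
                 alpha: float = 0.05, relative: bool = True, validate: bool = True,
                 n_iter: int = 1000, support_threshold: float = 0.95,
                 boot_relax: float = 0.9, degree_quantile: float = 0.9,
                 closeness_quantile: float = 0.9, seed: int = 0):
        self.prevalence = prevalence
        self.r_threshold = r_threshold
        self.alpha = alpha
        self.relative = relative
        self.validate = validate
        self.n_iter = n_iter
        self.support_threshold = support_threshold
        self.boot_relax = boot_relax
        self.degree_quantile = degree_quantile
        self.closeness_quantile = closeness_quantile
        self.seed = seed

    def fit(self, table: OtuTable, design=None):
        filtered = (prevalence_filter(table, design, self.prevalence)
                    if self.prevalence else table)
        cand = correlation_edges(filtered, self.r_threshold, self.alpha, self.relative) \
            if filtered.shape[0] >= 2 and filtered.shape[1] >= 4 else _empty_edges()
        if self.validate and not cand.empty:
            edges = validate_edges(cand, filtered, n_iter=self.n_iter,
                                   support_threshold=self.support_threshold,
                                   r_threshold=self.r_threshold, alpha=self.alpha,
                                   boot_relax=self.boot_relax, relative=self.relative,
                                   seed=self.seed)
        else:
            edges = cand.copy()
            edges["p_perm"] = np.nan
            edges["boot_support"] = np.nan
            edges["validated"] = True if not cand.empty else pd.Series(dtype=bool)
        graph = build_graph(edges, genus=filtered.genus)
        modules, q = detect_modules(graph, seed=self.seed)
        for node in graph.nodes:
            graph.nodes[node]["module"] = str(modules.get(node, ""))
        keystones = identify_keystones(graph, self.degree_quantile,
                                       self.closeness_quantile)
        for node in graph.nodes:
            graph.nodes[node]["keystone"] = node in set(keystones.keystones)
        self.filtered_table_ = filtered
        self.candidates_ = cand
        self.edges_ = edges
        self.graph_ = graph
        self.topology_ = topology(graph)
        self.modules_ = modules
        self.modularity_ = q
        self.keystones_ = keystones
        self.network_ = ValidatedNetwork(table.gene_tag, graph, edges,
                                         self.topology_, modules, q, keystones)
        return self
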