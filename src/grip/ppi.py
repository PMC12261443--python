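"""Physical PPI network: construction, distances, and the proximity test.

The working hypothesis is that TFs regulating the same target gene sit
closer to each other in a physical protein–protein interaction network
than randomly chosen TFs. This module builds the network from an edge
table restricted to physical interactions, computes shortest-path hop
distances and the diffusion state distance (DSD) — the L1 distance
between expected random-walk visit-count vectors — and runs a one-sided
Mann–Whitney U test comparing within-regulon distances to a background
distribution of TF pair distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb
from scipy.stats import norm, rankdata


def _normalize_symbol(s: object) -> str:
    return str(s).strip().upper()


@dataclass
class PPINetwork:
    """Undirected simple graph of physical protein–protein interactions.

    Nodes are uppercase gene symbols; edges carry the tag ``"physical"``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree())


@dataclass
class DSDMatrix:
    """Diffusion state distances between proteins of one connected component.

    ``D[i, j]`` is the L1 distance between the t-step expected visit-count
    vectors of nodes i and j under a simple random walk; ``n_steps`` is the
    walk horizon (-1 marks the converged, infinite-horizon variant).
    """

    node_ids: list[str]
    D: np.ndarray
    n_steps: int

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("DSD matrix shape does not match node_ids")
        self._index = {s: i for i, s in enumerate(self.node_ids)}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def loc(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.node_ids, columns=self.node_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_steps: int = -1) -> "DSDMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("DSD table must have identical row and column labels")
        return cls(node_ids=[str(s) for s in df.index], D=df.to_numpy(dtype=float),
                   n_steps=n_steps)


@dataclass
class ProximityTestResult:
    """Tie-corrected Mann–Whitney U result for the proximity hypothesis."""

    u_statistic: float
    z_score: float
    p_value: float
    n_regulon_pairs: int
    n_background_pairs: int


def load_ppi(edge_table) -> PPINetwork:
    """Build a physical-interaction network from an edge table.

    Parameters
    ----------
    edge_table
        A path to a headered TSV with columns ``symbol_a``, ``symbol_b``,
        ``interaction_type``; a DataFrame with three such columns; or an
        iterable of ``(symbol_a, symbol_b, interaction_type)`` rows.

    Only rows whose type equals ``"physical"`` (case-insensitive) are kept;
    self-loops and duplicate edges are dropped. Symbols are uppercased and
    whitespace-stripped, so mixed-case duplicates collapse to one node.
    """
    if isinstance(edge_table, (str, Path)):
        df = pd.read_csv(edge_table, sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise ValueError("PPI edge table needs >= 3 columns "
                             "(symbol_a, symbol_b, interaction_type)")
        rows = df.iloc[:, :3].itertuples(index=False, name=None)
    elif isinstance(edge_table, pd.DataFrame):
        if edge_table.shape[1] < 3:
            raise ValueError("PPI edge table needs >= 3 columns")
        rows = edge_table.iloc[:, :3].itertuples(index=False, name=None)
    else:
        rows = edge_table

    g = nx.Graph()
    n_rows = 0
    for lineno, row in enumerate(rows, start=1):
        try:
            a, b, kind = row[0], row[1], row[2]
        except (TypeError, IndexError) as exc:
            raise ValueError(f"malformed PPI row at line {lineno}: {row!r}") from exc
        a, b = _normalize_symbol(a), _normalize_symbol(b)
        if not a or not b or a in ("NAN", "NONE") or b in ("NAN", "NONE"):
            raise ValueError(f"malformed PPI row at line {lineno}: empty symbol")
        n_rows += 1
        if str(kind).strip().lower() != "physical":
            continue
        if a == b:
            continue
        g.add_edge(a, b, interaction_type="physical")

    if g.number_of_edges() == 0:
        raise ValueError("no physical interactions in edge table")
    return PPINetwork(graph=g)


def shortest_path_distances(net: PPINetwork, sources: Sequence[str]) -> pd.DataFrame:
    """Unweighted BFS hop counts from each source to every node.

    Returns a DataFrame indexed by ``sources`` with one column per network
    node; unreachable pairs are NaN (missing), never an infinity sentinel.
    """
    nodes = sorted(net.graph.nodes)
    for s in sources:
        if s not in net.graph:
            raise KeyError(f"source {s!r} is not in the PPI network")
    out = pd.DataFrame(np.nan, index=list(sources), columns=nodes, dtype=float)
    for s in set(sources):
        lengths = nx.single_source_shortest_path_length(net.graph, s)
        row = pd.Series(lengths, dtype=float).reindex(nodes)
        out.loc[out.index == s, :] = row.to_numpy()
    return out


def _transition_matrix(g: nx.Graph, nodes: list[str]) -> np.ndarray:
    A = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated node in component; cannot form random walk")
    return A / deg[:, None]


def dsd_matrix(net: PPINetwork, n_steps: int = 7, converged: bool = False,
               component: str = "all") -> DSDMatrix:
    """Diffusion state distance matrix of the network.

    Finite-horizon form: with row-stochastic transition matrix P from the
    unweighted adjacency, the diffusion state of node v is
    ``He_t(v) = sum_{i=0..t} e_v^T P^i`` and
    ``D[u, v] = || He_t(u) - He_t(v) ||_1``. The converged variant uses the
    closed form ``||(e_u - e_v)(I - P + W)^{-1}||_1`` with ``W = 1 pi^T``
    built from the stationary distribution pi (degree / 2|E|).

    Random-walk distances are undefined across components, so the graph
    must be connected; pass ``component="largest"`` to restrict to the
    largest connected component instead of erroring.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(g):
        if component == "largest":
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        else:
            raise ValueError(
                "network is disconnected; pass component='largest' to use "
                "the largest connected component")
    if not converged and n_steps < 1:
        raise ValueError("n_steps must be >= 1 (or set converged=True)")

    nodes = sorted(g.nodes)
    P = _transition_matrix(g, nodes)
    n = len(nodes)
    if converged:
        deg = nx.to_numpy_array(g, nodelist=nodes).sum(axis=1)
        pi = deg / deg.sum()
        W = np.ones((n, 1)) @ pi[None, :]
        H = np.linalg.inv(np.eye(n) - P + W)
        steps = -1
    else:
        H = np.eye(n)
        Pi = np.eye(n)
        for _ in range(n_steps):
            Pi = Pi @ P
            H = H + Pi
        steps = n_steps
    D = squareform(pdist(H, metric="cityblock"))
    np.fill_diagonal(D, 0.0)
    return DSDMatrix(node_ids=nodes, D=D, n_steps=steps)


def distance_submatrix(dsd: DSDMatrix, tf_ids: Sequence[str],
                       missing_policy: str = "error"
                       ) -> tuple[np.ndarray, list[str], list[str]]:
    """Slice the pairwise TF distance matrix S aligned to ``tf_ids``.

    TFs absent from the DSD matrix are handled per ``missing_policy``:
    ``error`` raises naming the symbol, ``max_fill`` fills their row/column
    with the largest observed DSD value (diagonal stays 0), ``drop``
    removes them. Returns ``(S, kept_ids, dropped_ids)``.
    """
    if missing_policy not in ("error", "max_fill", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    tf_ids = [str(t) for t in tf_ids]
    missing = [t for t in tf_ids if t not in dsd]
    if missing and missing_policy == "error":
        raise KeyError(f"TF(s) absent from DSD matrix: {', '.join(missing)}")

    if missing_policy == "drop":
        kept = [t for t in tf_ids if t in dsd]
        idx = [dsd._index[t] for t in kept]
        S = dsd.D[np.ix_(idx, idx)].copy()
        return S, kept, missing

    # max_fill (or no missing at all)
    n = len(tf_ids)
    S = np.zeros((n, n))
    fill = float(dsd.D.max()) if missing else 0.0
    for i, a in enumerate(tf_ids):
        for j, b in enumerate(tf_ids):
            if i == j:
                continue
            if a in dsd and b in dsd:
                S[i, j] = dsd.loc(a, b)
            else:
                S[i, j] = fill
    return S, tf_ids, missing


# --- Mann–Whitney U with tie correction -----------------------------------

_EXACT_MAX_N = 12  # enumerate C(N, n_a) rank subsets below this pooled size


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float],
                   alternative: str = "less") -> ProximityTestResult:
    """One-sided Mann–Whitney U test that ``sample_a`` is stochastically smaller.

    Ranks are midranks; the z-score uses the tie-corrected variance. On
    small tie-free samples the p-value is the exact permutation tail
    probability P(U <= U_obs); otherwise the normal approximation is used.
    """
    if alternative != "less":
        raise ValueError("only alternative='less' is supported")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate (all ties): every value identical")

    n_a, n_b = a.size, b.size
    N = n_a + n_b
    ranks = rankdata(pooled)  # midranks
    R_a = ranks[:n_a].sum()
    U_a = R_a - n_a * (n_a + 1) / 2.0

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    z = (U_a - mu) / math.sqrt(var)

    has_ties = np.any(tie_counts > 1)
    if N <= _EXACT_MAX_N and not has_ties:
        # exact permutation null: all C(N, n_a) assignments of ranks to a
        count = 0
        total = 0
        base = n_a * (n_a + 1) / 2.0
        for combo in itertools.combinations(ranks, n_a):
            u = sum(combo) - base
            if u <= U_a + 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(norm.cdf(z))
    return ProximityTestResult(u_statistic=float(U_a), z_score=float(z),
                               p_value=float(p),
                               n_regulon_pairs=int(n_a),
                               n_background_pairs=int(n_b))


def _pairwise_distances(tfs: Sequence[str], metric: str, net_or_dsd) -> list[float]:
    vals: list[float] = []
    tfs = sorted(set(tfs))
    if metric == "dsd":
        dsd: DSDMatrix = net_or_dsd
        present = [t for t in tfs if t in dsd]
        for x, y in itertools.combinations(present, 2):
            vals.append(dsd.loc(x, y))
    elif metric == "shortest_path":
        net: PPINetwork = net_or_dsd
        present = [t for t in tfs if t in net.graph]
        for x, y in itertools.combinations(present, 2):
            try:
                vals.append(float(nx.shortest_path_length(net.graph, x, y)))
            except nx.NetworkXNoPath:
                continue  # unreachable pair: missing, not infinite
    else:
        raise ValueError("metric must be 'dsd' or 'shortest_path'")
    return vals


def proximity_test(regulon_sets: Mapping[str, Iterable[str]],
                   background_tfs: Sequence[str],
                   metric: str = "dsd",
                   net_or_dsd=None) -> ProximityTestResult:
    """Test whether same-regulon TFs are closer than background TF pairs.

    Sample A pools all pairwise distances within each regulon (over all
    TGs); sample B holds all pairwise distances among ``background_tfs``.
    Returns the one-sided test that A is stochastically smaller than B.
    """
    sample_a: list[float] = []
    n_usable = 0
    for tg, tfs in regulon_sets.items():
        d = _pairwise_distances(list(tfs), metric, net_or_dsd)
        if d:
            n_usable += 1
            sample_a.extend(d)
    if n_usable == 0:
        raise ValueError("no regulon with >= 2 TFs mappable to the network")
    sample_b = _pairwise_distances(background_tfs, metric, net_or_dsd)
    if not sample_b:
        raise ValueError("background has no mappable TF pairs")
    res = mann_whitney_u(sample_a, sample_b, alternative="less")
    return ProximityTestResult(
        u_statistic=res.u_statistic, z_score=res.z_score, p_value=res.p_value,
        n_regulon_pairs=len(sample_a), n_background_pairs=len(sample_b))
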