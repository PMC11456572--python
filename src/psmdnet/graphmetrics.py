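"""Global topology of FN-weighted connectomes.

Weighted metric conventions (recorded in pipeline provenance):

* edge lengths are reciprocal normalized weights, shortest paths by Dijkstra;
* global efficiency is the mean inverse shortest-path length over ordered
  node pairs (0 for disconnected pairs);
* clustering is Onnela's geometric-mean-of-triangles form; local efficiency
  averages the efficiency of each node's neighbor-induced subgraph;
* gamma and lambda normalize clustering / characteristic path length by the
  means of a Maslov-Sneppen degree-preserving null ensemble with weights
  randomly permuted onto the rewired edges; sigma = gamma / lambda;
* assortativity is the Pearson correlation of endpoint strengths over edges;
* modularity is the best Louvain value over seeded restarts;
* hierarchy is the exponent beta in C ~ k^(-beta) across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix


@dataclass
class TopologyMetrics:
    Eg: float
    Eloc: float
    C: float
    Lp: float
    gamma: float
    lam: float
    sigma: float
    assortativity: float
    modularity: float
    hierarchy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Eg": self.Eg, "Eloc": self.Eloc, "gamma": self.gamma,
            "lambda": self.lam, "sigma": self.sigma,
            "assortativity": self.assortativity,
            "modularity": self.modularity, "hierarchy": self.hierarchy,
        }


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("diagonal must be zero")
    return W


def normalize_weights(W: np.ndarray) -> np.ndarray:
    """Scale weights into [0, 1] by the maximum entry."""
    W = _check_weights(W)
    m = W.max()
    if m <= 0:
        raise ValueError("all-zero weight matrix")
    return W / m


def distance_matrix(Wn: np.ndarray) -> np.ndarray:
    """Shortest-path distances over edge lengths 1/w (inf if disconnected)."""
    Wn = _check_weights(Wn)
    with np.errstate(divide="ignore"):
        L = np.where(Wn > 0, 1.0 / Wn, 0.0)
    return dijkstra(csr_matrix(L), directed=False)


def _efficiency(Wn: np.ndarray) -> float:
    """Mean inverse shortest-path length; tolerant of edgeless graphs."""
    n = Wn.shape[0]
    if n < 2:
        return 0.0
    D = distance_matrix(Wn)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(Wn: np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs; disconnected pairs contribute 0."""
    Wn = _check_weights(Wn)
    if Wn.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return _efficiency(Wn)


def characteristic_path_length(Wn: np.ndarray) -> float:
    """Mean shortest-path length over finite off-diagonal pairs."""
    D = distance_matrix(Wn)
    off = ~np.eye(D.shape[0], dtype=bool)
    finite = off & np.isfinite(D)
    if not finite.any():
        raise ValueError("no finite paths")
    return float(D[finite].mean())


def nodal_clustering(Wn: np.ndarray) -> np.ndarray:
    """Onnela per-node clustering: C_i = sum (w_ij w_ih w_jh)^(1/3) / k_i(k_i-1)."""
    Wn = _check_weights(Wn)
    cube = np.cbrt(Wn)
    t = np.diagonal(cube @ cube @ cube)  # 2x the geometric triangle count
    k = (Wn > 0).sum(axis=1)
    C = np.zeros(Wn.shape[0])
    mask = k >= 2
    C[mask] = t[mask] / (k[mask] * (k[mask] - 1.0))
    return C


def clustering_and_local_efficiency(Wn: np.ndarray) -> tuple[float, float]:
    """Mean clustering coefficient and local efficiency."""
    Wn = _check_weights(Wn)
    n = Wn.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    C = float(nodal_clustering(Wn).mean())
    eloc = 0.0
    for i in range(n):
        nb = np.flatnonzero(Wn[i] > 0)
        if len(nb) < 2:
            continue
        eloc += _efficiency(Wn[np.ix_(nb, nb)])
    return C, eloc / n


def _largest_component(Wn: np.ndarray) -> np.ndarray:
    D = distance_matrix(Wn)
    reach = np.isfinite(D)
    sizes = reach.sum(axis=1)
    comp = reach[int(np.argmax(sizes))]
    return Wn[np.ix_(comp, comp)]


def null_ensemble(
    Wn: np.ndarray,
    n_nulls: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
) -> list[np.ndarray]:
    """Degree-preserving rewired nulls with weights permuted onto edges."""
    Wn = _check_weights(Wn)
    G0 = nx.from_numpy_array(Wn)
    edges0 = list(G0.edges())
    weights = np.array([Wn[i, j] for i, j in edges0])
    degrees0 = sorted(d for _, d in G0.degree())
    rng = np.random.default_rng(seed)
    nulls = []
    m = len(edges0)
    for _ in range(n_nulls):
        G = nx.Graph()
        G.add_nodes_from(range(Wn.shape[0]))
        G.add_edges_from(edges0)
        if m > 1:
            try:
                nx.double_edge_swap(
                    G,
                    nswap=rewires_per_edge * m,
                    max_tries=100 * rewires_per_edge * m,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except nx.NetworkXAlgorithmError:
                pass  # few swappable pairs; keep the partially rewired graph
        assert sorted(d for _, d in G.degree()) == degrees0
        perm = rng.permutation(m)
        Wnull = np.zeros_like(Wn)
        for (i, j), w in zip(G.edges(), weights[perm]):
            Wnull[i, j] = Wnull[j, i] = w
        nulls.append(Wnull)
    return nulls


def normalized_metrics(
    Wn: np.ndarray,
    n_nulls: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """gamma = C/<C_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda.

    Uses the largest connected component if the graph is disconnected.
    """
    Wn = _check_weights(Wn)
    Wn = _largest_component(Wn)
    if Wn.shape[0] < 3:
        raise ValueError("largest component too small for normalized metrics")
    C = float(nodal_clustering(Wn).mean())
    Lp = characteristic_path_length(Wn)
    c_nulls = []
    l_nulls = []
    for Wnull in null_ensemble(Wn, n_nulls, rewires_per_edge, seed):
        c_nulls.append(float(nodal_clustering(Wnull).mean()))
        l_nulls.append(characteristic_path_length(Wnull))
    c_mean = float(np.mean(c_nulls))
    l_mean = float(np.mean(l_nulls))
    if c_mean <= 0:
        raise ValueError("degenerate null (zero mean clustering)")
    gamma = C / c_mean
    lam = Lp / l_mean
    return gamma, lam, gamma / lam


def assortativity(Wn: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over edges (both orientations)."""
    Wn = _check_weights(Wn)
    ii, jj = np.nonzero(np.triu(Wn, 1))
    if len(ii) < 2:
        raise ValueError("need at least 2 edges")
    s = Wn.sum(axis=1)
    x = np.concatenate([s[ii], s[jj]])
    y = np.concatenate([s[jj], s[ii]])
    vx = x.var()
    if vx <= 1e-30:
        raise ValueError("undefined assortativity (regular graph)")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / vx)
    return r


def modularity(Wn: np.ndarray, seed: int = 0, n_restarts: int = 10) -> float:
    """Maximum Newman Q over community partitions.

    Exact exhaustive search for graphs with up to 8 nodes (Bell(8) = 4140
    partitions); seeded Louvain restarts with greedy refinement beyond that.
    """
    Wn = _check_weights(Wn)
    if not (Wn > 0).any():
        raise ValueError("edgeless graph")
    if Wn.shape[0] <= 8:
        return _exact_modularity(Wn)
    G = nx.from_numpy_array(Wn)
    best = -np.inf
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        parts = _refine_partition(Wn, [set(p) for p in parts])
        q = nx.community.modularity(G, parts, weight="weight")
        best = max(best, q)
    return float(best)


def _exact_modularity(Wn: np.ndarray) -> float:
    """Maximize Q over all set partitions, enumerated as restricted growth
    strings (iterative, no recursion)."""
    n = Wn.shape[0]
    two_m = Wn.sum()
    s = Wn.sum(axis=1)
    a = np.zeros(n, dtype=int)  # restricted growth string
    b = np.zeros(n, dtype=int)  # running maxima
    best = -np.inf

    def q_of(member):
        q = 0.0
        for c in range(member.max() + 1):
            idx = member == c
            q += Wn[np.ix_(idx, idx)].sum() - s[idx].sum() ** 2 / two_m
        return q / two_m

    while True:
        best = max(best, q_of(a))
        # next restricted growth string
        j = n - 1
        while j > 0 and a[j] == b[j] + 1:
            j -= 1
        if j == 0:
            return float(best)
        a[j] += 1
        for k in range(j + 1, n):
            a[k] = 0
            b[k] = max(b[k - 1], a[k - 1])


def _partition_q(Wn: np.ndarray, member: np.ndarray) -> float:
    two_m = Wn.sum()
    s = Wn.sum(axis=1)
    q = 0.0
    for c in set(member.tolist()):
        idx = member == c
        q += Wn[np.ix_(idx, idx)].sum() - s[idx].sum() ** 2 / two_m
    return q / two_m


def _refine_partition(Wn: np.ndarray, parts: list[set]) -> list[set]:
    """Greedy refinement: single-node moves (including splitting a node off
    into its own community) and whole-community merges, until no move
    improves Q."""
    n = Wn.shape[0]
    member = np.zeros(n, dtype=int)
    for c, p in enumerate(parts):
        for i in p:
            member[i] = c
    two_m = Wn.sum()
    strength = Wn.sum(axis=1)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            ci = member[i]
            fresh = max(member) + 1  # singleton target
            best_dq, best_c = 0.0, ci
            for c in set(member.tolist()) | {fresh}:
                if c == ci:
                    continue
                w_new = Wn[i, member == c].sum()
                w_old = Wn[i, member == ci].sum()
                s_new = strength[member == c].sum()
                s_old = strength[member == ci].sum() - strength[i]
                dq = (w_new - w_old) / two_m * 2 - 2 * strength[i] * (
                    s_new - s_old
                ) / two_m**2
                if dq > best_dq + 1e-12:
                    best_dq, best_c = dq, c
            if best_c != ci:
                member[i] = best_c
                improved = True
        # community merges
        comms = sorted(set(member.tolist()))
        for a, b in ((a, b) for k, a in enumerate(comms) for b in comms[k + 1:]):
            wa = member == a
            wb = member == b
            dq = 2.0 * (
                Wn[np.ix_(wa, wb)].sum() / two_m
                - strength[wa].sum() * strength[wb].sum() / two_m**2
            )
            if dq > 1e-12:
                member[wb] = a
                improved = True
    out = [set(np.flatnonzero(member == c)) for c in sorted(set(member.tolist()))]
    return [p for p in out if p]


def hierarchy(Wn: np.ndarray) -> float:
    """Exponent beta of C_i ~ k_i^(-beta) by least squares in log-log space.

    Qualifying nodes have degree > 1 and positive clustering; requires at
    least 3 such nodes with non-constant degree.
    """
    Wn = _check_weights(Wn)
    k = (Wn > 0).sum(axis=1).astype(float)
    C = nodal_clustering(Wn)
    ok = (k > 1) & (C > 0)
    if ok.sum() < 3 or np.ptp(k[ok]) == 0:
        raise ValueError("hierarchy undefined (constant degrees or too few nodes)")
    logk = np.log(k[ok])
    logc = np.log(C[ok])
    slope = np.polyfit(logk, logc, 1)[0]
    return float(-slope)


def compute_topology(
    W: np.ndarray,
    n_nulls: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
) -> TopologyMetrics:
    """All eight global metrics of one connectome weight matrix."""
    Wn = normalize_weights(W)
    eg = global_efficiency(Wn)
    C, eloc = clustering_and_local_efficiency(Wn)
    Lp = characteristic_path_length(Wn)
    try:
        gamma, lam, sigma = normalized_metrics(Wn, n_nulls, rewires_per_edge, seed)
    except (ValueError, nx.NetworkXError):
        gamma = lam = sigma = float("nan")
    try:
        assort = assortativity(Wn)
    except ValueError:
        assort = float("nan")
    Q = modularity(Wn, seed=seed, n_restarts=n_restarts)
    try:
        beta = hierarchy(Wn)
    except ValueError:
        beta = float("nan")
    return TopologyMetrics(eg, eloc, C, Lp, gamma, lam, sigma, assort, Q, beta)
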