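"""Functional-connectome graph theory for case-control cohorts.

From a per-subject Fisher-z connectivity matrix the module builds a graph
at a target density by proportional thresholding around a maximum-weight
spanning-tree backbone (which guarantees a connected graph at every
density), then computes the global measures — transitivity, global
efficiency, Louvain modularity Q — normalized against degree-preserving
rewired null networks, plus the nodal participation coefficient aggregated
over a parcellation into modules. Group comparisons use permutation tests
with Bonferroni correction over densities for global metrics and
Benjamini-Hochberg FDR over parcellation modules for participation, and
module-level participation is correlated with g per group with FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed, substream

__all__ = [
    "ConnectivityMatrix",
    "ParcellationScheme",
    "ThresholdedGraph",
    "MetricProfile",
    "correlation_to_z",
    "mst_backbone",
    "threshold_at_density",
    "transitivity",
    "global_efficiency",
    "louvain_q",
    "participation_coefficient",
    "degree_preserving_null",
    "normalized_metrics",
    "density_sweep",
    "group_metric_tests",
    "pc_g_correlation",
    "global_table",
    "parcel_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z node x node matrix for one subject."""

    z: np.ndarray
    subject_id: str = ""
    group: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity matrix has non-finite entries")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric (tol 1e-10)")
        if np.any(np.abs(np.diag(z)) > 1e-12):
            raise ValueError("connectivity matrix must have zero diagonal")
        self.z = z

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def to_text(self, path) -> None:
        np.savetxt(path, self.z, fmt="%.8g")

    @classmethod
    def from_text(cls, path, subject_id: str = "", group: int = 0) -> "ConnectivityMatrix":
        return cls(z=np.loadtxt(path), subject_id=subject_id, group=group)


@dataclass
class ParcellationScheme:
    """Assignment of each node to one of >= 2 labelled modules."""

    module_of: np.ndarray

    def __post_init__(self) -> None:
        self.module_of = np.asarray(self.module_of)
        if len(self.modules) < 2:
            raise ValueError("parcellation needs at least 2 modules")

    @property
    def n_nodes(self) -> int:
        return len(self.module_of)

    @property
    def modules(self) -> list:
        return sorted(set(self.module_of.tolist()))

    def indicator(self) -> np.ndarray:
        """N x S binary membership matrix, module columns in sorted order."""
        mods = self.modules
        return (self.module_of[:, None] == np.asarray(mods)[None, :]).astype(float)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"node_index": np.arange(self.n_nodes), "module_label": self.module_of}
        ).to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcellationScheme":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["node_index", "module_label"])
        df = df.sort_values("node_index")
        if not np.array_equal(df["node_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("parcellation must cover node indices 0..N-1 exactly")
        return cls(module_of=df["module_label"].to_numpy())


@dataclass
class ThresholdedGraph:
    """Weighted adjacency at a target density containing its MST backbone."""

    adjacency: np.ndarray
    density: float
    backbone_edges: frozenset

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edge_set(self) -> frozenset:
        iu = np.triu_indices(self.n_nodes, 1)
        present = self.adjacency[iu] > 0
        return frozenset(zip(iu[0][present].tolist(), iu[1][present].tolist()))


@dataclass
class MetricProfile:
    """Per-subject global metrics and participation across densities."""

    subject_id: str
    group: int
    globals: pd.DataFrame          # indexed by density
    nodal_pc: pd.DataFrame         # density x node
    parcel_pc: pd.DataFrame        # density x module


# ---------------------------------------------------------------------------
# matrix -> graph
# ---------------------------------------------------------------------------

def correlation_to_z(corr, subject_id: str = "", group: int = 0) -> ConnectivityMatrix:
    """Fisher-z transform a correlation matrix; zero the diagonal."""
    C = np.asarray(corr, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    off = ~np.eye(C.shape[0], dtype=bool)
    if np.any(np.abs(C[off]) >= 1.0):
        raise ValueError("off-diagonal correlations must lie strictly in (-1, 1)")
    z = np.arctanh(np.where(off, C, 0.0))
    return ConnectivityMatrix(z=z, subject_id=subject_id, group=group)


def _weights(z) -> np.ndarray:
    return z.z if isinstance(z, ConnectivityMatrix) else np.asarray(z, dtype=float)


def _apply_negative_policy(W: np.ndarray, policy: str) -> np.ndarray:
    if policy == "zero":
        return np.where(W < 0, 0.0, W)
    if policy == "abs":
        return np.abs(W)
    if policy == "error":
        if np.any(W < 0):
            raise ValueError("negative connectivity entries present")
        return W.copy()
    raise ValueError(f"unknown negative_policy {policy!r}")


def mst_backbone(z) -> frozenset:
    """Maximum-weight spanning tree over all node pairs.

    Kruskal on edges sorted by (descending weight, node pair) — the
    lexicographic tie-break makes the tree deterministic. Equivalent to a
    minimum spanning tree under length = 1/weight.
    """
    W = _weights(z)
    N = W.shape[0]
    if N < 2:
        raise ValueError("need at least 2 nodes")
    iu, ju = np.triu_indices(N, 1)
    order = np.lexsort((ju, iu, -W[iu, ju]))
    parent = list(range(N))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == N - 1:
                break
    return frozenset(edges)


def threshold_at_density(
    z, density: float, negative_policy: str = "zero"
) -> ThresholdedGraph:
    """Proportional threshold with the spanning-tree backbone always kept.

    The edge budget is round(density * N(N-1)/2); the backbone's N-1 edges
    enter first, then the strongest remaining edges by weight (ties broken
    lexicographically). Weights are retained on surviving edges, so the
    graph is connected at every admissible density.
    """
    W = _apply_negative_policy(_weights(z), negative_policy)
    N = W.shape[0]
    n_pairs = N * (N - 1) // 2
    target = int(round(density * n_pairs))
    if target < N - 1:
        raise ValueError(
            f"density {density} gives {target} edges, below the spanning-tree "
            f"floor of {N - 1}"
        )
    available = int(np.count_nonzero(np.triu(W, 1) > 0))
    if available < target:
        raise ValueError(
            f"only {available} positive-weight node pairs available under "
            f"negative_policy={negative_policy!r}, cannot reach {target} edges"
        )
    backbone = mst_backbone(W)
    iu, ju = np.triu_indices(N, 1)
    order = np.lexsort((ju, iu, -W[iu, ju]))
    A = np.zeros_like(W)
    for i, j in backbone:
        if W[i, j] <= 0:
            raise ValueError(
                "positive part of the matrix is disconnected; spanning-tree "
                f"backbone would need the non-positive edge ({i},{j})"
            )
        A[i, j] = A[j, i] = W[i, j]
    n_edges = len(backbone)
    for k in order:
        if n_edges == target:
            break
        i, j = int(iu[k]), int(ju[k])
        if (i, j) in backbone:
            continue
        A[i, j] = A[j, i] = W[i, j]
        n_edges += 1
    return ThresholdedGraph(adjacency=A, density=density, backbone_edges=backbone)


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

def _adjacency(graph) -> np.ndarray:
    if isinstance(graph, ThresholdedGraph):
        return graph.adjacency
    return np.asarray(graph, dtype=float)


def _scaled(W: np.ndarray) -> np.ndarray:
    m = W.max()
    return W / m if m > 0 else W


def transitivity(graph, mode: str = "weighted") -> float:
    """Ratio of closed triangles to connected triplets.

    Binary: trace(A³) / Σ k_i (k_i − 1). Weighted: the same ratio with the
    triangle count replaced by geometric-mean triangle intensities on
    weights rescaled to a maximum of 1 (Onnela-style).
    """
    W = _adjacency(graph)
    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    denom = float(np.sum(k * (k - 1)))
    if denom == 0:
        raise ValueError("no node with degree >= 2; transitivity undefined")
    if mode == "binary":
        num = float(np.trace(A @ A @ A))
    elif mode == "weighted":
        C = np.cbrt(_scaled(W))
        num = float(np.trace(C @ C @ C))
    else:
        raise ValueError("mode must be 'binary' or 'weighted'")
    return num / denom


def _distances(W: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        A = csr_array((W > 0).astype(float))
        return shortest_path(A, method="D", unweighted=True)
    if mode == "weighted":
        Ws = _scaled(W)
        with np.errstate(divide="ignore"):
            L = np.where(Ws > 0, 1.0 / Ws, 0.0)
        return shortest_path(csr_array(L), method="D")
    raise ValueError("mode must be 'binary' or 'weighted'")


def global_efficiency(graph, mode: str = "weighted") -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Binary distances are hop counts; weighted distances use length =
    1/weight on weights rescaled to max 1.
    """
    W = _adjacency(graph)
    N = W.shape[0]
    D = _distances(W, mode)
    off = ~np.eye(N, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], 0.0)
    return float(np.mean(inv))


def louvain_q(
    graph, n_restarts: int = 100, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Best-of-restarts Louvain modularity and its partition.

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j) on the weighted graph;
    each restart runs Louvain under a different derived seed and the highest
    Q is kept.
    """
    W = _adjacency(graph)
    G = nx.from_numpy_array(W)
    best_q, best_labels = -np.inf, None
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(
            G, weight="weight", seed=child_seed(seed, "louvain", r)
        )
        q = nx.community.modularity(G, parts, weight="weight")
        if q > best_q:
            best_q = q
            best_labels = np.empty(W.shape[0], dtype=int)
            for c, nodes in enumerate(parts):
                best_labels[list(nodes)] = c
    return float(best_q), best_labels


def participation_coefficient(
    graph, parcellation: ParcellationScheme, mode: str = "weighted"
) -> np.ndarray:
    """Nodal participation: PC_i = 1 − Σ_s (k_is / k_i)².

    k_is is node i's (weighted) strength into module s. 0 means all of a
    node's connections stay inside its own module; values near 1 mean they
    are spread evenly across modules.
    """
    W = _adjacency(graph)
    if parcellation.n_nodes != W.shape[0]:
        raise ValueError("parcellation does not cover the node set")
    if mode == "binary":
        W = (W > 0).astype(float)
    M = parcellation.indicator()
    K = W @ M                       # N x S strength into each module
    k = K.sum(axis=1)
    if np.any(k <= 0):
        raise AssertionError("isolated node encountered after thresholding")
    return 1.0 - np.sum((K / k[:, None]) ** 2, axis=1)


# ---------------------------------------------------------------------------
# null model and normalization
# ---------------------------------------------------------------------------

def degree_preserving_null(
    graph, n_swaps_per_edge: int = 10, seed: int = 0
) -> np.ndarray:
    """Connected degree-preserving rewiring (Maslov-Sneppen double edge swaps).

    Swaps that would create self-loops, multi-edges or disconnect the graph
    are rejected; connectivity is enforced with an adaptive check window
    (swaps in a window are undone if the window ends disconnected). The
    original weight multiset is shuffled onto the rewired edge list, so both
    the degree sequence and the weight multiset are preserved exactly.
    """
    W = _adjacency(graph)
    N = W.shape[0]
    iu = np.triu_indices(N, 1)
    present = W[iu] > 0
    edges = list(zip(iu[0][present].tolist(), iu[1][present].tolist()))
    weights = W[iu][present].copy()
    E = len(edges)
    rng = substream(seed, "null")

    n_pairs = N * (N - 1) // 2
    if E == n_pairs or E < 2:
        warnings.warn(
            "swap saturation: graph admits no double edge swaps; returned unchanged",
            stacklevel=2,
        )
        return W.copy()

    adj: list[set] = [set() for _ in range(N)]
    for (u, v) in edges:
        adj[u].add(v)
        adj[v].add(u)

    def connected() -> bool:
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == N

    def apply_swap(e1: int, e2: int, u, v, x, y) -> None:
        adj[u].discard(v); adj[v].discard(u)
        adj[x].discard(y); adj[y].discard(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))

    def revert(log: list[tuple]) -> None:
        for (f1, f2, a, b, c, d) in reversed(log):
            # invert (a,b),(c,d) -> (a,c),(b,d)
            adj[a].discard(c); adj[c].discard(a)
            adj[b].discard(d); adj[d].discard(b)
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)
            edges[f1] = (min(a, b), max(a, b))
            edges[f2] = (min(c, d), max(c, d))
        log.clear()

    target = n_swaps_per_edge * E
    max_attempts = 100 * target
    accepted = attempts = 0
    window = 1
    window_log: list[tuple] = []
    while accepted < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(0, E, size=2)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if x in adj[u] or y in adj[v]:
            continue
        apply_swap(int(e1), int(e2), u, v, x, y)
        window_log.append((int(e1), int(e2), u, v, x, y))
        accepted += 1
        if len(window_log) >= window:
            if connected():
                window_log.clear()
                window = min(window * 2, max(E // 4, 1))
            else:
                accepted -= len(window_log)
                revert(window_log)
                window = max(window // 2, 1)
    if window_log and not connected():
        accepted -= len(window_log)
        revert(window_log)
    if accepted < target:
        warnings.warn(
            f"swap saturation: accepted {accepted}/{target} swaps "
            f"after {attempts} attempts",
            stacklevel=2,
        )

    out = np.zeros_like(W)
    perm = rng.permutation(E)
    for idx, (u, v) in enumerate(edges):
        w = weights[perm[idx]]
        out[u, v] = out[v, u] = w
    return out


def normalized_metrics(
    graph,
    k_nulls: int = 20,
    seed: int = 0,
    mode: str = "weighted",
    n_swaps_per_edge: int = 10,
) -> tuple[float, float]:
    """Transitivity and global efficiency divided by their null-ensemble means."""
    if k_nulls < 1:
        raise ValueError("k_nulls must be >= 1")
    t_raw = transitivity(graph, mode)
    e_raw = global_efficiency(graph, mode)
    t_null, e_null = [], []
    for k in range(k_nulls):
        null = degree_preserving_null(
            graph, n_swaps_per_edge=n_swaps_per_edge, seed=child_seed(seed, "nulls", k)
        )
        t_null.append(transitivity(null, mode))
        e_null.append(global_efficiency(null, mode))
    tn, en = float(np.mean(t_null)), float(np.mean(e_null))
    if tn == 0 or en == 0:
        raise ValueError("null ensemble metric is zero; cannot normalize")
    return t_raw / tn, e_raw / en


# ---------------------------------------------------------------------------
# sweeps and group statistics
# ---------------------------------------------------------------------------

def density_sweep(
    subjects: list[ConnectivityMatrix],
    densities: list[float],
    parcellation: ParcellationScheme,
    k_nulls: int = 20,
    seed: int = 0,
    mode: str = "weighted",
    n_restarts: int = 100,
    n_swaps_per_edge: int = 10,
    negative_policy: str = "zero",
) -> list[MetricProfile]:
    """Full metric profile (global + participation) per subject per density."""
    if not subjects:
        return []
    n_nodes = subjects[0].n_nodes
    profiles = []
    for si, subj in enumerate(subjects):
        if subj.n_nodes != n_nodes:
            raise ValueError(f"subject {subj.subject_id}: node count mismatch")
        g_rows, pc_rows, parcel_rows = [], [], []
        for di, d in enumerate(densities):
            sub_seed = child_seed(seed, "sweep", subj.subject_id, di)
            try:
                graph = threshold_at_density(subj, d, negative_policy)
            except ValueError as exc:
                raise ValueError(f"subject {subj.subject_id}: {exc}") from exc
            t_norm, e_norm = normalized_metrics(
                graph, k_nulls=k_nulls, seed=sub_seed, mode=mode,
                n_swaps_per_edge=n_swaps_per_edge,
            )
            q, _ = louvain_q(graph, n_restarts=n_restarts, seed=sub_seed)
            pc = participation_coefficient(graph, parcellation, mode)
            g_rows.append(
                {
                    "density": d,
                    "transitivity_raw": transitivity(graph, mode),
                    "transitivity_norm": t_norm,
                    "efficiency_raw": global_efficiency(graph, mode),
                    "efficiency_norm": e_norm,
                    "modularity_q": q,
                }
            )
            pc_rows.append(pd.Series(pc, name=d))
            M = parcellation.indicator()
            parcel_rows.append(
                pd.Series(
                    (pc @ M) / M.sum(axis=0), index=parcellation.modules, name=d
                )
            )
        metric_cols = [
            "transitivity_raw", "transitivity_norm", "efficiency_raw",
            "efficiency_norm", "modularity_q",
        ]
        glob_df = (
            pd.DataFrame(g_rows).set_index("density")
            if g_rows
            else pd.DataFrame(columns=metric_cols, index=pd.Index([], name="density"))
        )
        profiles.append(
            MetricProfile(
                subject_id=subj.subject_id,
                group=subj.group,
                globals=glob_df,
                nodal_pc=pd.DataFrame(pc_rows),
                parcel_pc=pd.DataFrame(parcel_rows),
            )
        )
    return profiles


def global_table(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Long-format (subject, group, density, metric, value) table."""
    rows = []
    for p in profiles:
        for d, row in p.globals.iterrows():
            for metric, value in row.items():
                rows.append(
                    {
                        "subject": p.subject_id,
                        "group": p.group,
                        "density": d,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def parcel_table(profiles: list[MetricProfile], density: float) -> pd.DataFrame:
    """Subjects x modules mean participation at one density, plus group."""
    rows, groups = [], []
    for p in profiles:
        rows.append(p.parcel_pc.loc[density])
        groups.append(p.group)
    out = pd.DataFrame(rows, index=[p.subject_id for p in profiles])
    out.insert(0, "group", groups)
    return out


def group_metric_tests(
    profiles: list[MetricProfile],
    metrics: tuple[str, ...] = ("transitivity_norm", "efficiency_norm", "modularity_q"),
    pc_density: float | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Group comparisons of global metrics and parcel participation.

    Global metrics: permutation test per density, Bonferroni over densities
    within each metric family. Parcel participation (at ``pc_density``,
    default the largest swept density): permutation test per module with
    Benjamini-Hochberg FDR across modules.
    """
    from .groupstats import permutation_test  # local import to avoid cycle

    groups = np.array([p.group for p in profiles])
    if len(np.unique(groups)) != 2:
        raise ValueError("need exactly two groups")
    glob = global_table(profiles)
    densities = sorted(glob["density"].unique())
    rows = []
    for metric in metrics:
        for d in densities:
            sub = glob[(glob.metric == metric) & (glob.density == d)]
            vals = sub.set_index("subject")["value"].to_numpy()
            gv = sub["group"].to_numpy()
            p_raw = permutation_test(
                vals, gv, n_perm=n_perm, seed=child_seed(seed, "glob", metric, d)
            )
            rows.append(
                {
                    "metric": metric,
                    "density": d,
                    "mean_control": vals[gv == 0].mean(),
                    "mean_patient": vals[gv == 1].mean(),
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, p_raw * len(densities)),
                }
            )
    global_tests = pd.DataFrame(rows)
    global_tests["significant"] = global_tests["p_bonferroni"] < alpha

    if pc_density is None:
        pc_density = densities[-1]
    pc = parcel_table(profiles, pc_density)
    gv = pc.pop("group").to_numpy()
    prow = []
    for module in pc.columns:
        vals = pc[module].to_numpy()
        prow.append(
            {
                "module": module,
                "mean_control": vals[gv == 0].mean(),
                "mean_patient": vals[gv == 1].mean(),
                "p_raw": permutation_test(
                    vals, gv, n_perm=n_perm, seed=child_seed(seed, "pc", module)
                ),
            }
        )
    pc_tests = pd.DataFrame(prow)
    rej, p_fdr, _, _ = multipletests(pc_tests["p_raw"], alpha=alpha, method="fdr_bh")
    pc_tests["p_fdr"] = p_fdr
    pc_tests["significant"] = rej
    return {"global": global_tests, "parcel_pc": pc_tests, "pc_density": pc_density}


def pc_g_correlation(
    parcel_pc: pd.DataFrame,
    g: pd.Series,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of each module's mean participation with g.

    Computed within each group separately with Benjamini-Hochberg FDR
    across modules, mirroring the within-patient network-g analysis.
    """
    gv = np.asarray(groups)
    gval = np.asarray(g, dtype=float)
    out = []
    for grp in np.unique(gv):
        mask = gv == grp
        if mask.sum() < 4:
            raise ValueError(f"group {grp} has fewer than 4 subjects")
        rows = []
        for module in parcel_pc.columns:
            rho, p = spearmanr(parcel_pc[module].to_numpy()[mask], gval[mask])
            rows.append({"group": grp, "module": module, "rho": float(rho), "p_raw": float(p)})
        sub = pd.DataFrame(rows)
        rej, p_fdr, _, _ = multipletests(sub["p_raw"], alpha=alpha, method="fdr_bh")
        sub["p_fdr"] = p_fdr
        sub["significant"] = rej
        out.append(sub)
    return pd.concat(out, ignore_index=True)
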