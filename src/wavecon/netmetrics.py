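"""Graph-theoretic characterization of functional networks under subsampling.

Comparing networks with different node and edge counts biases every common
graph measure, so all statistics are computed on random subsamples of a
fixed size (100 neurons) at matched connectivity densities, repeated many
times; the mean and the root-mean-square spread over repeats are reported.

Measures: number of disconnected nodes, global clustering coefficient
(mean local clustering over nodes with at least two neighbours), network
efficiency (mean inverse shortest-path length, zero for unreachable
pairs), and degree assortativity (Pearson correlation of end-point degrees
over edges).  Clustering, efficiency and path structure use the undirected
projection of the network (a pair is connected regardless of direction);
degree distributions use the out-degree, where a non-directed edge adds to
both end-points.

Also provided: reference degree laws (binomial/random, mean-matched
exponential, and the empirical law of subsampled preferential-attachment
scale-free networks), a reduced chi-square comparison against them, and
the exponential distance-decay fit of connection probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .connectivity import Connection, FunctionalNetwork

__all__ = [
    "SubsampleSpec",
    "MetricsResult",
    "DecayFit",
    "to_graph",
    "clustering_global",
    "efficiency",
    "assortativity",
    "disconnected_count",
    "subsample_metrics",
    "degree_distribution",
    "model_degree_distributions",
    "chi2_compare",
    "fit_decay",
]

MEASURES = ("disconnected", "clustering", "efficiency", "assortativity")


@dataclass(frozen=True)
class SubsampleSpec:
    """Subsampling protocol: sample size, repeats, density grid, seed."""

    n_nodes: int = 100
    n_repeats: int = 100
    densities: tuple[float, ...] = (0.005, 0.01, 0.015, 0.02)
    reference_density: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 < d <= 1.0 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")


@dataclass(frozen=True)
class MetricsResult:
    """Mean and RMS spread of each measure per density, over subsample repeats.

    ``undefined[measure]`` counts repeats where the measure had no value
    (e.g. assortativity of a degree-regular sample); those repeats are
    excluded from the mean/RMS.  ``degree_distribution`` pools out-degrees
    over repeats at ``reference_density``.
    """

    densities: tuple[float, ...]
    mean: dict[str, np.ndarray]
    rms: dict[str, np.ndarray]
    undefined: dict[str, np.ndarray]
    degree_distribution: np.ndarray
    reference_density: float
    n_repeats: int


@dataclass(frozen=True)
class DecayFit:
    """Exponential distance decay ``P(d) = A * exp(-d / lam) + C`` (d in um)."""

    A: float
    lam: float
    C: float
    ci_A: tuple[float, float]
    ci_lam: tuple[float, float]
    ci_C: tuple[float, float]
    bin_centers: np.ndarray
    probability: np.ndarray
    sem: np.ndarray

    def predict(self, d) -> np.ndarray:
        return self.A * np.exp(-np.asarray(d, dtype=float) / self.lam) + self.C


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    return to_graph(net)


def to_graph(net: FunctionalNetwork) -> nx.Graph:
    """Undirected binary projection of a functional network."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((min(c.pair), max(c.pair)) for c in net.edges)
    return g


def clustering_global(net) -> float:
    """Mean local clustering over nodes with >= 2 neighbours; NaN if none."""
    g = _as_graph(net)
    local = [c for node, c in nx.clustering(g).items() if g.degree(node) >= 2]
    return float(np.mean(local)) if local else float("nan")


def efficiency(net) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Unreachable pairs contribute zero, so the measure is finite on
    disconnected graphs.
    """
    g = _as_graph(net)
    if len(g) < 2:
        return 0.0
    return float(nx.global_efficiency(g))


def assortativity(net) -> float:
    """Degree assortativity: Pearson correlation of end degrees over edges.

    Computed directly from the edge list (Newman's closed form).  NaN when
    fewer than 2 edges or zero degree variance at edge ends (e.g. regular
    graphs).
    """
    g = _as_graph(net)
    edges = list(g.edges())
    m = len(edges)
    if m < 2:
        return float("nan")
    deg = dict(g.degree())
    j = np.array([deg[u] for u, _ in edges], dtype=float)
    k = np.array([deg[v] for _, v in edges], dtype=float)
    num = (j * k).mean() - (0.5 * (j + k)).mean() ** 2
    den = (0.5 * (j**2 + k**2)).mean() - (0.5 * (j + k)).mean() ** 2
    if den <= 1e-12:
        return float("nan")
    return float(num / den)


def disconnected_count(net) -> int:
    """Number of nodes with no connection at all (zero total degree)."""
    g = _as_graph(net)
    return sum(1 for _, d in g.degree() if d == 0)


def _out_degrees(nodes: Sequence[int], edges: Iterable[Connection]) -> np.ndarray:
    """Out-degree per node; non-directed edges count for both end-points."""
    idx = {nid: i for i, nid in enumerate(nodes)}
    out = np.zeros(len(nodes), dtype=int)
    for c in edges:
        if c.directed:
            out[idx[c.source_target[0]]] += 1
        else:
            out[idx[c.pair[0]]] += 1
            out[idx[c.pair[1]]] += 1
    return out


def subsample_metrics(net: FunctionalNetwork, spec: SubsampleSpec) -> MetricsResult:
    """Subsampling-controlled network measures of one band network.

    For each repeat, ``spec.n_nodes`` nodes are drawn without replacement,
    the edge set is restricted to the sample, truncated to each density by
    significance order, and all measures are computed.  Raises when the
    population is smaller than the sample size (mirroring the exclusion of
    undersized recordings from analysis).
    """
    if len(net.nodes) < spec.n_nodes:
        raise ValueError(
            f"population of {len(net.nodes)} is smaller than the "
            f"{spec.n_nodes}-node subsample"
        )
    rng = np.random.default_rng(spec.seed)
    ranked_all = sorted(
        net.edges, key=lambda c: (-c.significance_ratio, (min(c.pair), max(c.pair)))
    )
    n = spec.n_nodes
    n_pairs = n * (n - 1) // 2
    values = {m: np.full((spec.n_repeats, len(spec.densities)), np.nan) for m in MEASURES}
    degree_pool = np.zeros(n, dtype=np.int64)  # histogram of out-degree 0..n-1

    nodes_arr = np.asarray(net.nodes)
    for r in range(spec.n_repeats):
        sample = set(nodes_arr[rng.choice(nodes_arr.size, size=n, replace=False)].tolist())
        in_sample = [c for c in ranked_all if c.pair[0] in sample and c.pair[1] in sample]
        sample_nodes = sorted(sample)
        for di, d in enumerate(spec.densities):
            cap = int(np.floor(d * n_pairs))
            sub = FunctionalNetwork(
                nodes=tuple(sample_nodes), edges=tuple(in_sample[:cap]), band=net.band
            )
            g = to_graph(sub)
            values["disconnected"][r, di] = disconnected_count(g)
            values["clustering"][r, di] = clustering_global(g)
            values["efficiency"][r, di] = efficiency(g)
            values["assortativity"][r, di] = assortativity(g)
            if math.isclose(d, spec.reference_density):
                degs = _out_degrees(sample_nodes, sub.edges)
                degree_pool += np.bincount(degs, minlength=n)

    mean, rms, undef = {}, {}, {}
    for m in MEASURES:
        v = values[m]
        undef[m] = np.sum(np.isnan(v), axis=0)
        with np.errstate(invalid="ignore"):
            mean[m] = np.nanmean(v, axis=0)
            rms[m] = np.nanstd(v, axis=0)
    total = degree_pool.sum()
    dist = degree_pool / total if total else degree_pool.astype(float)
    return MetricsResult(
        densities=tuple(spec.densities),
        mean=mean,
        rms=rms,
        undefined=undef,
        degree_distribution=dist,
        reference_density=spec.reference_density,
        n_repeats=spec.n_repeats,
    )


def degree_distribution(nets: Sequence[FunctionalNetwork], mode: str = "out") -> np.ndarray:
    """Pooled normalized out-degree distribution over same-size networks."""
    if mode != "out":
        raise ValueError("only out-degree distributions are supported")
    sizes = {len(net.nodes) for net in nets}
    if len(sizes) != 1:
        raise ValueError("all networks must have the same number of nodes")
    n = sizes.pop()
    hist = np.zeros(n, dtype=np.int64)
    for net in nets:
        degs = _out_degrees(sorted(net.nodes), net.edges)
        hist += np.bincount(degs, minlength=n)
    return hist / hist.sum()


def _exponential_degree_law(n: int, mean_degree: float) -> np.ndarray:
    """Discrete exponential ``P(k) ~ exp(-k/kbar)`` on ``k = 0..n-1``.

    The single free parameter is fixed by matching the mean degree, which
    makes the law fully determined by network size and density.
    """
    k = np.arange(n, dtype=float)
    if mean_degree <= 0:
        p = np.zeros(n)
        p[0] = 1.0
        return p

    def mean_of(alpha: float) -> float:
        w = np.exp(-alpha * k)
        return float((k * w).sum() / w.sum())

    lo, hi = 1e-9, 50.0
    # mean_of is decreasing in alpha; bracket then bisect
    alpha = optimize.brentq(lambda a: mean_of(a) - mean_degree, lo, hi)
    w = np.exp(-alpha * k)
    return w / w.sum()


def _preferential_attachment(n: int, m_mean: float, rng: np.random.Generator) -> nx.Graph:
    """Barabasi-Albert-style graph with (possibly fractional) mean attachment.

    Starts from a small clique; each new node attaches to ``floor(m)`` or
    ``ceil(m)`` (Bernoulli on the fraction) distinct existing nodes chosen
    proportionally to degree.
    """
    m0 = max(2, int(np.ceil(m_mean)) + 1)
    g = nx.complete_graph(m0)
    repeated: list[int] = [u for e in g.edges() for u in e]
    m_lo = int(np.floor(m_mean))
    frac = m_mean - m_lo
    for v in range(m0, n):
        m_i = m_lo + (1 if rng.random() < frac else 0)
        m_i = min(m_i, v)
        targets: set[int] = set()
        while len(targets) < m_i:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            g.add_edge(v, t)
            repeated.extend((v, t))
    return g


def model_degree_distributions(
    n: int = 100,
    p: float = 0.01,
    parent_n: int = 1000,
    n_parents: int = 1000,
    n_subsamples: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Reference degree laws at network size ``n`` and density ``p``.

    * ``random``: binomial ``B(n - 1, p)``;
    * ``exponential``: discrete exponential with mean ``(n - 1) * p``;
    * ``scalefree_subsampled``: empirical degree law of ``n``-node uniform
      subsamples of ``parent_n``-node preferential-attachment graphs built
      at density ``p`` (subsampling destroys the power-law tail, which is
      why the subsampled law — not the parent law — is the right
      comparison).  ``n_parents``/``n_subsamples`` control the Monte-Carlo
      replication (1000 x 100 at full fidelity; reducible for tests).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("density p must lie in (0, 1)")
    k = np.arange(n)
    out = {
        "random": stats.binom.pmf(k, n - 1, p),
        "exponential": _exponential_degree_law(n, (n - 1) * p),
    }
    rng = np.random.default_rng(seed)
    target_edges = p * parent_n * (parent_n - 1) / 2.0
    m0 = max(2, int(np.ceil(2 * target_edges / parent_n)) + 1)
    e0 = m0 * (m0 - 1) / 2.0
    m_mean = (target_edges - e0) / (parent_n - m0)
    hist = np.zeros(n, dtype=np.int64)
    for _ in range(n_parents):
        g = _preferential_attachment(parent_n, m_mean, rng)
        deg_all = np.array([d for _, d in g.degree()])
        adj_nodes = np.arange(parent_n)
        for _ in range(n_subsamples):
            sample = rng.choice(adj_nodes, size=n, replace=False)
            sub = g.subgraph(sample.tolist())
            degs = np.fromiter((d for _, d in sub.degree()), dtype=int, count=n)
            hist += np.bincount(np.minimum(degs, n - 1), minlength=n)
    out["scalefree_subsampled"] = hist / hist.sum()
    return out


def chi2_compare(observed: np.ndarray, sem: np.ndarray, model: np.ndarray) -> float:
    """Reduced chi-square between an observed degree law (with SEM) and a model.

    Sums ``(obs - model)**2 / sem**2`` over bins with defined (positive,
    finite) SEM and divides by the number of such bins.
    """
    observed = np.asarray(observed, dtype=float)
    sem = np.asarray(sem, dtype=float)
    model = np.asarray(model, dtype=float)
    mask = np.isfinite(sem) & (sem > 0)
    dof = int(mask.sum())
    if dof == 0:
        raise ValueError("no bins with defined SEM; zero degrees of freedom")
    return float(np.sum(((observed[mask] - model[mask]) / sem[mask]) ** 2) / dof)


def _connection_probability_profile(
    net: FunctionalNetwork, bin_width_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pairs, connected pairs, summed distances) per distance bin."""
    nodes = [nid for nid in net.nodes if net.positions.get(nid) is not None]
    pos = np.array([net.positions[nid] for nid in nodes], dtype=float)
    if len(nodes) < 2:
        raise ValueError("need at least two positioned nodes")
    connected = {(min(c.pair), max(c.pair)) for c in net.edges}
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    iu, ju = np.triu_indices(len(nodes), k=1)
    dists = d[iu, ju]
    bins = np.floor(dists / bin_width_um).astype(int)
    n_bins = bins.max() + 1
    total = np.bincount(bins, minlength=n_bins)
    d_sum = np.bincount(bins, weights=dists, minlength=n_bins)
    is_conn = np.fromiter(
        (
            (min(nodes[a], nodes[b]), max(nodes[a], nodes[b])) in connected
            for a, b in zip(iu, ju)
        ),
        dtype=bool,
        count=iu.size,
    )
    conn = np.bincount(bins[is_conn], minlength=n_bins)
    return total, conn, d_sum


def fit_decay(
    nets: Sequence[FunctionalNetwork],
    bin_width_um: float = 50.0,
    min_pairs_per_bin: int = 50,
) -> DecayFit:
    """Least-squares exponential fit of connection probability vs distance.

    Pairs are binned by inter-neuron distance (50 um default), the
    connection probability is computed per bin for each network and
    averaged across networks (mean and SEM per bin), and
    ``P(d) = A * exp(-d / lam) + C`` is fitted by ordinary least squares.
    Only bins holding at least ``min_pairs_per_bin`` pairs in every network
    enter the fit (sparsely populated extreme-distance bins otherwise
    produce wild probability outliers), and each kept bin is placed at the
    mean distance of its pairs rather than its geometric center (neuron
    positions are lattice-like, so within-bin distances are not uniform).
    Confidence intervals are 95% normal intervals from the fit covariance;
    a flat profile leaves ``lam`` unidentifiable, which surfaces as a very
    wide interval or a vanishing amplitude.
    """
    profiles = [_connection_probability_profile(net, bin_width_um) for net in nets]
    n_bins = max(t.size for t, _, _ in profiles)
    probs = np.full((len(nets), n_bins), np.nan)
    weight = np.zeros((len(nets), n_bins))
    dist_sum = np.zeros((len(nets), n_bins))
    for i, (total, conn, d_sum) in enumerate(profiles):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total >= min_pairs_per_bin, conn / np.maximum(total, 1), np.nan)
        probs[i, : p.size] = p
        weight[i, : total.size] = total
        dist_sum[i, : d_sum.size] = d_sum
    n_valid = np.sum(np.isfinite(probs), axis=0)
    keep = n_valid == len(nets)
    if keep.sum() < 4:
        raise ValueError("need at least 4 well-populated distance bins for the decay fit")
    mean = np.nanmean(probs[:, keep], axis=0)
    sem = np.nanstd(probs[:, keep], axis=0) / np.sqrt(len(nets))
    centers = dist_sum[:, keep].sum(axis=0) / weight[:, keep].sum(axis=0)

    def model(d, A, lam, C):
        return A * np.exp(-d / lam) + C

    a0 = max(mean.max() - mean.min(), 1e-4)
    p0 = (a0, 300.0, max(mean.min(), 1e-6))
    try:
        popt, pcov = optimize.curve_fit(
            model,
            centers,
            mean,
            p0=p0,
            bounds=([0.0, 1e-3, 0.0], [1.0, 1e6, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"distance-decay fit did not converge: {exc}") from exc
    err = 1.96 * np.sqrt(np.diag(pcov))
    return DecayFit(
        A=float(popt[0]),
        lam=float(popt[1]),
        C=float(popt[2]),
        ci_A=(float(popt[0] - err[0]), float(popt[0] + err[0])),
        ci_lam=(float(popt[1] - err[1]), float(popt[1] + err[1])),
        ci_C=(float(popt[2] - err[2]), float(popt[2] + err[2])),
        bin_centers=centers,
        probability=mean,
        sem=sem,
    )
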