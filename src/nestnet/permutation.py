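"""Node-permutation null models for assortativity.

The null hypothesis is that a breeder's position in the spatial network is
independent of its personality: each replicate reassigns the observed
multiset of scores to nodes by a uniform random permutation, leaving
topology and edge weights untouched, and recomputes the statistic. Scores
are shuffled within each year's network only. Multi-year inputs are
combined per replicate by the link-weighted mean with the observed link
counts, mirroring how the observed statistic is combined.

P values use the add-one (never-zero) convention
``(1 + #{null >= r_obs}) / (1 + N)`` for the upper tail, the analogue for
the lower tail, and twice the smaller tail (capped at 1) two-sided.

The ``dedupe`` variant guards against pseudoreplication from dyads that
recur across years: before each replicate, every dyad occurring in more
than one year is kept in exactly one uniformly chosen year and deleted
(both directions) elsewhere; link counts are recomputed per replicate.

Reproducibility contract: each year receives an independent RNG substream
spawned from the master seed, so results do not depend on evaluation
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assortment import _VAR_TOL
from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

TAILS = ("two_sided", "upper", "lower")


@dataclass
class NullDistribution:
    """Permutation-null replicate values of (combined) assortativity."""

    values: np.ndarray
    n_requested: int
    n_undefined: int
    seed: int | None
    tail: str = "two_sided"
    #: mean observed combined r under dedupe deletion draws (None otherwise)
    observed_dedupe: float | None = None
    #: mean combined link count under dedupe deletion draws (None otherwise)
    n_links_dedupe: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def quantiles(self, q=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.values, q)


def permute_node_labels(network, seed=None):
    """Copy of ``network`` with scores reassigned by a uniform permutation.

    Topology and weights are untouched; the score multiset is conserved.
    ``seed`` may be an int or a numpy Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = network.graph.copy()
    scored = [n for n in g.nodes if "score" in g.nodes[n]]
    if len(scored) < 2:
        raise UndefinedStatisticError("need >= 2 scored nodes to permute")
    scores = np.array([g.nodes[n]["score"] for n in scored])
    perm = rng.permutation(len(scored))
    for n, s in zip(scored, scores[perm]):
        g.nodes[n]["score"] = float(s)
    from .networks import SpatialNetwork

    return SpatialNetwork(
        graph=g, year=network.year, sex=network.sex, method=network.method,
        k=network.k, weighted=network.weighted,
        restrict_order=network.restrict_order,
    )


def _null_r_block(
    x: np.ndarray,
    src: np.ndarray,
    tgt: np.ndarray,
    w: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vector of assortativity values under ``n_perm`` label permutations.

    Undefined replicates (zero variance at an edge end) come back as NaN.
    """
    n = len(x)
    # one uniform permutation per row
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    X = x[order]
    xs = X[:, src]
    xt = X[:, tgt]
    W = w.sum()
    ms = xs @ w / W
    mt = xt @ w / W
    vs = (xs * xs) @ w / W - ms * ms
    vt = (xt * xt) @ w / W - mt * mt
    cov = (xs * xt) @ w / W - ms * mt
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vs * vt)
    r[(vs < _VAR_TOL) | (vt < _VAR_TOL)] = np.nan
    return r


def _network_arrays(network):
    src, tgt, w, nodes = network.edge_arrays()
    if len(src) == 0:
        raise UndefinedStatisticError(
            f"network {network.year}/{network.sex} has no edges"
        )
    x = network.score_vector()
    if np.isnan(x[src]).any() or np.isnan(x[tgt]).any():
        raise UndefinedStatisticError("edge endpoint without a score")
    return x, src, tgt, w


def _dyads(network) -> dict[frozenset, list[tuple[str, str]]]:
    """Unordered bird pairs -> the directed/undirected edges realising them."""
    out: dict[frozenset, list[tuple[str, str]]] = {}
    for u, v in network.graph.edges:
        out.setdefault(frozenset((u, v)), []).append((u, v))
    return out


def null_distribution(
    networks_by_year,
    n_perm: int = 1000,
    seed: int | None = None,
    dedupe: bool = False,
) -> NullDistribution:
    """Permutation null of the (combined) assortativity statistic.

    ``networks_by_year`` is a list of scored networks (one suffices); each
    replicate permutes every year independently and combines the per-year
    values by the link-weighted mean with the observed link counts.
    Replicates where any year's statistic is undefined are excluded and
    tallied in ``n_undefined``. With ``dedupe=True`` the per-replicate
    duplicate-dyad deletion described in the module docstring is applied,
    and the deletion-averaged observed statistic is reported alongside.
    """
    networks = list(networks_by_year)
    if not networks:
        raise ValueError("no networks supplied")
    master = np.random.SeedSequence(seed)
    if not dedupe:
        year_streams = master.spawn(len(networks))
        r_year = np.empty((len(networks), n_perm))
        n_links = np.empty(len(networks))
        for yi, net in enumerate(networks):
            x, src, tgt, w = _network_arrays(net)
            rng = np.random.default_rng(year_streams[yi])
            r_year[yi] = _null_r_block(x, src, tgt, w, n_perm, rng)
            n_links[yi] = net.graph.number_of_edges()
        combined = (r_year * n_links[:, None]).sum(axis=0) / n_links.sum()
        bad = np.isnan(r_year).any(axis=0)
        values = combined[~bad]
        n_undefined = int(bad.sum())
        obs_d = links_d = None
    else:
        values_list: list[float] = []
        obs_list: list[float] = []
        links_list: list[float] = []
        n_undefined = 0
        dyads = [_dyads(net) for net in networks]
        all_pairs: dict[frozenset, list[int]] = {}
        for yi, dy in enumerate(dyads):
            for pair in dy:
                all_pairs.setdefault(pair, []).append(yi)
        shared = {p: ys for p, ys in all_pairs.items() if len(ys) > 1}
        rng = np.random.default_rng(master)
        for _ in range(n_perm):
            keep_year = {p: ys[rng.integers(len(ys))] for p, ys in shared.items()}
            r_rep, r_obs_rep, links_rep = [], [], []
            undefined = False
            for yi, net in enumerate(networks):
                drop = {
                    e
                    for p, ky in keep_year.items()
                    if ky != yi and yi in shared[p]
                    for e in dyads[yi].get(p, [])
                }
                x, src, tgt, w, nl = _reduced_arrays(net, drop)
                if nl == 0:
                    undefined = True
                    break
                try:
                    xs, xt = x[src], x[tgt]
                    r_obs_rep.append(_safe_r(xs, xt, w))
                except UndefinedStatisticError:
                    undefined = True
                    break
                r = _null_r_block(x, src, tgt, w, 1, rng)[0]
                if np.isnan(r):
                    undefined = True
                    break
                r_rep.append(r)
                links_rep.append(nl)
            if undefined:
                n_undefined += 1
                continue
            links = np.array(links_rep, dtype=float)
            values_list.append(float(np.dot(r_rep, links) / links.sum()))
            obs_list.append(float(np.dot(r_obs_rep, links) / links.sum()))
            links_list.append(float(np.mean(links)))
        values = np.array(values_list)
        obs_d = float(np.mean(obs_list)) if obs_list else None
        links_d = float(np.mean(links_list)) if links_list else None
    if len(values) == 0:
        raise UndefinedStatisticError(
            f"all {n_perm} null replicates undefined (constant scores?)"
        )
    if n_undefined:
        logger.info("null_distribution: %d/%d replicates undefined", n_undefined, n_perm)
    return NullDistribution(
        values=values, n_requested=n_perm, n_undefined=n_undefined, seed=seed,
        observed_dedupe=obs_d, n_links_dedupe=links_d,
    )


def _safe_r(xs, xt, w) -> float:
    from .assortment import _weighted_r

    return _weighted_r(xs, xt, w)


def _reduced_arrays(network, drop_edges: set):
    """Edge arrays of ``network`` with ``drop_edges`` (graph edges) removed."""
    nodes = list(network.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    src, tgt, w = [], [], []
    for u, v, data in network.graph.edges(data=True):
        if (u, v) in drop_edges or (not network.directed and (v, u) in drop_edges):
            continue
        src.append(index[u]); tgt.append(index[v]); w.append(data["weight"])
        if not network.directed:
            src.append(index[v]); tgt.append(index[u]); w.append(data["weight"])
    x = network.score_vector()
    n_links = len(src) if network.directed else len(src) // 2
    return x, np.array(src, dtype=np.intp), np.array(tgt, dtype=np.intp), np.array(w), n_links


def p_value(r_obs: float, null, tail: str = "two_sided") -> float:
    """Permutation P with the add-one correction.

    upper: (1 + #{null >= r_obs}) / (1 + N); lower analogous;
    two_sided: min(1, 2 * min(upper, lower)).
    """
    values = null.values if isinstance(null, NullDistribution) else np.asarray(null, dtype=float)
    if len(values) == 0:
        raise ValueError("empty null distribution")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    n = len(values)
    upper = (1 + np.sum(values >= r_obs)) / (1 + n)
    lower = (1 + np.sum(values <= r_obs)) / (1 + n)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float(lower)
    return float(min(1.0, 2.0 * min(upper, lower)))
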