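"""Newman's assortativity for a continuous trait, with jackknife SE.

For a directed weighted edge list E with weights ``w_ij`` and node trait
``x``, the coefficient is the weighted Pearson correlation between the
trait at the source end and the trait at the target end of an edge:

    r = [ <x_s x_t> - <x_s><x_t> ] / (sigma_s * sigma_t)

where ``<.>`` is the w-weighted mean over edges and ``sigma_s``,
``sigma_t`` the w-weighted SDs of the source-end and target-end traits.
Source and target moments are kept separate (the directed generalisation
used for animal social networks); on a symmetric edge list this reduces to
the classical undirected coefficient. Undirected networks contribute each
edge in both directions, binary networks use unit weights, so the binary
statistic is the weighted one with w = 1.

A zero-variance end makes r undefined; that is raised as
:class:`~nestnet.errors.UndefinedStatisticError` rather than returned as
NaN so that permutation loops must handle (and tally) such replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

_VAR_TOL = 1e-12


@dataclass
class AssortmentResult:
    """One row of an assortment analysis (a single network or the
    link-weighted across-year combination)."""

    scope: tuple  # (year-or-"combined", sex, method, k)
    r_obs: float
    se_jackknife: float | None
    null_mean: float | None
    effect_size: float | None
    p_value: float | None
    n_links: float
    n_permutations: int | None

    def as_dict(self) -> dict:
        year, sex, method, k = self.scope
        return {
            "year": year,
            "sex": sex,
            "method": method,
            "k": k,
            "n_links": self.n_links,
            "observed": self.r_obs,
            "se_jackknife": self.se_jackknife,
            "permuted": self.null_mean,
            "effect_size": self.effect_size,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def _weighted_r(xs: np.ndarray, xt: np.ndarray, w: np.ndarray) -> float:
    """Weighted correlation of source-end vs target-end trait values."""
    W = w.sum()
    if W <= 0:
        raise UndefinedStatisticError("total edge weight is zero")
    ms = (w * xs).sum() / W
    mt = (w * xt).sum() / W
    vs = (w * xs * xs).sum() / W - ms * ms
    vt = (w * xt * xt).sum() / W - mt * mt
    if vs < _VAR_TOL or vt < _VAR_TOL:
        raise UndefinedStatisticError("zero trait variance at one edge end")
    cov = (w * xs * xt).sum() / W - ms * mt
    return float(cov / np.sqrt(vs * vt))


def assortativity_continuous(network) -> float:
    """Newman's continuous-trait assortativity of a scored network.

    Requires at least one edge between scored nodes and nonzero trait
    variance at both edge ends.
    """
    src, tgt, w, nodes = network.edge_arrays()
    if len(src) == 0:
        raise UndefinedStatisticError("network has no edges")
    x = network.score_vector()
    xs, xt = x[src], x[tgt]
    if np.isnan(xs).any() or np.isnan(xt).any():
        raise UndefinedStatisticError("edge endpoint without a score")
    return _weighted_r(xs, xt, w)


def _jackknife_units(network, src: np.ndarray) -> list[np.ndarray]:
    """Indices into the directed edge array per jackknife unit.

    The unit is the directed edge for directed (k-NN) networks and the
    dyad (both directions of one undirected edge) for undirected ones —
    ``edge_arrays`` emits the two directions of an undirected edge
    consecutively.
    """
    m = len(src)
    if network.directed:
        return [np.array([i]) for i in range(m)]
    return [np.array([2 * t, 2 * t + 1]) for t in range(m // 2)]


def jackknife_se(network) -> float:
    """Jackknife standard error of assortativity over edges.

    se^2 = sum_e (r_{-e} - r)^2, where r_{-e} drops one directed edge
    (one dyad for undirected networks). Units whose removal leaves r
    undefined are skipped with a logged count.
    """
    src, tgt, w, _ = network.edge_arrays()
    x = network.score_vector()
    xs, xt = x[src], x[tgt]
    units = _jackknife_units(network, src)
    if len(units) < 2:
        raise UndefinedStatisticError("need >= 2 jackknife units")
    r = _weighted_r(xs, xt, w)
    # leave-one-unit-out via sufficient statistics
    terms = np.column_stack([w, w * xs, w * xt, w * xs * xs, w * xt * xt, w * xs * xt])
    totals = terms.sum(axis=0)
    skipped = 0
    ss = 0.0
    for idx in units:
        Wd, Sx, Sy, Sxx, Syy, Sxy = totals - terms[idx].sum(axis=0)
        if Wd <= 0:
            skipped += 1
            continue
        ms, mt = Sx / Wd, Sy / Wd
        vs, vt = Sxx / Wd - ms * ms, Syy / Wd - mt * mt
        if vs < _VAR_TOL or vt < _VAR_TOL:
            skipped += 1
            continue
        r_del = (Sxy / Wd - ms * mt) / np.sqrt(vs * vt)
        ss += (r_del - r) ** 2
    if skipped:
        logger.info("jackknife: skipped %d unit(s) with undefined r", skipped)
    return float(np.sqrt(ss))


def combine_years(per_year: list[tuple[float, float]]) -> float:
    """Across-year mean of r weighted by each year's link count.

    ``per_year`` is a list of (r, n_links); all link counts must be
    positive. The same weighting is applied to null replicates; the
    reported combined link count is the plain mean of the yearly counts.
    """
    if not per_year:
        raise ValueError("no per-year results to combine")
    r = np.array([p[0] for p in per_year], dtype=float)
    n = np.array([p[1] for p in per_year], dtype=float)
    if (n <= 0).any():
        raise ValueError("all link counts must be > 0")
    return float((r * n).sum() / n.sum())


def effect_size(r_obs: float, null_mean: float) -> float:
    """Observed assortment minus the permutation-null mean."""
    if not (np.isfinite(r_obs) and np.isfinite(null_mean)):
        raise ValueError("effect size requires finite inputs")
    return r_obs - null_mean
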