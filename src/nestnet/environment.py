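"""Environmental checks: nestbox repeatability and density–personality.

Two analyses guard the social interpretation of assortment against
habitat confounds:

* **Nestbox repeatability** — if certain boxes attract certain
  personalities, box identity should explain score variance across
  occupant-years. Estimated as the intraclass correlation from unbalanced
  one-way ANOVA variance components with nestbox as the grouping factor,
  scores centred within sex. Birds reusing a box across years would
  inflate the estimate, so each subsample keeps one uniformly chosen year
  per (bird, box) pair; the estimate is the mean over subsamples with a
  percentile interval.

* **Strength–personality association** — if bold birds settle in denser
  neighbourhoods, node strength (summed edge weights, a local-density
  proxy) should track score. Estimated as the within-year-centred least
  squares slope of strength on score, with a permutation P value from
  shuffling scores within years.

Both replace the original Bayesian mixed-model formulations with
frequentist equivalents targeting the same estimands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .networks import node_strength

logger = logging.getLogger(__name__)


@dataclass
class RepeatabilityResult:
    """Intraclass correlation of scores across nestbox occupant-years."""

    estimate: float
    interval_low: float
    interval_high: float
    n_groups: int
    n_subsamples: int


@dataclass
class AssociationResult:
    """Slope of node strength on personality with permutation P."""

    slope: float
    p_value: float
    n_obs: int


def _oneway_icc(groups: np.ndarray, values: np.ndarray) -> float:
    """ICC from unbalanced one-way ANOVA variance components, truncated at 0.

    sigma2_between = (MSB - MSW) / n0 with n0 = (N - sum n_i^2 / N)/(k - 1);
    ICC = sigma2_between / (sigma2_between + MSW).
    """
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    N = len(values)
    if k < 2 or N <= k:
        logger.warning("repeatability: all groups singleton; ICC reported as 0")
        return 0.0
    sums = np.bincount(inv, weights=values)
    sqs = np.bincount(inv, weights=values**2)
    ns = np.bincount(inv).astype(float)
    gmean = values.sum() / N
    means = sums / ns
    ssb = float((ns * (means - gmean) ** 2).sum())
    ssw = float((sqs - ns * means**2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - (ns**2).sum() / N) / (k - 1)
    sigma2_b = (msb - msw) / n0
    if sigma2_b < 0:
        logger.debug("negative between-group variance %.4g truncated to 0", sigma2_b)
        sigma2_b = 0.0
    denom = sigma2_b + msw
    return float(sigma2_b / denom) if denom > 0 else 1.0


def _occupant_years(records: pd.DataFrame, personality: pd.DataFrame) -> pd.DataFrame:
    """Long table of typed occupant-years: bird_id, sex, box_id, year, score."""
    scores = personality.set_index("bird_id")["score"]
    sexes = personality.set_index("bird_id")["sex"]
    parts = []
    for col, sex in (("male_id", "male"), ("female_id", "female")):
        sub = records[records[col].notna()][["year", "box_id", col]].rename(
            columns={col: "bird_id"}
        )
        sub = sub[sub["bird_id"].isin(scores.index[sexes == sex])]
        sub["sex"] = sex
        sub["score"] = sub["bird_id"].map(scores).astype(float)
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def nestbox_repeatability(
    records: pd.DataFrame,
    personality: pd.DataFrame,
    n_subsamples: int = 1000,
    seed: int | None = None,
) -> RepeatabilityResult:
    """Subsampled nestbox ICC of occupant personality.

    Scores are centred within sex (sex as a fixed effect); each subsample
    keeps one uniformly chosen year per (bird, box) pair before the
    one-way variance-component fit. The reported estimate is the mean
    over subsamples, the interval its 2.5/97.5 percentiles.
    """
    data = _occupant_years(records, personality)
    if data["box_id"].nunique() < 2:
        raise UndefinedStatisticError("need >= 2 nestboxes with typed occupants")
    data = data.copy()
    data["score_c"] = data["score"] - data.groupby("sex")["score"].transform("mean")
    rng = np.random.default_rng(seed)
    pair_groups = data.groupby(["bird_id", "box_id"], sort=True).indices
    idx_lists = [np.sort(v) for _, v in sorted(pair_groups.items())]
    boxes = data["box_id"].to_numpy()
    values = data["score_c"].to_numpy()
    estimates = np.empty(n_subsamples)
    for s in range(n_subsamples):
        keep = np.array([ix[rng.integers(len(ix))] for ix in idx_lists])
        estimates[s] = _oneway_icc(boxes[keep], values[keep])
    return RepeatabilityResult(
        estimate=float(estimates.mean()),
        interval_low=float(np.percentile(estimates, 2.5)),
        interval_high=float(np.percentile(estimates, 97.5)),
        n_groups=int(data["box_id"].nunique()),
        n_subsamples=n_subsamples,
    )


def strength_personality_association(
    networks_by_year,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AssociationResult:
    """Within-year slope of node strength on personality score.

    One observation per scored bird per yearly network; strength and score
    are centred within year (year as a blocking factor) and the pooled
    least squares slope is tested by permuting scores within years.
    """
    rows = []
    for net in networks_by_year:
        for bird, sc in net.scores().items():
            rows.append((net.year, sc, node_strength(net, bird)))
    if len(rows) < 10:
        raise UndefinedStatisticError("need >= 10 (bird, year) observations")
    df = pd.DataFrame(rows, columns=["year", "score", "strength"])
    if np.allclose(df["score"].var(ddof=0), 0.0):
        raise UndefinedStatisticError("zero score variance")
    year_idx = df.groupby("year").indices
    x = df["score"].to_numpy(dtype=float).copy()
    y = df["strength"].to_numpy(dtype=float).copy()
    for idx in year_idx.values():
        x[idx] -= x[idx].mean()
        y[idx] -= y[idx].mean()
    sxx = float((x * x).sum())
    if sxx == 0.0:
        raise UndefinedStatisticError("zero within-year score variance")
    slope = float((x * y).sum() / sxx)
    rng = np.random.default_rng(seed)
    perm_slopes = np.empty(n_perm)
    for p in range(n_perm):
        xp = x.copy()
        for idx in year_idx.values():
            xp[idx] = xp[idx][rng.permutation(len(idx))]
        perm_slopes[p] = (xp * y).sum() / (xp * xp).sum()
    upper = (1 + np.sum(perm_slopes >= slope)) / (1 + n_perm)
    lower = (1 + np.sum(perm_slopes <= slope)) / (1 + n_perm)
    pval = float(min(1.0, 2.0 * min(upper, lower)))
    return AssociationResult(slope=slope, p_value=pval, n_obs=len(df))
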