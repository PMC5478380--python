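"""Model/results interface for personality-assortment analyses.

:class:`PersonalityAssortment` is built from per-year networks (or
directly from the three input tables via :meth:`from_tables`); ``fit``
runs the observed statistic, the jackknife SE, the node-permutation null
and the across-year combination, returning an
:class:`AssortmentResults` object with per-year and combined estimates, a
``summary()`` table and a null-band plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import networks as netmod
from .assortment import (
    AssortmentResult,
    assortativity_continuous,
    combine_years,
    effect_size,
    jackknife_se,
)
from .errors import UndefinedStatisticError
from .permutation import NullDistribution, null_distribution, p_value

logger = logging.getLogger(__name__)


class PersonalityAssortment:
    """Assortment-by-personality model over one or more yearly networks.

    Parameters
    ----------
    networks : list of SpatialNetwork
        Scored (typed-restricted) networks, typically one per breeding
        season; all should share sex/method/weighting.
    """

    def __init__(self, networks):
        networks = [n for n in networks if n.graph.number_of_edges() > 0]
        if not networks:
            raise UndefinedStatisticError("no non-empty networks supplied")
        self.networks = sorted(networks, key=lambda n: (n.year is None, n.year))

    @classmethod
    def from_tables(
        cls,
        records: pd.DataFrame,
        nestboxes: pd.DataFrame,
        personality: pd.DataFrame,
        sex: str,
        method: str = "knn",
        k: int = 5,
        weighted: bool = True,
        years=None,
        region: str | None = None,
        restrict_order: str = "construct_then_restrict",
        window=None,
        d_min: float = netmod.DEFAULT_D_MIN,
    ) -> "PersonalityAssortment":
        """Build the yearly networks from the three standard tables.

        Years whose typed network comes out empty are dropped with a
        warning rather than aborting the model.
        """
        if years is None:
            years = sorted(records["year"].unique())
        nets = []
        for year in years:
            if method == "knn":
                net = netmod.build_knn_network(
                    records, nestboxes, personality, year=year, sex=sex, k=k,
                    weighted=weighted, restrict_order=restrict_order,
                    region=region, d_min=d_min,
                )
            elif method == "thiessen":
                net = netmod.build_thiessen_network(
                    records, nestboxes, personality, year=year, sex=sex,
                    weighted=weighted, restrict_order=restrict_order,
                    region=region, window=window, d_min=d_min,
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            if net.graph.number_of_edges() == 0:
                logger.warning("year %s (%s, %s): empty typed network; dropped", year, sex, method)
                continue
            nets.append(net)
        return cls(nets)

    def fit(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        tail: str = "two_sided",
        dedupe: bool = False,
    ) -> "AssortmentResults":
        """Observed assortment, jackknife SEs, permutation null and P values."""
        per_year_rows = []
        per_year_nulls = {}
        obs_pairs = []
        master = np.random.SeedSequence(seed)
        year_seeds = master.spawn(len(self.networks) + 1)
        for net, ss in zip(self.networks, year_seeds):
            r = assortativity_continuous(net)
            se = jackknife_se(net) if net.graph.number_of_edges() > 1 else None
            nl = netmod.count_links(net)
            null = null_distribution([net], n_perm=n_perm, seed=ss.generate_state(1)[0] % (2**31))
            p = p_value(r, null, tail)
            per_year_nulls[net.year] = null
            per_year_rows.append(
                AssortmentResult(
                    scope=(net.year, net.sex, net.method, net.k),
                    r_obs=r, se_jackknife=se, null_mean=null.mean,
                    effect_size=effect_size(r, null.mean), p_value=p,
                    n_links=nl, n_permutations=n_perm,
                )
            )
            obs_pairs.append((r, nl))
        combined_seed = int(year_seeds[-1].generate_state(1)[0] % (2**31))
        combined_null = null_distribution(
            self.networks, n_perm=n_perm, seed=combined_seed, dedupe=dedupe
        )
        if dedupe:
            r_comb = combined_null.observed_dedupe
            nl_comb = combined_null.n_links_dedupe
        else:
            r_comb = combine_years(obs_pairs)
            nl_comb = float(np.mean([nl for _, nl in obs_pairs]))
        net0 = self.networks[0]
        combined = AssortmentResult(
            scope=("combined", net0.sex, net0.method, net0.k),
            r_obs=r_comb, se_jackknife=None, null_mean=combined_null.mean,
            effect_size=effect_size(r_comb, combined_null.mean),
            p_value=p_value(r_comb, combined_null, tail),
            n_links=nl_comb, n_permutations=n_perm,
        )
        return AssortmentResults(
            model=self, per_year=per_year_rows, combined=combined,
            per_year_nulls=per_year_nulls, combined_null=combined_null,
            tail=tail, seed=seed, dedupe=dedupe,
        )


@dataclass
class AssortmentResults:
    """Fitted assortment analysis: estimates, uncertainties, null model."""

    model: PersonalityAssortment
    per_year: list[AssortmentResult]
    combined: AssortmentResult
    per_year_nulls: dict[int, NullDistribution]
    combined_null: NullDistribution
    tail: str
    seed: int | None
    dedupe: bool

    def frame(self) -> pd.DataFrame:
        """All rows (per year plus combined) as a DataFrame."""
        return pd.DataFrame([r.as_dict() for r in [*self.per_year, self.combined]])

    def summary(self) -> str:
        """Human-readable results table (3-decimal, like the field's tables)."""
        net0 = self.model.networks[0]
        head = (
            f"Personality assortment — sex={net0.sex}, method={net0.method}"
            + (f", k={net0.k}" if net0.k else "")
            + f", {'weighted' if net0.weighted else 'binary'}\n"
            f"permutations={self.combined.n_permutations}, tail={self.tail}, "
            f"dedupe={self.dedupe}, seed={self.seed}\n"
        )
        lines = [head]
        cols = f"{'scope':>9} {'links':>8} {'observed':>9} {'SE':>7} {'permuted':>9} {'effect':>7} {'P':>7}"
        lines.append(cols)
        lines.append("-" * len(cols))
        for r in [*self.per_year, self.combined]:
            se = f"{r.se_jackknife:7.3f}" if r.se_jackknife is not None else "      -"
            lines.append(
                f"{str(r.scope[0]):>9} {r.n_links:8.1f} {r.r_obs:9.3f} {se} "
                f"{r.null_mean:9.3f} {r.effect_size:7.3f} {r.p_value:7.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-year observed r (± jackknife SE) against the 95% null band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        years = [r.scope[0] for r in self.per_year]
        obs = [r.r_obs for r in self.per_year]
        ses = [r.se_jackknife or 0.0 for r in self.per_year]
        for i, (year, r, se) in enumerate(zip(years, obs, ses)):
            lo, hi = self.per_year_nulls[year].quantiles()
            ax.vlines(i, lo, hi, color="black", lw=2, zorder=1)
            ax.errorbar(i, r, yerr=se, fmt="o", color="tab:blue", capsize=3, zorder=2)
        ax.axhline(0.0, color="grey", lw=0.5, ls="--")
        ax.set_xticks(range(len(years)))
        ax.set_xticklabels([str(y) for y in years])
        ax.set_xlabel("year")
        ax.set_ylabel("assortment r")
        return ax
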