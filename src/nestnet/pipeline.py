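"""Whole-study orchestration: every network variant, observed + null.

``run_analysis`` sweeps the grid (method, k, sex, weighting) over all
years, fits a :class:`~nestnet.model.PersonalityAssortment` per cell, and
writes results tables (3-decimal presentation plus full-precision
machine-readable copies), per-year population summaries, network exports,
null-distribution dumps and a run manifest sufficient to reproduce the
run. A cell whose typed networks are all empty is reported as missing
rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import NestnetError
from .io import read_breeding_records, read_nestboxes, read_personality, summarize_population, write_network
from .model import PersonalityAssortment
from .simulate import ScenarioConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run (YAML-mappable)."""

    nestboxes: str | None = None
    breeding: str | None = None
    personality: str | None = None
    scenario: str | None = None  # simulate instead of reading tables
    years: list[int] | None = None
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    methods: list[str] = field(default_factory=lambda: ["knn", "thiessen"])
    k_values: list[int] = field(default_factory=lambda: [3, 5, 7])
    weightings: list[str] = field(default_factory=lambda: ["weighted"])
    region: str | None = None
    n_perm: int = 1000
    seed: int = 0
    tail: str = "two_sided"
    dedupe: bool = False
    restrict_order: str = "construct_then_restrict"
    outdir: str = "results"

    def __post_init__(self):
        if not self.methods or not self.sexes:
            raise ValueError("at least one method and one sex required")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        scen = ScenarioConfig.from_yaml(config.scenario)
        ds = simulate_dataset(scen)
        return ds.nestboxes, ds.records, ds.personality
    if not (config.nestboxes and config.breeding and config.personality):
        raise ValueError("provide either scenario or all three table paths")
    nestboxes = read_nestboxes(config.nestboxes)
    records = read_breeding_records(config.breeding, nestboxes)
    personality = read_personality(config.personality)
    return nestboxes, records, personality


def _cells(config: RunConfig):
    for sex in config.sexes:
        for method in config.methods:
            ks = config.k_values if method == "knn" else [None]
            for k in ks:
                for weighting in config.weightings:
                    yield sex, method, k, weighting == "weighted"


def run_analysis(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Run the full grid; returns (and optionally writes) the results table."""
    nestboxes, records, personality = _loaded = _load_inputs(config)
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "networks").mkdir(exist_ok=True)
        (outdir / "nulls").mkdir(exist_ok=True)
    years = config.years or sorted(records["year"].unique())
    seed_rng = np.random.default_rng(config.seed)
    all_rows = []
    for sex, method, k, weighted in _cells(config):
        cell = f"{sex}/{method}" + (f"-{k}" if k else "") + ("/w" if weighted else "/b")
        cell_seed = int(seed_rng.integers(2**31))
        logger.info("cell %s (seed %d)", cell, cell_seed)
        try:
            model = PersonalityAssortment.from_tables(
                records, nestboxes, personality, sex=sex, method=method,
                k=k or 5, weighted=weighted, years=years, region=config.region,
                restrict_order=config.restrict_order,
            )
            res = model.fit(
                n_perm=config.n_perm, seed=cell_seed, tail=config.tail,
                dedupe=config.dedupe,
            )
        except NestnetError as exc:
            logger.warning("cell %s missing: %s", cell, exc)
            all_rows.append(
                {"sex": sex, "method": method, "k": k,
                 "weighting": "weighted" if weighted else "binary",
                 "year": "combined", "status": "missing", "note": str(exc)}
            )
            continue
        frame = res.frame()
        frame.insert(0, "weighting", "weighted" if weighted else "binary")
        frame["status"] = "ok"
        all_rows.extend(frame.to_dict("records"))
        if write:
            tag = cell.replace("/", "_")
            np.savetxt(outdir / "nulls" / f"{tag}_combined_null.txt", res.combined_null.values)
            for net in model.networks:
                write_network(net, outdir / "networks" / f"{tag}_{net.year}.graphml")
    results = pd.DataFrame(all_rows)
    if write:
        full = outdir / "results_full.csv"
        results.to_csv(full, index=False)
        rounded = results.copy()
        for col in ("n_links", "observed", "se_jackknife", "permuted", "effect_size", "p_value"):
            if col in rounded.columns:
                rounded[col] = pd.to_numeric(rounded[col], errors="coerce").round(3)
        rounded.to_csv(outdir / "results.csv", index=False)
        summaries = [summarize_population(records, personality, nestboxes, label="all")]
        if config.region:
            summaries.append(
                summarize_population(records, personality, nestboxes, region=config.region)
            )
        pd.concat(summaries).to_csv(outdir / "population_summary.csv", index=False)
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "package_version": __version__,
            "n_results": int(len(results)),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results
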