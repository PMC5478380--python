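"""Readers, writers and population summaries for the three input tables.

The package exchanges three comma-separated tables (header row, UTF-8):

* nestboxes: ``box_id,x,y,region`` — candidate breeding sites, planar
  metric coordinates (distances are Euclidean; convert any geographic
  CRS upstream).
* breeding: ``year,box_id,male_id,female_id`` — one breeding attempt per
  box per year; either partner id may be missing, not both.
* personality: ``bird_id,sex,score`` — one continuous exploration score
  per bird (repeat assays must be pre-averaged by the caller; duplicate
  rows are rejected rather than silently averaged).

Networks are exported as GraphML or as an edge list with a ``.nodes.csv``
sidecar so that isolated nodes and node attributes survive the round trip.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

NESTBOX_COLUMNS = ["box_id", "x", "y", "region"]
BREEDING_COLUMNS = ["year", "box_id", "male_id", "female_id"]
PERSONALITY_COLUMNS = ["bird_id", "sex", "score"]

SEXES = ("male", "female")


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention of printed summary tables)."""
    value = float(value)
    if not np.isfinite(value):
        return float("nan")
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {missing}")


# ---------------------------------------------------------------------------
# readers / validators
# ---------------------------------------------------------------------------

def validate_nestboxes(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, NESTBOX_COLUMNS, "nestboxes")
    out = df.copy()
    out["box_id"] = out["box_id"].astype(str)
    out["region"] = out["region"].astype(str)
    for col in ("x", "y"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[~np.isfinite(coerced.to_numpy(dtype=float, na_value=np.nan))]
        if len(bad):
            rows = [int(i) + 2 for i in bad]  # +2: header + 1-based
            raise ValidationError(
                f"nestboxes: malformed coordinate {col!r} on file row(s) {rows}"
            )
        out[col] = coerced.astype(float)
    dup = out["box_id"][out["box_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"nestboxes: duplicate box_id(s): {sorted(set(dup))}")
    xy = out[["x", "y"]].to_numpy()
    _, counts = np.unique(xy, axis=0, return_counts=True)
    if (counts > 1).any():
        raise ValidationError("nestboxes: two or more boxes share identical coordinates")
    return out.reset_index(drop=True)


def read_nestboxes(path: str | Path) -> pd.DataFrame:
    """Read and validate a nestbox table; returns box_id, x, y, region."""
    return validate_nestboxes(pd.read_csv(path, dtype=str))


def validate_breeding_records(
    df: pd.DataFrame, nestboxes: pd.DataFrame | None = None
) -> pd.DataFrame:
    _require_columns(df, BREEDING_COLUMNS, "breeding")
    out = df.copy()
    out["year"] = pd.to_numeric(out["year"], errors="raise").astype(int)
    out["box_id"] = out["box_id"].astype(str)
    for col in ("male_id", "female_id"):
        out[col] = out[col].astype("string")
        out.loc[out[col].isin(["", "NA", "nan"]), col] = pd.NA
    both_missing = out["male_id"].isna() & out["female_id"].isna()
    if both_missing.any():
        rows = [int(i) + 2 for i in out.index[both_missing]]
        raise ValidationError(f"breeding: neither partner identified on row(s) {rows}")
    dup = out.duplicated(subset=["year", "box_id"])
    if dup.any():
        pairs = out.loc[dup, ["year", "box_id"]].to_records(index=False).tolist()
        raise ValidationError(f"breeding: duplicated (year, box_id): {pairs}")
    if nestboxes is not None:
        known = set(nestboxes["box_id"])
        unknown = sorted(set(out["box_id"]) - known)
        if unknown:
            raise ValidationError(f"breeding: unknown box_id(s): {unknown}")
    return out.reset_index(drop=True)


def read_breeding_records(
    path: str | Path, nestboxes: pd.DataFrame | None = None
) -> pd.DataFrame:
    return validate_breeding_records(pd.read_csv(path, dtype=str), nestboxes)


def validate_personality(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, PERSONALITY_COLUMNS, "personality")
    out = df.copy()
    out["bird_id"] = out["bird_id"].astype(str)
    out["sex"] = out["sex"].astype(str)
    bad_sex = sorted(set(out["sex"]) - set(SEXES))
    if bad_sex:
        raise ValidationError(f"personality: sex must be one of {SEXES}; got {bad_sex}")
    out["score"] = pd.to_numeric(out["score"], errors="raise").astype(float)
    if not np.isfinite(out["score"]).all():
        raise ValidationError("personality: non-finite score(s)")
    dup = out["bird_id"][out["bird_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"personality: bird(s) with more than one score: {sorted(set(dup))}; "
            "pre-average repeat assays upstream"
        )
    return out.reset_index(drop=True)


def read_personality(path: str | Path) -> pd.DataFrame:
    return validate_personality(pd.read_csv(path, dtype=str))


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def summarize_population(
    records: pd.DataFrame,
    personality: pd.DataFrame,
    nestboxes: pd.DataFrame | None = None,
    region: str | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-year counts of breeding pairs and personality-typed breeders.

    Returns one row per year with columns region, year, n_pairs,
    n_typed_males, prop_typed_males, n_typed_females, prop_typed_females.
    Proportions are typed/pairs rounded half-up to 3 decimals; a year with
    zero pairs reports NaN proportions. ``region`` restricts the records to
    nestboxes carrying that region label (requires ``nestboxes``).
    """
    recs = records
    if region is not None:
        if nestboxes is None:
            raise ValueError("region filtering requires a nestboxes table")
        boxes = set(nestboxes.loc[nestboxes["region"] == region, "box_id"])
        recs = records[records["box_id"].isin(boxes)]
    typed = {
        sex: set(personality.loc[personality["sex"] == sex, "bird_id"])
        for sex in SEXES
    }
    rows = []
    for year, grp in recs.groupby("year", sort=True):
        n_pairs = len(grp)
        n_m = grp["male_id"].dropna().isin(typed["male"]).sum()
        n_f = grp["female_id"].dropna().isin(typed["female"]).sum()
        rows.append(
            {
                "region": label or region or "all",
                "year": int(year),
                "n_pairs": int(n_pairs),
                "n_typed_males": int(n_m),
                "prop_typed_males": round_half_up(n_m / n_pairs) if n_pairs else float("nan"),
                "n_typed_females": int(n_f),
                "prop_typed_females": round_half_up(n_f / n_pairs) if n_pairs else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "year", "n_pairs",
            "n_typed_males", "prop_typed_males",
            "n_typed_females", "prop_typed_females",
        ],
    )


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("box_id", "x", "y", "score")


def write_network(network, path: str | Path, fmt: str = "graphml") -> None:
    """Serialise a :class:`~nestnet.networks.SpatialNetwork`.

    ``graphml`` keeps everything in one file; ``edgelist`` writes
    ``source,target,weight`` rows plus a ``<path>.nodes.csv`` sidecar with
    node attributes so isolated nodes round-trip too. Weights are written
    at full float precision.
    """
    path = Path(path)
    g = network.graph
    if fmt == "graphml":
        h = g.copy()
        h.graph.update(network.metadata())
        for _, data in h.nodes(data=True):
            if data.get("score") is None or (
                isinstance(data.get("score"), float) and np.isnan(data["score"])
            ):
                data.pop("score", None)
        nx.write_graphml(h, path)
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source,target,weight\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u},{v},{data['weight']!r}\n")
        nodes = []
        for n, data in g.nodes(data=True):
            row = {"bird_id": n}
            for a in _NODE_ATTRS:
                row[a] = data.get(a)
            nodes.append(row)
        pd.DataFrame(nodes, columns=["bird_id", *_NODE_ATTRS]).to_csv(
            path.with_suffix(path.suffix + ".nodes.csv"), index=False
        )
        meta = network.metadata()
        pd.DataFrame([meta]).to_csv(
            path.with_suffix(path.suffix + ".meta.csv"), index=False
        )
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml"):
    from .networks import SpatialNetwork

    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        meta = dict(g.graph)
        directed = g.is_directed()
        cls = nx.DiGraph if directed else nx.Graph
        h = cls()
        for n, data in g.nodes(data=True):
            attrs = {a: data[a] for a in _NODE_ATTRS if a in data}
            if "x" in attrs:
                attrs["x"] = float(attrs["x"])
            if "y" in attrs:
                attrs["y"] = float(attrs["y"])
            if "score" in attrs:
                attrs["score"] = float(attrs["score"])
            h.add_node(str(n), **attrs)
        for u, v, data in g.edges(data=True):
            h.add_edge(str(u), str(v), weight=float(data["weight"]))
    elif fmt == "edgelist":
        meta_df = pd.read_csv(path.with_suffix(path.suffix + ".meta.csv"))
        meta = meta_df.iloc[0].to_dict() if len(meta_df) else {}
        directed = bool(meta.get("directed", True))
        cls = nx.DiGraph if directed else nx.Graph
        h = cls()
        nodes = pd.read_csv(path.with_suffix(path.suffix + ".nodes.csv"), dtype={"bird_id": str, "box_id": str})
        for _, row in nodes.iterrows():
            attrs = {}
            if pd.notna(row.get("box_id")):
                attrs["box_id"] = str(row["box_id"])
            for a in ("x", "y", "score"):
                if pd.notna(row.get(a)):
                    attrs[a] = float(row[a])
            h.add_node(str(row["bird_id"]), **attrs)
        edges = pd.read_csv(
            path, dtype={"source": str, "target": str}, float_precision="round_trip"
        )
        for _, row in edges.iterrows():
            h.add_edge(str(row["source"]), str(row["target"]), weight=float(row["weight"]))
    else:
        raise ValueError(f"unknown network format: {fmt!r}")

    def _get(key, cast, default=None):
        v = meta.get(key, default)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return default
        return cast(v)

    return SpatialNetwork(
        graph=h,
        year=_get("year", int),
        sex=_get("sex", str),
        method=_get("method", str, "knn"),
        k=_get("k", int),
        weighted=bool(_get("weighted", lambda v: str(v).lower() in ("true", "1"), True)),
    )
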