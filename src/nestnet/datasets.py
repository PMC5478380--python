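"""Published reference tables from a six-year great tit breeding study.

These are the printed population and assortment summary tables from a
long-term nestbox study at Wytham Woods (2005–2010, with a focal
well-sampled section, Marley). The underlying field data are not public;
the tables serve as arithmetic fixtures: population counts for checking
:func:`nestnet.io.summarize_population` proportions, and assortment rows
for checking effect-size bookkeeping. Nothing here feeds the estimators
themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# region, year, breeding pairs, typed males, typed females
_POPULATION_COUNTS = [
    ("Marley", 2005, 120, 46, 53),
    ("Marley", 2006, 93, 47, 51),
    ("Marley", 2007, 107, 51, 69),
    ("Marley", 2008, 108, 45, 48),
    ("Marley", 2009, 79, 38, 45),
    ("Marley", 2010, 93, 32, 47),
    ("Wytham", 2005, 493, 99, 107),
    ("Wytham", 2006, 432, 142, 144),
    ("Wytham", 2007, 481, 159, 203),
    ("Wytham", 2008, 470, 140, 168),
    ("Wytham", 2009, 324, 106, 122),
    ("Wytham", 2010, 381, 94, 116),
]

# printed proportions accompanying the counts above (typed/pairs at 3 dp)
_POPULATION_PROPORTIONS = [
    (0.383, 0.442), (0.505, 0.548), (0.477, 0.645), (0.417, 0.444),
    (0.481, 0.570), (0.344, 0.505),
    (0.201, 0.217), (0.329, 0.333), (0.331, 0.422), (0.298, 0.357),
    (0.327, 0.377), (0.247, 0.304),
]

# scope, variant, sex, n_links, observed, permuted, effect size, p
# k-NN rows are Marley, weighted; Thiessen rows as labelled.
_ASSORTMENT_ROWS = [
    ("Marley", "knn-3", "male", 60.5, 0.140, -0.034, 0.174, 0.020),
    ("Marley", "knn-5", "male", 102.7, 0.092, -0.027, 0.120, 0.030),
    ("Marley", "knn-7", "male", 141.8, 0.108, -0.027, 0.135, 0.004),
    ("Marley", "knn-3", "female", 93.2, 0.004, -0.024, 0.028, 0.606),
    ("Marley", "knn-5", "female", 153.2, 0.041, -0.024, 0.065, 0.130),
    ("Marley", "knn-7", "female", 212.0, 0.046, -0.024, 0.070, 0.066),
    ("Marley", "thiessen-weighted", "male", 99.7, -0.017, -0.031, 0.014, 0.796),
    ("Marley", "thiessen-binary", "male", 99.7, -0.001, -0.029, 0.029, 0.568),
    ("Marley", "thiessen-nodup", "male", 96.0, -0.015, -0.032, 0.017, 0.755),
    ("Wytham", "thiessen-weighted", "male", 235.0, 0.000, -0.013, 0.013, 0.694),
    ("Marley", "thiessen-weighted", "female", 149.3, 0.042, -0.028, 0.070, 0.122),
    ("Marley", "thiessen-binary", "female", 149.3, 0.039, -0.027, 0.066, 0.142),
    ("Marley", "thiessen-nodup", "female", 143.2, 0.031, -0.024, 0.055, 0.238),
    ("Wytham", "thiessen-weighted", "female", 320.0, 0.025, -0.010, 0.035, 0.258),
]


def population_counts() -> pd.DataFrame:
    """Per-region per-year pair counts and typed-breeder counts, with the
    printed proportions alongside."""
    df = pd.DataFrame(
        _POPULATION_COUNTS,
        columns=["region", "year", "n_pairs", "n_typed_males", "n_typed_females"],
    )
    props = pd.DataFrame(
        _POPULATION_PROPORTIONS,
        columns=["printed_prop_typed_males", "printed_prop_typed_females"],
    )
    return pd.concat([df, props], axis=1)


def assortment_reference() -> pd.DataFrame:
    """Printed across-year assortment summaries (observed, permuted mean,
    effect size, P, mean link count) per network variant and sex."""
    return pd.DataFrame(
        _ASSORTMENT_ROWS,
        columns=[
            "region", "variant", "sex", "n_links",
            "observed", "permuted", "effect_size", "p_value",
        ],
    )


def counts_to_tables(counts: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand the summary counts into synthetic breeding/personality tables.

    Builds, for each year, one breeding record per pair (Marley pairs form
    a subset of the Wytham total, as in the source woodland) and marks
    exactly the counted numbers of males/females as personality-typed, so
    that :func:`nestnet.io.summarize_population` can recompute the printed
    proportions from table-shaped input. Scores are synthetic placeholders
    (the proportions do not depend on them).
    """
    counts = population_counts() if counts is None else counts
    recs, typed = [], []
    for _, row in counts[counts["region"] == "Wytham"].iterrows():
        year = int(row["year"])
        m_row = counts[(counts["region"] == "Marley") & (counts["year"] == year)]
        n_marley = int(m_row["n_pairs"].iloc[0]) if len(m_row) else 0
        nm_marley = int(m_row["n_typed_males"].iloc[0]) if len(m_row) else 0
        nf_marley = int(m_row["n_typed_females"].iloc[0]) if len(m_row) else 0
        n_total = int(row["n_pairs"])
        nm_total, nf_total = int(row["n_typed_males"]), int(row["n_typed_females"])
        for i in range(n_total):
            in_marley = i < n_marley
            box = f"{'M' if in_marley else 'W'}{year}-{i:04d}"
            male, female = f"m{year}-{i:04d}", f"f{year}-{i:04d}"
            recs.append({"year": year, "box_id": box, "male_id": male, "female_id": female})
            # typed males: first nm_marley inside Marley, remainder outside
            if (in_marley and i < nm_marley) or (
                not in_marley and n_marley <= i < n_marley + (nm_total - nm_marley)
            ):
                typed.append({"bird_id": male, "sex": "male", "score": float(i % 7)})
            if (in_marley and i < nf_marley) or (
                not in_marley and n_marley <= i < n_marley + (nf_total - nf_marley)
            ):
                typed.append({"bird_id": female, "sex": "female", "score": float(i % 5)})
    records = pd.DataFrame(recs, columns=["year", "box_id", "male_id", "female_id"])
    personality = pd.DataFrame(typed, columns=["bird_id", "sex", "score"])
    return records, personality


def counts_to_nestboxes(records: pd.DataFrame) -> pd.DataFrame:
    """Minimal nestbox table for the expanded counts: Marley boxes carry the
    'Marley' region label; coordinates are an arbitrary non-degenerate grid."""
    boxes = sorted(set(records["box_id"]))
    n = len(boxes)
    side = int(np.ceil(np.sqrt(n)))
    rows = []
    for i, b in enumerate(boxes):
        rows.append(
            {
                "box_id": b,
                "x": 50.0 * (i % side),
                "y": 50.0 * (i // side),
                "region": "Marley" if b.startswith("M") else "Wytham-other",
            }
        )
    return pd.DataFrame(rows, columns=["box_id", "x", "y", "region"])
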