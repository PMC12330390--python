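"""Within- versus between-region genome-similarity contrasts.

Pairwise average-nucleotide-identity (ANI) records are analyzed at two
tiers: species level (all pairs) and strain level (pairs with ANI >= 95%,
the conventional species boundary).  For each focal region, within-region
similarity is contrasted against between-region similarity with a
rank-sum test, and region pairs are summarized and ordered by the
great-circle distance between region centroids.
"""

from __future__ import annotations

import pandas as pd

from .biogeography_stats import GroupContrast, bh_adjust, haversine_km, rank_sum_contrast
from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "STRAIN_ANI_THRESHOLD",
    "tier_filter",
    "within_between_contrast",
    "region_centroids",
    "region_pair_ordering",
]

#: Genome pairs at or above this ANI belong to the same species; such
#: pairs constitute the strain-level tier (inclusive bound).
STRAIN_ANI_THRESHOLD = 95.0

_ANI_COLS = ["genome_a", "genome_b", "ani_percent", "region_a", "region_b"]


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in _ANI_COLS if c not in records.columns]
    if missing:
        raise InvalidArgumentError(f"ANI records lack columns {missing}")


def tier_filter(records: pd.DataFrame, tier: str) -> pd.DataFrame:
    """Select the similarity tier: 'species' keeps all pairs, 'strain' keeps ANI >= 95."""
    _check_records(records)
    if tier == "species":
        return records.copy()
    if tier == "strain":
        return records.loc[records["ani_percent"] >= STRAIN_ANI_THRESHOLD].copy()
    raise InvalidArgumentError(f"unknown tier {tier!r} (expected 'species' or 'strain')")


def within_between_contrast(records: pd.DataFrame, focal_region: str,
                            alternative: str = "two-sided") -> GroupContrast:
    """Rank-sum contrast of within- vs between-region ANI for one region.

    Within = both genomes from the focal region; between = exactly one.
    Raises :class:`InsufficientDataError` when either side is empty (as
    happens for region pairs with no strain-level genome pairs).
    """
    _check_records(records)
    a = records["region_a"].to_numpy()
    b = records["region_b"].to_numpy()
    within = records.loc[(a == focal_region) & (b == focal_region), "ani_percent"]
    between = records.loc[(a == focal_region) ^ (b == focal_region), "ani_percent"]
    if within.empty or between.empty:
        raise InsufficientDataError(
            f"region {focal_region!r}: {len(within)} within-region and "
            f"{len(between)} between-region pairs; need at least 1 of each")
    return rank_sum_contrast(within, between, group_a=f"within:{focal_region}",
                             group_b=f"between:{focal_region}",
                             alternative=alternative)


def region_centroids(metadata: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean sample coordinates per region."""
    for col in ("region", "latitude", "longitude"):
        if col not in metadata.columns:
            raise InvalidArgumentError(f"metadata lacks column {col!r}")
    return metadata.groupby("region")[["latitude", "longitude"]].mean()


def region_pair_ordering(records: pd.DataFrame,
                         metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of every unordered region pair, ordered by centroid distance.

    Returns ``(summaries, contrasts)``.  ``summaries`` has one row per
    region pair with its pair count, median between-region ANI and
    centroid distance, sorted by distance descending (ties broken
    lexicographically on the pair label).  ``contrasts`` holds all
    pairwise rank-sum comparisons between the region-pair ANI
    distributions, BH-adjusted.
    """
    _check_records(records)
    cent = region_centroids(metadata)
    regions = sorted(cent.index)
    key = records.apply(
        lambda r: " - ".join(sorted([r["region_a"], r["region_b"]])), axis=1)
    between = records.loc[records["region_a"] != records["region_b"]].copy()
    between["pair"] = key[between.index]

    rows = []
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            pair = f"{ra} - {rb}"
            vals = between.loc[between["pair"] == pair, "ani_percent"]
            rows.append({
                "region_pair": pair,
                "n_pairs": int(len(vals)),
                "median_ani": float(vals.median()) if len(vals) else float("nan"),
                "centroid_distance_km": haversine_km(
                    cent.loc[ra, "latitude"], cent.loc[ra, "longitude"],
                    cent.loc[rb, "latitude"], cent.loc[rb, "longitude"]),
            })
    summaries = (pd.DataFrame(rows)
                 .sort_values(["centroid_distance_km", "region_pair"],
                              ascending=[False, True])
                 .reset_index(drop=True))

    con_rows = []
    pairs_with_data = [r["region_pair"] for r in rows if r["n_pairs"] > 0]
    for i, pa in enumerate(pairs_with_data):
        for pb in pairs_with_data[i + 1:]:
            c = rank_sum_contrast(
                between.loc[between["pair"] == pa, "ani_percent"],
                between.loc[between["pair"] == pb, "ani_percent"],
                group_a=pa, group_b=pb)
            con_rows.append({"group_a": pa, "group_b": pb,
                             "statistic": c.statistic, "p_value": c.p_value,
                             "median_a": c.median_a, "median_b": c.median_b})
    contrasts = pd.DataFrame(con_rows)
    if not contrasts.empty:
        contrasts["p_adjusted"] = bh_adjust(contrasts["p_value"].to_numpy())
    return summaries, contrasts
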