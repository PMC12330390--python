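"""Species abundance estimation and geographic-occupancy classification.

Abundance follows the read-recruitment convention: per species, mapped
bases are divided by the representative-sequence length to give a
recruitment rate, and rates are renormalized per sample to sum to one
million (TPM).  Occupancy classes partition species by the regions in
which they are detected — core (all regions), endemic (exactly one) and
intermediate — and the range-size index summarizes how evenly a species'
abundance spreads across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidMetadataError

__all__ = [
    "AbundanceTable",
    "tpm_abundance",
    "abundance_table",
    "classify_occupancy",
    "occupancy_summary",
    "range_size",
    "range_size_table",
    "classify_gene_occupancy",
]

_SUMMARY_COLS = ["species_id", "sample_id", "mapped_bases", "ref_length_bp",
                 "sample_total_bases"]


@dataclass
class AbundanceTable:
    """Species x sample TPM matrix plus per-sample metadata.

    ``matrix`` is indexed by species_id with one column per sample_id;
    ``metadata`` is indexed by sample_id with columns region, habitat,
    latitude, longitude.  Every sample in the matrix must carry a region.
    """

    matrix: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.metadata
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        missing = [s for s in self.matrix.columns if s not in meta.index]
        if missing:
            raise InvalidMetadataError(f"samples without metadata: {missing[:5]}")
        if meta.loc[list(self.matrix.columns), "region"].isna().any():
            raise InvalidMetadataError("every sample must be assigned a region")
        self.metadata = meta

    @property
    def regions(self) -> list:
        return sorted(self.metadata.loc[list(self.matrix.columns), "region"].unique())

    def region_of(self) -> pd.Series:
        return self.metadata.loc[list(self.matrix.columns), "region"]


def tpm_abundance(summaries: pd.DataFrame, sample_id: str) -> pd.Series:
    """Per-species TPM for one sample.

    rate_i = mapped_bases_i / ref_length_i; TPM_i = rate_i / sum(rates) * 1e6.
    Returns the zero vector when no species recruited any bases.
    """
    sub = summaries.loc[summaries["sample_id"] == sample_id]
    if sub.empty:
        raise InvalidArgumentError(f"no mapping summaries for sample {sample_id!r}")
    if (sub["ref_length_bp"] <= 0).any():
        raise InvalidArgumentError("ref_length_bp must be positive")
    if (sub["mapped_bases"] < 0).any():
        raise InvalidArgumentError("mapped_bases must be non-negative")
    rate = sub["mapped_bases"].to_numpy(float) / sub["ref_length_bp"].to_numpy(float)
    total = rate.sum()
    tpm = rate / total * 1e6 if total > 0 else np.zeros_like(rate)
    return pd.Series(tpm, index=pd.Index(sub["species_id"], name="species_id"),
                     name=sample_id)


def abundance_table(summaries: pd.DataFrame, metadata: pd.DataFrame) -> AbundanceTable:
    """Build the full species x sample TPM matrix from mapping summaries.

    Species absent from a sample's summaries get TPM 0 there.
    """
    for col in _SUMMARY_COLS[:4]:
        if col not in summaries.columns:
            raise InvalidArgumentError(f"mapping summaries lack column {col!r}")
    cols = [tpm_abundance(summaries, s) for s in sorted(summaries["sample_id"].unique())]
    matrix = pd.concat(cols, axis=1).fillna(0.0).sort_index()
    matrix.columns.name = "sample_id"
    return AbundanceTable(matrix=matrix, metadata=metadata.copy())


def classify_occupancy(table: AbundanceTable,
                       presence_threshold: float = 0.0) -> pd.DataFrame:
    """Per-species region-presence sets and occupancy classes.

    A species is present in a region iff its TPM exceeds
    ``presence_threshold`` in at least one sample of that region.  Classes:
    core = present in every region, endemic = exactly one region,
    intermediate = anything in between.  Species detected nowhere (possible
    at a positive threshold) are classed ``absent``.
    """
    region_of = table.region_of()
    present = table.matrix > presence_threshold  # species x samples
    by_region = present.T.groupby(region_of).any().T  # species x regions
    n_regions = by_region.shape[1]
    n_present = by_region.sum(axis=1)
    cls = np.select(
        [n_present == n_regions, n_present == 1, n_present == 0],
        ["core", "endemic", "absent"],
        default="intermediate",
    )
    regions_present = by_region.apply(
        lambda row: ";".join(sorted(row.index[row])), axis=1)
    out = pd.DataFrame({
        "species_id": by_region.index,
        "n_regions": n_present.to_numpy(),
        "regions_present": regions_present.to_numpy(),
        "occupancy_class": cls,
    }).reset_index(drop=True)
    return out


def occupancy_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per occupancy class, plus per-region endemic counts."""
    total = len(profiles)
    rows = []
    for cls, cnt in profiles["occupancy_class"].value_counts().items():
        rows.append({"group": f"class:{cls}", "count": int(cnt),
                     "fraction": cnt / total})
    endemics = profiles.loc[profiles["occupancy_class"] == "endemic"]
    n_end = len(endemics)
    for region, cnt in endemics["regions_present"].value_counts().items():
        rows.append({"group": f"endemic:{region}", "count": int(cnt),
                     "fraction": cnt / n_end if n_end else float("nan")})
    return pd.DataFrame(rows)


def range_size(abundance_fraction_per_region: np.ndarray) -> float:
    """Range-size index: 1 minus the sample SD of the region abundance fractions.

    The fractions must be non-negative and sum to 1 over the K regions.
    With K = 4 the index runs from 0.5 (all abundance in one region) to
    1.0 (even spread).  The sample standard deviation (K-1 denominator) is
    used; it is the convention for which a one-hot vector gives exactly 0.5.
    """
    f = np.asarray(abundance_fraction_per_region, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise InvalidArgumentError("need a 1-D vector of >= 2 region fractions")
    if np.any(f < 0):
        raise InvalidArgumentError("fractions must be non-negative")
    total = f.sum()
    if total == 0:
        raise InvalidArgumentError("all-zero species: range size undefined")
    if abs(total - 1.0) > 1e-8:
        raise InvalidArgumentError("fractions must sum to 1")
    return float(1.0 - f.std(ddof=1))


def range_size_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-species range-size index from region-summed TPM fractions.

    Each species' TPM is summed within each region and divided by its
    global total; species with zero total abundance are flagged and
    excluded (``range_size`` = NaN).
    """
    region_of = table.region_of()
    by_region = table.matrix.T.groupby(region_of).sum().T  # species x regions
    totals = by_region.sum(axis=1)
    frac = by_region.div(totals.replace(0, np.nan), axis=0)
    rs = 1.0 - frac.std(axis=1, ddof=1)
    return pd.DataFrame({
        "species_id": by_region.index,
        "range_size": rs.to_numpy(),
        "excluded": (totals == 0).to_numpy(),
    }).reset_index(drop=True)


def classify_gene_occupancy(genome_ko: pd.DataFrame,
                            genome_region: pd.Series | dict) -> pd.DataFrame:
    """Classify gene families (KOs) by the regions of their carrier genomes.

    ``genome_ko``: long table with columns genome_id, ko_id (one row per
    annotation).  Singleton KOs (carried by exactly one genome) are
    discarded first — a guard against assembly and annotation artifacts —
    and the remainder are classified like species: shared (all regions),
    region-specific (one region) or multi-region.
    """
    if not {"genome_id", "ko_id"}.issubset(genome_ko.columns):
        raise InvalidArgumentError("genome_ko needs columns genome_id, ko_id")
    if genome_ko.empty:
        raise InvalidArgumentError("empty annotation table")
    region_map = pd.Series(genome_region)
    missing = set(genome_ko["genome_id"]) - set(region_map.index)
    if missing:
        raise InvalidMetadataError(f"genomes without region: {sorted(missing)[:5]}")
    n_region_total = region_map.nunique()
    df = genome_ko.drop_duplicates(["genome_id", "ko_id"]).copy()
    df["region"] = df["genome_id"].map(region_map)
    grp = df.groupby("ko_id").agg(
        n_genomes=("genome_id", "nunique"),
        n_regions=("region", "nunique"),
        regions_present=("region", lambda r: ";".join(sorted(set(r)))),
    )
    cls = np.select(
        [grp["n_genomes"] == 1, grp["n_regions"] == n_region_total,
         grp["n_regions"] == 1],
        ["discarded-singleton", "shared", "region-specific"],
        default="multi-region",
    )
    grp["occupancy_class"] = cls
    return grp.reset_index()
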