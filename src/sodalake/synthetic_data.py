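"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate a 51-sample, four-region soda-lake survey design
(East African Rift Valley, Inner Mongolia in China, the Kulunda Steppe in
Russia, and the Cariboo Plateau in Canada): read-recruitment summaries and
sample metadata for community profiling, pairwise genome ANI records,
genome sizes coupled to range size, and Mk-evolved tip states on a Yule
tree with a known rate matrix.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .mk_transition import RateModel, TipStateMatrix, _edge_probabilities
from .trees import Phylogeny, yule_tree

__all__ = [
    "Region",
    "DEFAULT_REGIONS",
    "SimConfig",
    "MkSimConfig",
    "SyntheticCommunity",
    "generate_tree",
    "simulate_tip_states",
    "generate_abundance_inputs",
    "generate_ani_pairs",
    "generate_genome_sizes",
]


@dataclass(frozen=True)
class Region:
    """A geographic region: label, centroid coordinates, sample count."""

    name: str
    latitude: float
    longitude: float
    n_samples: int = 13


#: Four centroids approximating the surveyed regions; inter-region
#: great-circle distances span roughly 2,000-15,000 km.  Sample counts
#: follow the 51-sample survey (Africa 14, China 18, Russia 15, Canada 4).
DEFAULT_REGIONS = (
    Region("Africa", -2.5, 36.0, 14),
    Region("China", 41.0, 107.0, 18),
    Region("Russia", 51.7, 79.8, 15),
    Region("Canada", 51.3, -121.6, 4),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the community generator.

    ``core_fraction`` / ``endemic_fraction`` default to the observed
    proportions of all-region and single-region species (16.3% / 34.5%);
    the remainder is intermediate (2 to K-1 regions).  ``decay_scale_km``
    controls how fast a species' per-sample presence probability decays
    with distance from its home-region centroid, which is what produces
    the distance-decay signal downstream.
    """

    n_species: int = 3526
    n_samples_per_region: int | None = None
    regions: tuple = DEFAULT_REGIONS
    core_fraction: float = 0.163
    endemic_fraction: float = 0.345
    decay_scale_km: float = 3000.0
    home_presence_floor: float = 0.7
    lognormal_mu: float = 10.0
    lognormal_sigma: float = 2.0
    habitat_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise InvalidArgumentError("need at least 2 regions")
        if not (0 <= self.core_fraction <= 1 and 0 <= self.endemic_fraction <= 1):
            raise InvalidArgumentError("fractions must lie in [0, 1]")
        if self.core_fraction + self.endemic_fraction > 1 + 1e-12:
            raise InvalidArgumentError("core_fraction + endemic_fraction must be <= 1")
        if self.decay_scale_km <= 0:
            raise InvalidArgumentError("decay_scale_km must be positive")
        if not 0 <= self.home_presence_floor <= 1:
            raise InvalidArgumentError("home_presence_floor must lie in [0, 1]")
        if self.n_species < 1:
            raise InvalidArgumentError("n_species must be >= 1")

    def samples_per_region(self) -> dict:
        if self.n_samples_per_region is not None:
            return {r.name: int(self.n_samples_per_region) for r in self.regions}
        return {r.name: r.n_samples for r in self.regions}


@dataclass(frozen=True)
class MkSimConfig:
    """Forward-simulation settings for tip states under a known rate matrix.

    ``true_rates`` maps ordered state pairs (i, j) to instantaneous rates
    q_ij; unlisted pairs default to 0.
    """

    n_tips: int = 300
    birth_rate: float = 1.0
    true_rates: dict = field(default_factory=dict)
    root_frequencies: tuple = (1 / 3, 1 / 3, 1 / 3)
    state_names: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rf = np.asarray(self.root_frequencies, float)
        if abs(rf.sum() - 1.0) > 1e-8 or np.any(rf < 0):
            raise InvalidArgumentError("root_frequencies must sum to 1 and be non-negative")
        for p, q in self.true_rates.items():
            if q < 0:
                raise InvalidArgumentError(f"negative rate for pair {p}")

    @property
    def n_states(self) -> int:
        return len(self.root_frequencies)

    def rate_model(self) -> RateModel:
        K = self.n_states
        rates = {(i, j): 0.0 for i in range(K) for j in range(K) if i != j}
        rates.update({tuple(p): float(q) for p, q in self.true_rates.items()})
        names = self.state_names or tuple(f"S{i}" for i in range(K))
        return RateModel(n_states=K, rates=rates, state_names=names,
                         root_frequencies=np.asarray(self.root_frequencies, float))


# ======================================================================
# trees and tip states
# ======================================================================

def generate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` labelled extant tips."""
    return yule_tree(n_tips, birth_rate, seed)


def simulate_tip_states(tree: Phylogeny, config: MkSimConfig) -> TipStateMatrix:
    """Evolve one discrete state per tip along ``tree`` under the CTMC.

    The root state is drawn from ``config.root_frequencies``; each branch
    applies the transition kernel P(t) = exp(Qt) of the true rate matrix.
    Returns one-hot tip vectors; ambiguity coding, when wanted, is applied
    afterwards (see :func:`sodalake.mk_transition.encode_tip_states`).
    """
    model = config.rate_model()
    K = model.n_states
    rng = np.random.default_rng(config.seed)
    Q = model.generator()
    P = _edge_probabilities(Q, tree.edge_length)
    state = np.empty(tree.n_nodes, dtype=np.int64)
    # preorder: parents before children
    order = [tree.root]
    stack = list(tree.children[tree.root])
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(tree.children[node])
    state[tree.root] = rng.choice(K, p=model.root_frequencies)
    for node in order[1:]:
        state[node] = rng.choice(K, p=P[node][state[tree.parent[node]]])
    mat = np.zeros((tree.n_tips, K))
    mat[np.arange(tree.n_tips), state[: tree.n_tips]] = 1.0
    return TipStateMatrix(tip_labels=list(tree.tip_labels), matrix=mat,
                          state_names=model.state_names)


# ======================================================================
# community abundance inputs
# ======================================================================

@dataclass
class SyntheticCommunity:
    """Generator output: the two input tables plus the hidden ground truth."""

    mapping_summaries: pd.DataFrame
    sample_metadata: pd.DataFrame
    truth: pd.DataFrame  # species_id, occupancy_class, home_region, regions_present


def _haversine_km(lat1, lon1, lat2, lon2):
    # local copy to avoid a circular import with biogeography_stats
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(a))


def generate_abundance_inputs(config: SimConfig) -> SyntheticCommunity:
    """Read-mapping summaries + sample metadata with a known occupancy design.

    Species are split into core (seeded into every region), endemic (one
    home region only) and intermediate (2 to K-1 regions, chosen with
    distance-decaying inclusion probability).  Within its allowed regions a
    species appears in a sample with probability exp(-d/decay_scale_km)
    where d is the sample-to-home-centroid distance, and is forced into at
    least one sample of each allowed region so generated occupancy classes
    are recoverable exactly.  Mapped bases are log-normal; representative
    sequence lengths and per-sample total bases are included so abundance
    estimation has to perform the real normalization.
    """
    rng = np.random.default_rng(config.seed)
    regions = list(config.regions)
    K = len(regions)
    rnames = [r.name for r in regions]
    centroid = {r.name: (r.latitude, r.longitude) for r in regions}
    counts = config.samples_per_region()

    # ---- samples: jittered around region centroids, alternating habitat
    rows = []
    for r in regions:
        for k in range(counts[r.name]):
            rows.append({
                "sample_id": f"{r.name}_s{k + 1:02d}",
                "region": r.name,
                "habitat": "water" if k % 2 == 0 else "sediment",
                "latitude": r.latitude + rng.normal(0.0, 1.0),
                "longitude": r.longitude + rng.normal(0.0, 1.0),
            })
    metadata = pd.DataFrame(rows)

    # ---- species classes and allowed regions
    n = config.n_species
    n_core = int(round(config.core_fraction * n))
    n_end = int(round(config.endemic_fraction * n))
    n_end = min(n_end, n - n_core)
    classes = (["core"] * n_core + ["endemic"] * n_end
               + ["intermediate"] * (n - n_core - n_end))
    home = [rnames[i] for i in rng.integers(0, K, size=n)]
    region_dist = {
        (a, b): float(_haversine_km(*centroid[a], *centroid[b]))
        for a in rnames for b in rnames
    }
    allowed: list[list[str]] = []
    for cls, h in zip(classes, home):
        if cls == "core":
            allowed.append(rnames)
        elif cls == "endemic":
            allowed.append([h])
        else:
            others = [r for r in rnames if r != h]
            inc = [r for r in others
                   if rng.uniform() < math.exp(-region_dist[(h, r)] / config.decay_scale_km)]
            if not inc:  # intermediate must span >= 2 regions
                inc = [min(others, key=lambda r: region_dist[(h, r)])]
            if len(inc) == len(others):  # ... and < K regions
                inc.remove(max(inc, key=lambda r: region_dist[(h, r)]))
            allowed.append([h] + inc)

    # ---- per-sample presence and mapped bases
    ref_length = rng.integers(1500, 6000, size=n)
    sample_region = metadata["region"].to_numpy()
    sample_ids = metadata["sample_id"].to_numpy()
    d_home = {}  # (home_region, sample index) -> km
    for h in set(home):
        hlat, hlon = centroid[h]
        d_home[h] = _haversine_km(hlat, hlon,
                                  metadata["latitude"].to_numpy(),
                                  metadata["longitude"].to_numpy())
    habitat_pref = rng.choice([-1.0, 1.0], size=n)
    is_sediment = (metadata["habitat"] == "sediment").to_numpy()

    recs: list[tuple] = []
    for s_idx in range(n):
        h = home[s_idx]
        ok_regions = set(allowed[s_idx])
        candidate = np.where(np.isin(sample_region, list(ok_regions)))[0]
        p = np.exp(-d_home[h][candidate] / config.decay_scale_km)
        # a species reliably occupies its own home region regardless of the
        # decay scale; the scale governs how far beyond it presence reaches
        at_home = sample_region[candidate] == h
        p = np.where(at_home, np.maximum(p, config.home_presence_floor), p)
        present = rng.uniform(size=len(candidate)) < p
        # force >= 1 presence per allowed region (round-trip guarantee)
        for r in ok_regions:
            in_r = np.where(sample_region[candidate] == r)[0]
            if not present[in_r].any():
                present[rng.choice(in_r)] = True
        chosen = candidate[present]
        mu = (config.lognormal_mu
              + config.habitat_offset * habitat_pref[s_idx] * is_sediment[chosen])
        mapped = np.maximum(
            np.round(rng.lognormal(mean=mu, sigma=config.lognormal_sigma)).astype(np.int64),
            1,
        )
        for j, m in zip(chosen, mapped):
            recs.append((f"sp{s_idx + 1:05d}", sample_ids[j], int(m),
                         int(ref_length[s_idx])))

    summaries = pd.DataFrame(recs, columns=["species_id", "sample_id",
                                            "mapped_bases", "ref_length_bp"])
    totals = summaries.groupby("sample_id")["mapped_bases"].sum()
    # recruitment captures only a few percent of each metagenome
    frac = pd.Series(rng.uniform(0.02, 0.10, size=len(totals)), index=totals.index)
    total_bases = (totals / frac).round().astype(np.int64)
    summaries["sample_total_bases"] = summaries["sample_id"].map(total_bases)
    summaries = summaries.sort_values(["sample_id", "species_id"]).reset_index(drop=True)

    truth = pd.DataFrame({
        "species_id": [f"sp{i + 1:05d}" for i in range(n)],
        "occupancy_class": classes,
        "home_region": home,
        "regions_present": [";".join(sorted(a)) for a in allowed],
    })
    return SyntheticCommunity(summaries, metadata, truth)


# ======================================================================
# ANI pairs and genome sizes
# ======================================================================

def generate_ani_pairs(within_mean: float = 97.0,
                       between_decay_per_km: float = 3e-4,
                       noise_sd: float = 1.0,
                       regions: tuple = DEFAULT_REGIONS,
                       seed: int = 0,
                       n_pairs_per_group: int = 100) -> pd.DataFrame:
    """Pairwise genome-similarity records with a distance-dependent mean.

    Within-region pairs draw ANI ~ Normal(within_mean, noise_sd); a pair
    spanning two regions draws from Normal(within_mean - decay * centroid
    distance, noise_sd).  All values are truncated to [70, 100], the
    meaningful ANI range.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    regions = list(regions)
    centroid = {r.name: (r.latitude, r.longitude) for r in regions}
    counter: dict[str, int] = {r.name: 0 for r in regions}

    def genome(region: str) -> str:
        counter[region] += 1
        return f"g_{region}_{counter[region]:04d}"

    rows = []
    for i, ra in enumerate(regions):
        for rb in regions[i:]:
            if ra.name == rb.name:
                mean = within_mean
                dist = 0.0
            else:
                dist = float(_haversine_km(*centroid[ra.name], *centroid[rb.name]))
                mean = within_mean - between_decay_per_km * dist
            vals = np.clip(rng.normal(mean, noise_sd, size=n_pairs_per_group)
                           if noise_sd > 0 else np.full(n_pairs_per_group, mean),
                           70.0, 100.0)
            for v in vals:
                rows.append({"genome_a": genome(ra.name), "genome_b": genome(rb.name),
                             "ani_percent": float(v),
                             "region_a": ra.name, "region_b": rb.name})
    return pd.DataFrame(rows)


def generate_genome_sizes(range_sizes: np.ndarray, slope: float = 0.8,
                          intercept: float = 3.0, noise_sd: float = 0.5,
                          seed: int = 0) -> np.ndarray:
    """Genome sizes (Mbp) linear in range size, floored at 0.5 Mbp."""
    range_sizes = np.asarray(range_sizes, float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=range_sizes.shape) if noise_sd > 0 else 0.0
    return np.maximum(intercept + slope * range_sizes + noise, 0.5)
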