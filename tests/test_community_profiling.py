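"""TPM normalization, occupancy classes, range-size index, gene occupancy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sodalake import community_profiling as cp
from sodalake.errors import InvalidArgumentError, InvalidMetadataError


def _summaries(rows):
    return pd.DataFrame(rows, columns=["species_id", "sample_id", "mapped_bases",
                                       "ref_length_bp", "sample_total_bases"])


def _table(matrix: dict, regions: dict) -> cp.AbundanceTable:
    mat = pd.DataFrame(matrix)
    meta = pd.DataFrame({
        "sample_id": list(mat.columns),
        "region": [regions[s] for s in mat.columns],
        "habitat": "water", "latitude": 0.0, "longitude": 0.0,
    })
    return cp.AbundanceTable(matrix=mat, metadata=meta)


class TestTpm:
    @pytest.mark.parametrize("rows,expected", [
        ([("s1", "x", 42, 1000, 10_000)], {"s1": 1_000_000.0}),
        ([("s1", "x", 100, 1000, 10_000), ("s2", "x", 100, 1000, 10_000)],
         {"s1": 500_000.0, "s2": 500_000.0}),
        # rates (0.1, 0.1, 0.05) -> TPM (400000, 400000, 200000)
        ([("s1", "x", 300, 3000, 10_000), ("s2", "x", 100, 1000, 10_000),
          ("s3", "x", 100, 2000, 10_000)],
         {"s1": 400_000.0, "s2": 400_000.0, "s3": 200_000.0}),
    ])
    def test_worked_examples(self, rows, expected):
        tpm = cp.tpm_abundance(_summaries(rows), "x")
        for sp, val in expected.items():
            assert tpm[sp] == pytest.approx(val, rel=1e-12)

    def test_empty_sample_gives_zero_vector(self):
        tpm = cp.tpm_abundance(_summaries([("s1", "x", 0, 1000, 10)]), "x")
        assert (tpm == 0).all()

    def test_zero_ref_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cp.tpm_abundance(_summaries([("s1", "x", 5, 0, 10)]), "x")

    def test_per_sample_sum_is_one_million(self, small_table):
        sums = small_table.matrix.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    @given(scale=st.integers(min_value=2, max_value=10_000))
    def test_sequencing_depth_invariance(self, scale):
        rows = [("s1", "x", 300, 3000, 10**9), ("s2", "x", 100, 1000, 10**9),
                ("s3", "x", 100, 2000, 10**9)]
        scaled = [(a, b, m * scale, l, t) for a, b, m, l, t in rows]
        base = cp.tpm_abundance(_summaries(rows), "x")
        up = cp.tpm_abundance(_summaries(scaled), "x")
        np.testing.assert_allclose(base.to_numpy(), up.to_numpy(), rtol=1e-12)


class TestOccupancy:
    def test_class_definitions(self):
        regions = {"a1": "Africa", "c1": "China", "r1": "Russia", "k1": "Canada"}
        table = _table({
            "a1": {"core": 5.0, "endemic": 2.0, "mid": 1.0},
            "c1": {"core": 5.0, "endemic": 0.0, "mid": 1.0},
            "r1": {"core": 5.0, "endemic": 0.0, "mid": 0.0},
            "k1": {"core": 5.0, "endemic": 0.0, "mid": 0.0},
        }, regions)
        prof = cp.classify_occupancy(table).set_index("species_id")
        assert prof.loc["core", "occupancy_class"] == "core"
        assert prof.loc["endemic", "occupancy_class"] == "endemic"
        assert prof.loc["endemic", "regions_present"] == "Africa"
        assert prof.loc["mid", "occupancy_class"] == "intermediate"

    def test_sample_without_region_rejected(self):
        mat = pd.DataFrame({"x": {"s": 1.0}})
        meta = pd.DataFrame({"sample_id": ["x"], "region": [None],
                             "habitat": ["water"], "latitude": [0.0],
                             "longitude": [0.0]})
        with pytest.raises(InvalidMetadataError):
            cp.AbundanceTable(matrix=mat, metadata=meta)

    def test_round_trip_with_generator(self, small_community, small_table):
        profiles = cp.classify_occupancy(small_table, presence_threshold=0.0)
        merged = profiles.merge(small_community.truth, on="species_id",
                                suffixes=("_obs", "_true"))
        assert len(merged) == len(small_community.truth)
        assert (merged["occupancy_class_obs"] == merged["occupancy_class_true"]).all()
        assert (merged["regions_present_obs"] == merged["regions_present_true"]).all()

    def test_summary_counts(self, small_table):
        profiles = cp.classify_occupancy(small_table)
        summary = cp.occupancy_summary(profiles).set_index("group")
        n_end = (profiles["occupancy_class"] == "endemic").sum()
        assert summary.loc["class:endemic", "count"] == n_end


class TestRangeSize:
    @pytest.mark.parametrize("fractions,expected", [
        ((1.0, 0.0, 0.0, 0.0), 0.5),
        ((0.25, 0.25, 0.25, 0.25), 1.0),
        ((0.5, 0.5, 0.0, 0.0), 1.0 - 0.2886751345948129),
    ])
    def test_worked_examples(self, fractions, expected):
        assert cp.range_size(np.array(fractions)) == pytest.approx(expected, abs=1e-12)

    def test_bounds_over_random_fraction_vectors(self):
        rng = np.random.default_rng(42)
        f = rng.dirichlet(np.ones(4), size=10_000)
        idx = 1.0 - f.std(axis=1, ddof=1)
        assert np.all(idx >= 0.5 - 1e-12)
        assert np.all(idx <= 1.0)
        # extremes only at one-hot / uniform vectors
        assert idx.min() > 0.5
        assert idx.max() < 1.0

    def test_all_zero_species_flagged(self):
        with pytest.raises(InvalidArgumentError):
            cp.range_size(np.zeros(4))

    def test_table_excludes_zero_species(self, small_table):
        out = cp.range_size_table(small_table)
        assert not out["excluded"].any()
        ok = out["range_size"].dropna()
        assert ((ok >= 0.5 - 1e-12) & (ok <= 1.0 + 1e-12)).all()


class TestGeneOccupancy:
    def _inputs(self):
        genome_ko = pd.DataFrame({
            "genome_id": ["g1", "g2", "g3", "g4", "g1", "g3", "g3", "g4", "g1"],
            "ko_id":     ["K1", "K1", "K1", "K1", "K2", "K3", "K4", "K4", "K5"],
        })
        region = {"g1": "Africa", "g2": "China", "g3": "Russia", "g4": "Canada"}
        return genome_ko, region

    def test_classes(self):
        genome_ko, region = self._inputs()
        out = cp.classify_gene_occupancy(genome_ko, region).set_index("ko_id")
        assert out.loc["K1", "occupancy_class"] == "shared"
        assert out.loc["K2", "occupancy_class"] == "discarded-singleton"
        assert out.loc["K4", "occupancy_class"] == "multi-region"
        assert out.loc["K5", "occupancy_class"] == "discarded-singleton"

    def test_region_specific_multiple_genomes(self):
        # the genome->region map spans the whole 4-region study design
        genome_ko = pd.DataFrame({"genome_id": ["g3", "g5"], "ko_id": ["K9", "K9"]})
        region = {"g1": "Africa", "g2": "China", "g3": "Russia", "g4": "Canada",
                  "g5": "Russia"}
        out = cp.classify_gene_occupancy(genome_ko, region)
        assert out.loc[0, "occupancy_class"] == "region-specific"
        assert out.loc[0, "regions_present"] == "Russia"

    def test_unmapped_genome_rejected(self):
        genome_ko = pd.DataFrame({"genome_id": ["gX"], "ko_id": ["K1"]})
        with pytest.raises(InvalidMetadataError):
            cp.classify_gene_occupancy(genome_ko, {"g1": "Africa"})
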