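"""Geodesics, distance-decay regression, core detection, Venn partition."""

import itertools

import numpy as np
import pandas as pd
import pytest

from streamcom.biogeo import (
    abundance_occupancy,
    core_coverage,
    ddr,
    geodesic_matrix,
    venn_partition,
    vincenty_distance,
)
from streamcom.containers import CountTable, ValidationError, validate_metadata
from streamcom.preprocess import to_relative_abundance

# 20 random WGS-84 pairs with geodesic distances precomputed once with an
# independent high-precision implementation (Karney's algorithm,
# geosphere::distGeo); frozen here as the oracle. Columns: lat1, lon1,
# lat2, lon2, meters.
GEODESIC_ORACLE = [
    (-56.347387, -8.190213, -13.904157, -48.520119, 5823268.4993),
    (-63.454134, -136.261846, 55.765002, -84.616367, 13946720.2341),
    (-66.519292, 39.316443, 56.199184, 35.848386, 13614580.9125),
    (34.607716, -128.761484, -8.809207, -173.772246, 6747948.9031),
    (53.910656, -40.027738, -37.686608, -72.90335, 10628655.2224),
    (58.773701, -15.733239, 60.314887, -91.465453, 4048301.6525),
    (33.618648, 163.370598, 22.770872, -84.221892, 10525552.1535),
    (-50.270986, -26.390468, 14.524676, 131.55408, 15570686.2687),
    (42.802979, 83.165759, 63.834175, 95.825725, 2477161.7060),
    (50.781538, 49.177433, -40.019095, -49.610449, 13872381.6666),
    (61.160418, -118.018575, -37.617607, 41.56733, 17026953.8435),
    (12.013585, -42.005092, -32.616811, -161.285274, 13461636.2982),
    (53.235566, 163.830967, -19.403883, -129.760228, 10246654.4167),
    (-57.768894, 11.539411, -68.795483, -168.004447, 5963727.9918),
    (-13.621776, -79.657791, -19.320369, -34.196271, 4881864.4935),
    (-31.560913, 146.727122, 14.427178, 149.99191, 5100717.9518),
    (-7.738196, -89.390422, -29.74991, 55.030535, 14387842.3685),
    (-6.171568, 150.946921, -32.129685, 136.625436, 3236352.9641),
    (24.85157, -23.351933, 68.530813, 92.312302, 8429668.4544),
    (5.483855, 53.346306, 48.530603, -106.207592, 13699240.2767),
]


class TestVincenty:
    def test_identical_points_zero(self):
        assert vincenty_distance(44.9, 15.6, 44.9, 15.6) == 0.0

    def test_symmetry(self):
        d1 = vincenty_distance(10.0, 20.0, 30.0, 40.0)
        d2 = vincenty_distance(30.0, 40.0, 10.0, 20.0)
        assert d1 == pytest.approx(d2, abs=1e-9)

    @pytest.mark.parametrize("lat1,lon1,lat2,lon2,expected", GEODESIC_ORACLE)
    def test_against_high_precision_oracle(self, lat1, lon1, lat2, lon2, expected):
        assert vincenty_distance(lat1, lon1, lat2, lon2) == pytest.approx(
            expected, abs=0.5
        )

    def test_invalid_latitude(self):
        with pytest.raises(ValidationError):
            vincenty_distance(95.0, 0.0, 0.0, 0.0)


def _rel_table(rows, ids, taxa):
    return to_relative_abundance(
        CountTable(pd.DataFrame(rows, index=ids, columns=taxa))
    )


class TestDdr:
    def test_identical_communities_flat(self, toy_metadata):
        t = CountTable(
            pd.DataFrame(
                [[5, 5, 5]] * 4,
                index=["s1", "s2", "s3", "s4"],
                columns=["a", "b", "c"],
            )
        )
        fit, pairs = ddr(t, toy_metadata)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.n_pairs == 6

    def test_noiseless_linear_construction_recovered(self):
        """Similarity exactly linear in distance -> OLS recovers it exactly.

        Samples sit on one meridian so pairwise geodesic distances are
        additive; two-taxon communities [x, 1-x] with x linear in position
        make every pair's Bray-Curtis similarity exactly 1 - c * distance.
        """
        ids = ["s1", "s2", "s3", "s4"]
        meta = validate_metadata(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "site_id": ids,
                    "stream_type": ["tributary"] * 4,
                    "season": ["spring"] * 4,
                    "year": [2019] * 4,
                    "latitude": [44.85, 44.88, 44.93, 44.95],
                    "longitude": [15.6] * 4,
                }
            )
        )
        dist = geodesic_matrix(meta)
        c = 2e-5
        x = {s: 0.3 + c * dist.loc["s1", s] for s in ids}
        t = CountTable(
            pd.DataFrame({s: [x[s], 1 - x[s]] for s in ids}, index=["a", "b"]).T
            * 1000
        )
        fit, _ = ddr(t, meta)
        assert fit.slope == pytest.approx(-c, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_distances_rejected(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["latitude"] = 44.9
        meta["longitude"] = 15.6
        t = CountTable(
            pd.DataFrame(
                np.random.default_rng(0).integers(1, 9, (4, 3)),
                index=meta.index,
                columns=["a", "b", "c"],
            )
        )
        with pytest.raises(ValidationError):
            ddr(t, meta)


class TestAbundanceOccupancy:
    def test_membership_classes(self, toy_metadata):
        # s1,s2 tributary; s3 interlake; s4 korana
        rows = [
            # t_all in every sample; t_trib only tributaries; t_two in
            # tributary+interlake; t_three everywhere except s2
            [5, 3, 2, 4],
            [5, 2, 1, 0],
            [5, 0, 3, 2],
            [5, 0, 0, 3],
        ]
        t = _rel_table(rows, ["s1", "s2", "s3", "s4"], ["t_all", "t_trib", "t_two", "t_three"])
        core = abundance_occupancy(t, toy_metadata)
        assert core.loc["t_all", "membership"] == "core"
        assert core.loc["t_all", "occupancy"] == pytest.approx(1.0)
        assert core.loc["t_trib", "membership"] == "unique_tributary"
        assert core.loc["t_two", "membership"] == "shared_two"
        assert core.loc["t_three", "membership"] == "shared_three"
        assert core.loc["t_three", "occupancy"] == pytest.approx(0.75)

    def test_occupancy_invariant_to_rescaling(self, toy_metadata):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5, size=(4, 6))
        counts[:, 0] += 1
        raw = CountTable(
            pd.DataFrame(counts, index=toy_metadata.index, columns=[f"t{i}" for i in range(6)])
        )
        rel = to_relative_abundance(raw)
        occ_raw = abundance_occupancy(raw, toy_metadata)["occupancy"]
        occ_rel = abundance_occupancy(rel, toy_metadata)["occupancy"]
        pd.testing.assert_series_equal(occ_raw, occ_rel)

    def test_log_mean_uses_zero_inclusive_mean(self, toy_metadata):
        rows = [[1, 1], [1, 0], [1, 0], [1, 0]]
        t = _rel_table(rows, list(toy_metadata.index), ["x", "y"])
        core = abundance_occupancy(t, toy_metadata)
        # y: relative abundances (0.5, 0, 0, 0) -> mean 0.125
        assert core.loc["y", "log_mean_relative_abundance"] == pytest.approx(
            np.log10(0.125)
        )


class TestCoreCoverage:
    def test_hand_summed_fractions(self, toy_metadata):
        rows = [
            [6, 2, 2],  # tributary: core covers 0.6
            [8, 1, 1],  # tributary: 0.8
            [5, 5, 0],  # interlake: 0.5
            [10, 0, 0],  # korana: 1.0
        ]
        t = _rel_table(rows, list(toy_metadata.index), ["core1", "o1", "o2"])
        cov = core_coverage(t, ["core1"], toy_metadata)
        assert cov["tributary"] == pytest.approx(0.7)
        assert cov["interlake"] == pytest.approx(0.5)
        assert cov["korana"] == pytest.approx(1.0)

    def test_extremes(self, toy_metadata):
        rows = np.ones((4, 3))
        t = _rel_table(rows, list(toy_metadata.index), ["a", "b", "c"])
        assert (core_coverage(t, ["a", "b", "c"], toy_metadata) == 1.0).all()
        assert (core_coverage(t, [], toy_metadata) == 0.0).all()


class TestVenn:
    def test_toy_counts_match_set_algebra(self, toy_metadata):
        # presence patterns per taxon across (trib={s1,s2}, inter={s3}, kor={s4})
        rows = np.array(
            [
                # a: everywhere; b: trib only; c: inter only; d: kor only;
                # e: trib+inter; f: trib+kor
                [1, 1, 0, 0, 1, 1],
                [1, 1, 0, 0, 0, 0],
                [1, 0, 1, 0, 1, 0],
                [1, 0, 0, 1, 0, 1],
            ]
        )
        t = CountTable(
            pd.DataFrame(rows, index=list(toy_metadata.index), columns=list("abcdef"))
        )
        regions = venn_partition(t, toy_metadata)
        assert regions["interlake&korana&tributary"] == 1  # a
        assert regions["tributary"] == 1  # b
        assert regions["interlake"] == 1  # c
        assert regions["korana"] == 1  # d
        assert regions["interlake&tributary"] == 1  # e
        assert regions["korana&tributary"] == 1  # f
        assert regions["interlake&korana"] == 0

    def test_regions_partition_detected_taxa(self, toy_metadata):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(4, 20))
        counts[:, 0] += 1
        t = CountTable(
            pd.DataFrame(counts, index=list(toy_metadata.index), columns=[f"t{i}" for i in range(20)])
        )
        regions = venn_partition(t, toy_metadata)
        detected = int((counts.sum(axis=0) > 0).sum())
        assert sum(regions.values()) == detected

    def test_requires_three_groups(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["stream_type"] = ["tributary", "tributary", "interlake", "interlake"]
        t = CountTable(
            pd.DataFrame(np.ones((4, 2)), index=list(meta.index), columns=["a", "b"])
        )
        with pytest.raises(ValidationError):
            venn_partition(t, meta)
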