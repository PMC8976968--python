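import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentad.aggregate import (
    AreaMatrix,
    Pentad,
    PentadSettings,
    build_pentad,
    extract_area,
    filter_areas,
    rescale_area,
    stack_median,
)
from pentad.compartments import enumerate_areas_cis
from pentad.errors import ValidationError
from pentad.synthetic import SyntheticSpec, generate_genome, planted_oe_maps

from conftest import make_cis, make_interval, random_intervals

BIN = 100_000


def bilinear_oracle(v, size):
    """Direct per-pixel bilinear formula, written independently."""
    nr, nc = v.shape
    out = np.empty((size, size))
    for p in range(size):
        for q in range(size):
            x = min(max((p + 0.5) * nr / size - 0.5, 0.0), nr - 1.0)
            y = min(max((q + 0.5) * nc / size - 0.5, 0.0), nc - 1.0)
            i0 = min(int(np.floor(x)), max(nr - 2, 0))
            j0 = min(int(np.floor(y)), max(nc - 2, 0))
            i1, j1 = min(i0 + 1, nr - 1), min(j0 + 1, nc - 1)
            wx, wy = x - i0, y - j0
            total, bad = 0.0, False
            for ii, wi in ((i0, 1 - wx), (i1, wx)):
                for jj, wj in ((j0, 1 - wy), (j1, wy)):
                    w = wi * wj
                    if w > 0:
                        if not np.isfinite(v[ii, jj]):
                            bad = True
                        else:
                            total += w * v[ii, jj]
            out[p, q] = np.nan if bad else total
    return out


def area_from(values, kind="A_short", distance=0.0):
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    row = make_interval(0, rows, "A")
    col = make_interval(0, cols, "A") if kind.endswith("short") else \
        make_interval(rows, rows + cols, "A")
    from pentad.compartments import AreaDescriptor
    desc = AreaDescriptor(row=row, col=col, kind=kind, distance=distance,
                          context="chr1")
    return AreaMatrix(descriptor=desc, values=values)


class TestExtractArea:
    def test_rectangular_block(self):
        oe = make_cis(np.arange(100).reshape(10, 10).astype(float))
        from pentad.compartments import AreaDescriptor
        desc = AreaDescriptor(row=make_interval(0, 2, "A"),
                              col=make_interval(5, 8, "B"),
                              kind="AB", distance=550_000.0, context="chr1")
        block = extract_area(oe, desc)
        assert np.array_equal(block.values, oe.values[0:2, 5:8])

    def test_on_diagonal_block(self):
        oe = make_cis(np.arange(100).reshape(10, 10).astype(float))
        from pentad.compartments import AreaDescriptor
        iv = make_interval(3, 6, "A")
        desc = AreaDescriptor(row=iv, col=iv, kind="A_short", distance=0.0,
                              context="chr1")
        block = extract_area(oe, desc)
        assert block.values.shape == (3, 3)
        assert np.array_equal(block.values, oe.values[3:6, 3:6])

    def test_matches_brute_force_copies(self, rng):
        oe = make_cis(rng.random((40, 40)))
        ivs = random_intervals(rng, 9, max_len=4)
        for desc in enumerate_areas_cis(ivs, BIN)[:20]:
            block = extract_area(oe, desc)
            oracle = np.array([
                [oe.values[i, j] for j in range(desc.col.start, desc.col.end)]
                for i in range(desc.row.start, desc.row.end)])
            assert np.array_equal(block.values, oracle)

    def test_out_of_range_rejected(self):
        oe = make_cis(np.ones((5, 5)))
        from pentad.compartments import AreaDescriptor
        desc = AreaDescriptor(row=make_interval(0, 2, "A"),
                              col=make_interval(4, 7, "B"),
                              kind="AB", distance=0.0, context="chr1")
        with pytest.raises(ValidationError):
            extract_area(oe, desc)


class TestFilterAreas:
    def test_dimension_rule(self):
        kept, rejected = filter_areas([area_from(np.ones((2, 5)))], min_dimension=3)
        assert kept == [] and rejected["dimension"] == 1

    def test_coverage_rule(self):
        values = np.ones((4, 4))
        values.flat[:10] = 0.0
        kept, rejected = filter_areas([area_from(values)], min_dimension=3,
                                      max_zero_fraction=0.5)
        assert kept == [] and rejected["coverage"] == 1

    def test_distance_rule(self):
        area = area_from(np.ones((4, 4)), kind="A_long", distance=30e6)
        kept, rejected = filter_areas([area], max_distance=20e6)
        assert kept == [] and rejected["distance"] == 1
        kept, _ = filter_areas([area], max_distance=40e6)
        assert len(kept) == 1

    def test_first_failing_rule_attribution(self):
        # fails all three rules; only rule 1 is charged
        area = area_from(np.zeros((2, 2)), kind="A_long", distance=1e9)
        _, rejected = filter_areas([area], min_dimension=3, max_zero_fraction=0.0,
                                   max_distance=1e6)
        assert rejected == {"dimension": 1, "coverage": 0, "distance": 0}

    def test_matches_predicate_oracle(self, rng):
        areas = []
        for _ in range(100):
            shape = (int(rng.integers(1, 8)), int(rng.integers(1, 8)))
            values = rng.random(shape)
            values[rng.random(shape) < 0.4] = 0.0
            areas.append(area_from(values, kind="A_long",
                                   distance=float(rng.uniform(0, 50e6))))
        min_dim, max_zero, max_dist = 3, 0.3, 25e6
        kept, rejected = filter_areas(areas, min_dim, max_zero, max_dist)
        oracle_kept = [
            a for a in areas
            if min(a.values.shape) >= min_dim
            and np.mean((a.values == 0) | ~np.isfinite(a.values)) <= max_zero
            and a.descriptor.distance <= max_dist
        ]
        assert [id(a) for a in kept] == [id(a) for a in oracle_kept]
        assert sum(rejected.values()) + len(kept) == len(areas)

    def test_invalid_zero_fraction(self):
        with pytest.raises(ValidationError):
            filter_areas([], max_zero_fraction=1.5)

    def test_monotone_filtering(self, rng):
        areas = []
        for _ in range(60):
            shape = (int(rng.integers(1, 9)), int(rng.integers(1, 9)))
            values = rng.random(shape)
            values[rng.random(shape) < 0.3] = 0.0
            areas.append(area_from(values))
        counts = []
        for min_dim in (1, 2, 3, 4, 5):
            kept, _ = filter_areas(areas, min_dimension=min_dim)
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)
        counts = []
        for max_zero in (1.0, 0.6, 0.3, 0.0):
            kept, _ = filter_areas(areas, max_zero_fraction=max_zero)
            counts.append(len(kept))
        assert counts == sorted(counts, reverse=True)


class TestRescaleArea:
    def test_constant_preserved(self):
        for size in (3, 11, 33):
            out = rescale_area(np.full((3, 3), 2.0), size)
            assert out.shape == (size, size)
            assert np.allclose(out, 2.0)

    def test_checkerboard_center(self):
        out = rescale_area(np.array([[0.0, 1.0], [1.0, 0.0]]), 3)
        assert out[1, 1] == pytest.approx(0.5)

    def test_matches_direct_formula_oracle(self, rng):
        v = rng.random((5, 7))
        out = rescale_area(v, 33)
        assert np.allclose(out, bilinear_oracle(v, 33), atol=1e-9)

    def test_missing_propagates(self):
        v = np.ones((4, 4))
        v[1, 1] = np.nan
        out = rescale_area(v, 9)
        oracle = bilinear_oracle(v, 9)
        assert np.array_equal(np.isnan(out), np.isnan(oracle))
        assert np.isnan(out).any() and not np.isnan(out).all()

    def test_invalid_size(self):
        for size in (2, 4, 1, 0):
            with pytest.raises(ValidationError):
                rescale_area(np.ones((3, 3)), size)

    @given(st.integers(1, 6), st.integers(1, 6),
           st.sampled_from([3, 5, 9, 33]), st.floats(0.1, 10))
    @settings(max_examples=40, deadline=None)
    def test_constancy_property(self, nr, nc, size, c):
        out = rescale_area(np.full((nr, nc), c), size)
        assert np.allclose(out, c)


class TestStackMedian:
    def test_identical_arrays(self, rng):
        m = rng.random((5, 5))
        med, count = stack_median([m, m.copy(), m.copy()])
        assert np.allclose(med, m) and count == 3

    def test_outlier_robustness(self):
        arrays = [np.full((3, 3), v) for v in (1.0, 2.0, 100.0)]
        med, _ = stack_median(arrays)
        assert np.allclose(med, 2.0)

    def test_matches_sort_oracle(self, rng):
        arrays = []
        for _ in range(25):
            a = rng.random((11, 11))
            a[rng.random((11, 11)) < 0.15] = np.nan
            arrays.append(a)
        med, count = stack_median(arrays)
        assert count == 25
        for p in range(11):
            for q in range(11):
                pool = sorted(a[p, q] for a in arrays if np.isfinite(a[p, q]))
                if not pool:
                    assert np.isnan(med[p, q])
                else:
                    n = len(pool)
                    want = pool[n // 2] if n % 2 else (pool[n // 2 - 1] + pool[n // 2]) / 2
                    assert med[p, q] == pytest.approx(want)

    def test_all_missing_pixel(self):
        a = np.ones((3, 3))
        a[0, 0] = np.nan
        med, _ = stack_median([a, a.copy()])
        assert np.isnan(med[0, 0]) and med[1, 1] == 1.0

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValidationError):
            stack_median([np.ones((3, 3)), np.ones((5, 5))])

    def test_permutation_invariance(self, rng):
        arrays = [rng.random((7, 7)) for _ in range(10)]
        med1, _ = stack_median(arrays)
        order = rng.permutation(10)
        med2, _ = stack_median([arrays[i] for i in order])
        assert np.array_equal(med1, med2)


class TestBuildPentad:
    def two_chrom_genome(self):
        """One A and one B interval per chromosome, noise free."""
        spec = SyntheticSpec(
            chromsizes={"chr1": 2_000_000, "chr2": 2_000_000}, binsize=100_000,
            layouts={"chr1": [10, 10], "chr2": [10, 10]}, f=2.0, trans=True, seed=0,
        )
        genome = generate_genome(spec)
        oe_maps = planted_oe_maps(genome)
        intervals = {c: enumerate_intervals(genome, c) for c in ("chr1", "chr2")}
        return genome, oe_maps, intervals

    def test_cis_panel_counts(self):
        from pentad.compartments import segment_signal
        genome, oe_maps, _ = self.two_chrom_genome()
        intervals = {c: segment_signal(genome.tracks[c]) for c in genome.tracks}
        pentad = build_pentad(oe_maps, intervals, mode="cis")
        assert pentad.counts == {"A_short": 2, "B_short": 2, "A_long": 0,
                                 "B_long": 0, "AB": 2}
        assert np.isnan(pentad.panels["A_long"]).all()

    def test_trans_panel_counts(self):
        from pentad.compartments import segment_signal
        from pentad.genome_io import ContactMatrix
        from pentad.oe_transform import oe_trans
        genome, _, _ = self.two_chrom_genome()
        intervals = {c: segment_signal(genome.tracks[c]) for c in genome.tracks}
        trans_mat = ContactMatrix(row_chrom="chr1", col_chrom="chr2",
                                  values=genome.matrices[("chr1", "chr2")],
                                  binsize=100_000)
        pentad = build_pentad({("chr1", "chr2"): oe_trans(trans_mat)}, intervals,
                              mode="trans")
        assert pentad.counts == {"A_long": 1, "B_long": 1, "AB": 2}

    def test_constancy_invariant(self):
        from pentad.compartments import segment_signal
        genome, oe_maps, _ = self.two_chrom_genome()
        intervals = {c: segment_signal(genome.tracks[c]) for c in genome.tracks}
        for oe in oe_maps.values():
            oe.values[:] = 3.5
        pentad = build_pentad(oe_maps, intervals, mode="cis")
        for key, panel in pentad.panels.items():
            if pentad.counts[key]:
                assert np.allclose(panel, 3.5)

    def test_scale_equivariance(self):
        from pentad.compartments import segment_signal
        genome, oe_maps, _ = self.two_chrom_genome()
        intervals = {c: segment_signal(genome.tracks[c]) for c in genome.tracks}
        base = build_pentad(oe_maps, intervals, mode="cis")
        for oe in oe_maps.values():
            oe.values *= 7.0
        scaled = build_pentad(oe_maps, intervals, mode="cis")
        for key in base.panels:
            if base.counts[key]:
                assert np.allclose(scaled.panels[key], 7.0 * base.panels[key])

    def test_null_calibration(self):
        """Structureless genome: every panel pixel distribution sits near 1."""
        from pentad.compartments import segment_signal
        spec = SyntheticSpec(chromsizes={"chr1": 20_000_000}, binsize=100_000,
                             f=1.0, noise="poisson", depth=2000.0, seed=13)
        genome = generate_genome(spec)
        oe_maps = planted_oe_maps(genome)
        intervals = {"chr1": segment_signal(genome.tracks["chr1"])}
        pentad = build_pentad(oe_maps, intervals, mode="cis")
        for key, panel in pentad.panels.items():
            if pentad.counts[key] >= 20:
                assert abs(np.nanmedian(panel) - 1.0) < 0.05

    def test_distance_mode_strata(self):
        from pentad.compartments import segment_signal
        spec = SyntheticSpec(chromsizes={"chr1": 30_000_000}, binsize=100_000,
                             f=2.0, seed=4)
        genome = generate_genome(spec)
        oe_maps = planted_oe_maps(genome)
        intervals = {"chr1": segment_signal(genome.tracks["chr1"])}
        settings = PentadSettings(distance_bins=(2e6, 10e6, 20e6))
        pentad = build_pentad(oe_maps, intervals, mode="distance", settings=settings)
        assert pentad.strata == [2e6, 10e6, 20e6]
        assert set(pentad.panels) == {
            "A_short", "B_short",
            "A_long@0", "A_long@1", "B_long@0", "B_long@1", "AB@0", "AB@1"}
        # stratified counts never exceed the total number of off-diagonal areas
        n = len(intervals["chr1"])
        off_diag = n * (n - 1) // 2
        stratified = sum(v for k, v in pentad.counts.items() if "@" in k)
        assert stratified <= off_diag

    def test_json_roundtrip(self, tmp_path):
        from pentad.compartments import segment_signal
        genome, oe_maps, _ = self.two_chrom_genome()
        intervals = {c: segment_signal(genome.tracks[c]) for c in genome.tracks}
        pentad = build_pentad(oe_maps, intervals, mode="cis")
        path = tmp_path / "pentad.json"
        pentad.save(path)
        loaded = Pentad.load(path)
        assert loaded.mode == pentad.mode and loaded.counts == pentad.counts
        for key in pentad.panels:
            assert np.allclose(loaded.panels[key], pentad.panels[key], equal_nan=True)


def enumerate_intervals(genome, chrom):
    from pentad.compartments import segment_signal
    return segment_signal(genome.tracks[chrom])


def test_settings_validation():
    with pytest.raises(ValidationError):
        PentadSettings(rescale_size=10)
    with pytest.raises(ValidationError):
        PentadSettings(rescale_size=1)
    with pytest.raises(ValidationError):
        PentadSettings(max_zero_fraction=2.0)
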