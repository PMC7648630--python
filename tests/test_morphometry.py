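import numpy as np
import imageio.v3 as iio
import pytest

from lam_quant.morphometry import (
    AIRSPACE,
    WALL,
    BinaryMask,
    EmptyResultError,
    GrayImage,
    InterceptSet,
    LineGrid,
    MorphometryConfig,
    aggregate_by_subject,
    analyze_image,
    analyze_mask,
    binarize_otsu,
    chord_runs,
    compute_mli,
    fill_lumens,
    load_grayscale,
    make_line_grid,
    measure_intercepts,
    otsu_threshold,
)
from lam_quant.synthetic_histology import (
    LatticeSpec,
    RenderSpec,
    generate_lattice,
    punch_lumens,
    render_grayscale,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def otsu_brute_force(hist):
    """Exhaustive search over all 256 candidate thresholds."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_sigma = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:  # strict > keeps the lowest tie
            best_sigma, best_t = sigma, t
    return best_t


def closing_brute_force(wall, radius):
    """Dilation then erosion of the wall phase by an explicit disk, with the
    image padded by airspace, using per-pixel neighborhood loops."""
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    pad = radius + 1
    w = np.pad(wall.astype(bool), pad, constant_values=False)
    H, W = w.shape
    dil = np.zeros_like(w)
    for y in range(H):
        for x in range(W):
            dil[y, x] = any(
                0 <= y + dy < H and 0 <= x + dx < W and w[y + dy, x + dx]
                for dy, dx in offsets
            )
    ero = np.zeros_like(w)
    for y in range(H):
        for x in range(W):
            ero[y, x] = all(
                0 <= y + dy < H and 0 <= x + dx < W and dil[y + dy, x + dx]
                for dy, dx in offsets
            )
    return ero[pad:-pad, pad:-pad]


# ---------------------------------------------------------------------------
# load_grayscale
# ---------------------------------------------------------------------------


class TestLoadGrayscale:
    def test_all_black_png(self, tmp_path):
        path = tmp_path / "black.png"
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        img = load_grayscale(path, 1.0)
        assert (img.intensities == 0).all()
        assert img.pixel_size == 1.0

    def test_rgb_white_is_255(self, tmp_path):
        path = tmp_path / "white.png"
        iio.imwrite(path, np.full((4, 4, 3), 255, dtype=np.uint8))
        img = load_grayscale(path, 1.0)
        assert (img.intensities == 255).all()

    def test_rgb_red_luminance(self, tmp_path):
        # 0.299 * 255 = 76.245 -> 76 with round-half-up
        path = tmp_path / "red.png"
        arr = np.zeros((4, 4, 3), dtype=np.uint8)
        arr[:, :, 0] = 255
        iio.imwrite(path, arr)
        img = load_grayscale(path, 1.0)
        assert (img.intensities == 76).all()

    def test_16bit_rescaled(self, tmp_path):
        path = tmp_path / "deep.tif"
        iio.imwrite(path, np.full((4, 4), 65535, dtype=np.uint16))
        img = load_grayscale(path, 1.0)
        assert (img.intensities == 255).all()

    def test_missing_file_errors_with_name(self, tmp_path):
        with pytest.raises(OSError, match="nope.png"):
            load_grayscale(tmp_path / "nope.png", 1.0)

    def test_bad_pixel_size(self, tmp_path):
        path = tmp_path / "ok.png"
        iio.imwrite(path, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            load_grayscale(path, 0.0)


# ---------------------------------------------------------------------------
# Otsu binarization
# ---------------------------------------------------------------------------


class TestBinarizeOtsu:
    def test_bimodal_split(self):
        arr = np.concatenate(
            [np.full(32, 10, dtype=np.uint8), np.full(32, 200, dtype=np.uint8)]
        ).reshape(8, 8)
        img = GrayImage(arr, pixel_size=1.0)
        threshold, mask = binarize_otsu(img)
        assert 10 <= threshold <= 199
        assert mask.phase.sum() == 32  # exactly half wall
        assert (mask.phase[arr == 10] == WALL).all()
        assert (mask.phase[arr == 200] == AIRSPACE).all()

    def test_oracle_equivalence_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == otsu_brute_force(hist)

    def test_noise_free_lattice_roundtrip(self, lattice_50, clean_render):
        _, mask, _ = lattice_50
        img = render_grayscale(mask, clean_render)
        _, recovered = binarize_otsu(img)
        assert (recovered.phase == mask.phase).all()

    def test_constant_image_rejected(self):
        img = GrayImage(np.full((8, 8), 42, dtype=np.uint8), pixel_size=1.0)
        with pytest.raises(ValueError):
            binarize_otsu(img)

    def test_ties_broken_low(self):
        # symmetric two-spike histogram: several thresholds maximise the
        # criterion; the lowest must be returned
        hist = np.zeros(256)
        hist[[100, 110]] = 10
        assert otsu_threshold(hist) == otsu_brute_force(hist)


# ---------------------------------------------------------------------------
# lumen filling
# ---------------------------------------------------------------------------


class TestFillLumens:
    def test_radius_zero_identity(self, lattice_50):
        _, mask, _ = lattice_50
        out = fill_lumens(mask, 0)
        assert (out.phase == mask.phase).all()

    def test_single_pixel_hole_filled(self):
        phase = np.zeros((11, 11), dtype=np.uint8)
        phase[3:8, :] = WALL  # 5-px-thick horizontal wall
        phase[5, 5] = AIRSPACE  # 1-px lumen in the middle
        mask = BinaryMask(phase, pixel_size=1.0)
        out = fill_lumens(mask, 2)
        assert out.phase[5, 5] == WALL
        oracle = closing_brute_force(phase, 2)
        assert (out.phase.astype(bool) == oracle).all()

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(5):
            phase = (rng.random((24, 24)) < 0.5).astype(np.uint8)
            mask = BinaryMask(phase, pixel_size=1.0)
            for radius in (1, 2):
                out = fill_lumens(mask, radius)
                oracle = closing_brute_force(phase, radius)
                assert (out.phase.astype(bool) == oracle).all()

    def test_lattice_matches_oracle(self):
        # hole-free lattice: closing only rounds airspace corners; verify the
        # implementation against the brute-force oracle rather than identity
        mask, _ = generate_lattice(LatticeSpec(16, 4, 1.0, 2, 2))
        out = fill_lumens(mask, 2)
        oracle = closing_brute_force(mask.phase, 2)
        assert (out.phase.astype(bool) == oracle).all()

    def test_border_airspace_never_closed(self):
        # airspace frame around a wall block; padding with airspace must keep
        # the border rows airspace
        phase = np.zeros((12, 12), dtype=np.uint8)
        phase[4:8, 4:8] = WALL
        mask = BinaryMask(phase, pixel_size=1.0)
        out = fill_lumens(mask, 3)
        assert (out.phase[0, :] == AIRSPACE).all()
        assert (out.phase[:, 0] == AIRSPACE).all()

    def test_negative_radius_rejected(self, lattice_50):
        _, mask, _ = lattice_50
        with pytest.raises(ValueError):
            fill_lumens(mask, -1)


# ---------------------------------------------------------------------------
# line grid
# ---------------------------------------------------------------------------


class TestMakeLineGrid:
    def test_height_200(self):
        grid = make_line_grid(200, 20)
        assert grid.rows == tuple(range(5, 200, 10))

    def test_height_equals_lines(self):
        grid = make_line_grid(20, 20)
        assert grid.rows == tuple(range(20))

    @pytest.mark.parametrize("height,n", [(55, 20), (100, 7), (997, 20), (21, 20)])
    def test_spacing_property(self, height, n):
        grid = make_line_grid(height, n)
        rows = np.array(grid.rows)
        assert (np.diff(rows) > 0).all()
        gaps = np.diff(rows)
        assert gaps.max() - gaps.min() <= 1
        assert rows[0] >= 0 and rows[-1] < height

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            make_line_grid(10, 20)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            LineGrid(rows=(5, 5, 6))
        with pytest.raises(ValueError):
            LineGrid(rows=())


# ---------------------------------------------------------------------------
# intercepts
# ---------------------------------------------------------------------------


def one_row_mask(pattern):
    """Build a 3-row mask whose middle row is the given W/A pattern."""
    codes = {"W": WALL, "A": AIRSPACE}
    row = np.array([codes[c] for c in pattern], dtype=np.uint8)
    phase = np.tile(row, (3, 1))
    return BinaryMask(phase, pixel_size=1.0)


class TestMeasureIntercepts:
    def test_single_complete_chord(self):
        mask = one_row_mask("WAAAW")
        result = measure_intercepts(mask, LineGrid(rows=(1,)))
        np.testing.assert_array_equal(result.airspace_chords, [3.0])
        assert result.n_truncated == 0

    def test_truncated_chords_excluded(self):
        mask = one_row_mask("AAWAA")
        result = measure_intercepts(mask, LineGrid(rows=(1,)))
        assert result.airspace_chords.size == 0
        assert result.n_truncated == 2
        # the wall run is bounded by airspace on both sides: complete, 1 µm
        np.testing.assert_array_equal(result.wall_chords, [1.0])

    def test_include_truncated_option(self):
        mask = one_row_mask("AAWAA")
        result = measure_intercepts(mask, LineGrid(rows=(1,)), include_truncated=True)
        np.testing.assert_array_equal(np.sort(result.airspace_chords), [2.0, 2.0])

    def test_wall_intersections_count(self):
        mask = one_row_mask("WAAWWAAAW")
        result = measure_intercepts(mask, LineGrid(rows=(1,)))
        # airspace->wall transitions: positions 2->3 and 7->8
        assert result.wall_intersections == 2

    def test_lattice_chords_exact(self, lattice_50):
        _, mask, _ = lattice_50
        grid = make_line_grid(mask.shape[0], 20)
        result = measure_intercepts(mask, grid)
        assert result.airspace_chords.size > 0
        assert (np.abs(result.airspace_chords - 50.0) <= 1.0).all()
        assert (np.abs(result.wall_chords - 5.0) <= 1.0).all()

    def test_pixel_size_scales_chords(self):
        mask = one_row_mask("WAAAW")
        mask.pixel_size = 0.5
        result = measure_intercepts(mask, LineGrid(rows=(1,)))
        np.testing.assert_array_equal(result.airspace_chords, [1.5])

    def test_row_outside_mask_rejected(self):
        mask = one_row_mask("WAAAW")
        with pytest.raises(ValueError):
            measure_intercepts(mask, LineGrid(rows=(5,)))


class TestChordRuns:
    def test_no_phase_pixels(self):
        lengths, truncated = chord_runs(np.array([1, 1, 1]), 0)
        assert lengths.size == 0 and truncated == 0

    def test_all_phase_is_truncated(self):
        lengths, truncated = chord_runs(np.array([0, 0, 0]), 0)
        assert lengths.size == 0 and truncated == 1


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


class TestComputeMli:
    @staticmethod
    def _iset(air, wall=(), intersections=1):
        return InterceptSet(
            airspace_chords=np.asarray(air, dtype=float),
            wall_chords=np.asarray(wall, dtype=float),
            wall_intersections=intersections,
            n_truncated=0,
            per_line_counts=[len(air)],
        )

    def test_constant_chords(self):
        result = compute_mli(self._iset([10, 10, 10]))
        assert result.mli == 10
        assert result.mli_sd == 0
        assert result.dispersion_index == 0

    def test_two_chords(self):
        result = compute_mli(self._iset([5, 15]))
        assert result.mli == 10
        assert result.mli_sd == pytest.approx(7.0711, abs=1e-4)
        assert result.dispersion_index == pytest.approx(5.0)

    def test_cv_dispersion(self):
        result = compute_mli(self._iset([5, 15]), dispersion="cv")
        assert result.dispersion_index == pytest.approx(7.0711 / 10, abs=1e-4)

    def test_ast_from_wall_chords(self):
        result = compute_mli(self._iset([10], wall=[4, 6]))
        assert result.ast == 5
        assert result.ast_sd == pytest.approx(np.sqrt(2))

    def test_empty_raises_not_nan(self):
        with pytest.raises(EmptyResultError):
            compute_mli(self._iset([]))


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


def render_to_file(mask, tmp_path, name="img.png", noise_sd=0.0, seed=0):
    img = render_grayscale(
        mask, RenderSpec(220, 60, noise_sd=noise_sd, rng_seed=seed)
    )
    path = tmp_path / name
    iio.imwrite(path, img.intensities)
    return path


class TestAnalyzeImage:
    def test_lattice_recovery(self, tmp_path, lattice_50):
        _, mask, gt = lattice_50
        path = render_to_file(mask, tmp_path)
        result = analyze_image(path, MorphometryConfig(pixel_size=1.0))
        assert abs(result.mli - gt.true_mean_airspace_chord) <= 2.0
        assert abs(result.ast - gt.true_mean_wall_chord) <= 2.0
        assert result.threshold is not None

    def test_determinism(self, tmp_path, lattice_50):
        _, mask, _ = lattice_50
        path = render_to_file(mask, tmp_path, noise_sd=8.0, seed=3)
        config = MorphometryConfig(pixel_size=1.0)
        r1 = analyze_image(path, config)
        r2 = analyze_image(path, config)
        assert r1 == r2

    def test_closing_improves_punched_mli(self, tmp_path, lattice_50):
        _, mask, gt = lattice_50
        punched = punch_lumens(mask, 20, 2, rng_seed=3)
        path = render_to_file(punched, tmp_path)
        err_open = abs(
            analyze_image(path, MorphometryConfig(1.0, closing_radius=0)).mli
            - gt.true_mean_airspace_chord
        )
        err_closed = abs(
            analyze_image(path, MorphometryConfig(1.0, closing_radius=3)).mli
            - gt.true_mean_airspace_chord
        )
        assert err_open > 0  # the punched lumens do perturb this fixture
        assert err_closed < err_open

    def test_scale_equivariance(self, tmp_path):
        results = {}
        for px in (1.0, 0.5):
            mask, _ = generate_lattice(LatticeSpec(50, 5, px, 6, 6))
            path = render_to_file(mask, tmp_path, name=f"px{px}.png")
            results[px] = analyze_image(path, MorphometryConfig(pixel_size=px)).mli
        assert abs(results[1.0] - results[0.5]) <= 2.0

    def test_monotonic_in_airspace_side(self, tmp_path):
        mlis = []
        for side in (30, 50, 80):
            mask, _ = generate_lattice(LatticeSpec(side, 5, 1.0, 6, 6))
            path = render_to_file(mask, tmp_path, name=f"s{side}.png")
            mlis.append(analyze_image(path, MorphometryConfig(1.0)).mli)
        assert mlis[0] < mlis[1] < mlis[2]

    def test_stage_annotated_errors(self, tmp_path):
        with pytest.raises(OSError, match=r"\[load\]"):
            analyze_image(tmp_path / "missing.png", MorphometryConfig(1.0))
        flat = tmp_path / "flat.png"
        iio.imwrite(flat, np.full((30, 30), 99, dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\[binarize\]"):
            analyze_image(flat, MorphometryConfig(1.0, n_lines=5))

    def test_min_chord_filter(self, lattice_50):
        _, mask, _ = lattice_50
        punched = punch_lumens(mask, 40, 2, rng_seed=9)
        loose = analyze_mask(punched, MorphometryConfig(1.0, closing_radius=0))
        strict = analyze_mask(
            punched, MorphometryConfig(1.0, closing_radius=0, min_chord=10.0)
        )
        assert strict.n_chords <= loose.n_chords

    def test_dump_intermediates(self, tmp_path, lattice_50):
        _, mask, _ = lattice_50
        path = render_to_file(mask, tmp_path)
        config = MorphometryConfig(1.0, dump_dir=str(tmp_path / "dump"))
        analyze_image(path, config)
        assert (tmp_path / "dump" / "img_mask.png").exists()


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _result(image_id, mli, ast=8.0):
    from lam_quant.morphometry import MorphometryResult

    return MorphometryResult(
        mli=mli, mli_sd=1.0, dispersion_index=0.1, ast=ast, ast_sd=0.5,
        n_chords=100, image_id=image_id,
    )


class TestAggregateBySubject:
    def test_single_subject_mean_sd(self):
        results = [_result(f"i{k}", v) for k, v in enumerate([48, 50, 52])]
        table = aggregate_by_subject(results, {f"i{k}": "s1" for k in range(3)})
        assert len(table) == 1
        assert table.loc[0, "mli_mean"] == 50
        assert table.loc[0, "mli_sd"] == pytest.approx(2.0)
        assert table.loc[0, "n_images"] == 3

    def test_two_subjects_two_rows(self):
        results = [_result("a", 50), _result("b", 60)]
        table = aggregate_by_subject(results, {"a": "s1", "b": "s2"})
        assert len(table) == 2

    def test_identical_images_zero_sd(self):
        results = [_result(f"i{k}", 47.5) for k in range(15)]
        table = aggregate_by_subject(results, {f"i{k}": "s1" for k in range(15)})
        assert table.loc[0, "mli_sd"] == 0.0

    def test_unmapped_image_rejected(self):
        with pytest.raises(ValueError, match="orphan"):
            aggregate_by_subject([_result("orphan", 50)], {})


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@given(height=st.integers(1, 5000), n=st.integers(1, 64))
def test_line_grid_properties(height, n):
    if height < n:
        with pytest.raises(ValueError):
            make_line_grid(height, n)
        return
    rows = np.array(make_line_grid(height, n).rows)
    assert rows.size == n
    assert (rows >= 0).all() and (rows < height).all()
    if n > 1:
        gaps = np.diff(rows)
        assert (gaps > 0).all()
        assert gaps.max() - gaps.min() <= 1


@given(line=st.lists(st.integers(0, 1), min_size=1, max_size=60))
def test_chord_runs_partition_the_line(line):
    line = np.array(line, dtype=np.uint8)
    total = 0
    for phase in (AIRSPACE, WALL):
        padded = np.concatenate(([1 - phase], line, [1 - phase]))
        diff = np.diff((padded == phase).astype(np.int8))
        all_lengths = np.flatnonzero(diff == -1) - np.flatnonzero(diff == 1)
        complete, truncated = chord_runs(line, phase)
        assert complete.size + truncated == all_lengths.size
        # complete runs never touch the border pixels
        if complete.size:
            assert complete.sum() <= line.size - 2
        total += all_lengths.sum()
    assert total == line.size


@given(
    st.integers(30, 80),
    st.integers(3, 8),
    st.integers(2, 4),
)
@settings(max_examples=10, deadline=None)
def test_lattice_mli_recovery_property(side, wall, cells):
    mask, gt = generate_lattice(LatticeSpec(side, wall, 1.0, cells, cells))
    result = analyze_mask(mask, MorphometryConfig(pixel_size=1.0))
    assert abs(result.mli - gt.true_mean_airspace_chord) <= 2.0
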