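import numpy as np
import pytest

from retimosaic import bifurcation as bif


@pytest.fixture(scope="module")
def bank():
    return bif.build_bank()


class TestBank:
    def test_sixteen_elements_with_four_pixels_each(self, bank):
        assert len(bank) == 16
        for se in bank:
            assert se.array.sum() == 4
            assert se.array[1, 1] == 1

    def test_closed_under_quarter_rotation(self, bank):
        patterns = {tuple(se.array.ravel()) for se in bank}
        for se in bank:
            rotated = np.rot90(se.array)
            assert tuple(rotated.ravel()) in patterns

    def test_branch_direction_mix(self, bank):
        # 4 purely orthogonal (T), 4 purely diagonal (Y), 8 mixed
        ortho = diag = mixed = 0
        for se in bank:
            arr = se.array
            n_orth = arr[0, 1] + arr[1, 0] + arr[1, 2] + arr[2, 1]
            if n_orth == 3:
                ortho += 1
            elif n_orth == 0:
                diag += 1
            else:
                mixed += 1
        assert (ortho, diag, mixed) == (4, 4, 8)

    def test_adjacent_branches_rejected(self, tmp_path):
        bad = tmp_path / "bank.txt"
        bad.write_text("110\n010\n010\n")
        with pytest.raises(ValueError, match="adjacent"):
            bif.build_bank("custom", bad)

    def test_custom_file_roundtrip(self, tmp_path, bank):
        path = tmp_path / "bank.txt"
        blocks = []
        for se in bank[:3]:
            blocks.append("\n".join("".join(str(v) for v in row)
                                    for row in se.pattern))
        path.write_text("\n\n".join(blocks) + "\n")
        loaded = bif.build_bank("custom", path)
        assert len(loaded) == 3
        assert all(np.array_equal(a.array, b.array)
                   for a, b in zip(loaded, bank[:3]))


class TestErode:
    def test_straight_line_never_matches(self, bank):
        line = np.zeros((9, 15), np.uint8)
        line[4, 1:14] = 1
        for se in bank:
            assert bif.erode(line, se).sum() == 0

    def test_t_junction_matches_its_element(self, bank):
        t = np.zeros((9, 9), np.uint8)
        t[4, 1:8] = 1   # horizontal bar
        t[5:8, 4] = 1   # stem going down
        target = np.zeros((3, 3), np.uint8)
        target[1, 1] = target[1, 0] = target[1, 2] = target[2, 1] = 1
        se = next(s for s in bank if np.array_equal(s.array, target))
        out = bif.erode(t, se)
        assert out.sum() == 1 and out[4, 4] == 1

    def test_empty_skeleton(self, bank):
        assert bif.erode(np.zeros((5, 5), np.uint8), bank[0]).sum() == 0


class TestAccumulate:
    def test_mean_of_identical_masks(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        acc = bif.accumulate([m, m])
        assert np.allclose(acc, m)

    def test_single_pixel_in_one_of_fourteen(self):
        masks = [np.zeros((5, 5), np.uint8) for _ in range(14)]
        masks[4][2, 3] = 1
        acc = bif.accumulate(masks)
        assert acc[2, 3] == pytest.approx(1.0 / 14.0, abs=1e-15)
        assert acc.sum() == pytest.approx(1.0 / 14.0, abs=1e-14)

    @pytest.mark.parametrize("n", [2, 3, 7, 14, 16])
    def test_recursion_equals_brute_force_mean(self, n, rng):
        masks = [(rng.random((6, 6)) > 0.6).astype(np.uint8)
                 for _ in range(n)]
        acc = bif.accumulate(masks)
        oracle = np.mean([m.astype(float) for m in masks], axis=0)
        assert np.allclose(acc, oracle, atol=1e-15)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimensions"):
            bif.accumulate([np.zeros((4, 4)), np.zeros((5, 4))])

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            bif.accumulate([np.zeros((4, 4))])


class TestExtractAndSuppress:
    def test_union_semantics(self):
        acc = np.zeros((5, 5))
        assert bif.extract_candidates(acc).sum() == 0
        acc[2, 2] = 1.0 / 14.0
        acc[1, 3] = 1.0
        out = bif.extract_candidates(acc)
        assert out[2, 2] == 1 and out[1, 3] == 1 and out.sum() == 2

    def test_close_pair_keeps_raster_first(self):
        c = np.zeros((9, 9), np.uint8)
        c[4, 2] = c[4, 4] = 1  # 2 px apart, inside the 5x5 window
        assert bif.suppress(c, 5) == [(2, 4)]

    def test_distant_pair_survives(self):
        c = np.zeros((9, 12), np.uint8)
        c[4, 2] = c[4, 7] = 1  # 5 px apart, outside the window
        assert bif.suppress(c, 5) == [(2, 4), (7, 4)]

    def test_single_candidate(self):
        c = np.zeros((5, 5), np.uint8)
        c[3, 1] = 1
        assert bif.suppress(c) == [(1, 3)]

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            bif.suppress(np.zeros((5, 5), np.uint8), window=4)

    def test_suppression_spacing_property(self):
        from hypothesis import given, settings, strategies as st
        import hypothesis.extra.numpy as hnp

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(hnp.arrays(np.uint8, (18, 18),
                          elements=st.integers(min_value=0, max_value=1)))
        def check(cand):
            pts = bif.suppress(cand, window=5)
            # no emitted point lies within the 5x5 window of an earlier one
            for a in range(len(pts)):
                for b in range(a + 1, len(pts)):
                    dx = abs(pts[a][0] - pts[b][0])
                    dy = abs(pts[a][1] - pts[b][1])
                    assert max(dx, dy) > 2
            # every candidate is covered by some emitted window
            for y, x in zip(*np.nonzero(cand)):
                assert any(max(abs(x - px), abs(y - py)) <= 2
                           for px, py in pts)

        check()

    def test_output_in_raster_order(self, rng):
        c = (rng.random((30, 30)) > 0.9).astype(np.uint8)
        pts = bif.suppress(c)
        keys = [(y, x) for x, y in pts]
        assert keys == sorted(keys)


class TestDetect:
    def _y_skeleton(self):
        m = np.zeros((15, 15), np.uint8)
        for k in range(6):
            m[7 - k, 7] = 1          # north ray
            m[7 + k, 7 - k] = 1      # south-west ray
            m[7 + k, 7 + k] = 1      # south-east ray
        return m

    def test_perfect_y_gives_single_junction(self, bank):
        pts = bif.detect_bifurcations(self._y_skeleton(), bank)
        assert pts == [(7, 7)]

    def test_straight_line_gives_nothing(self, bank):
        line = np.zeros((9, 20), np.uint8)
        line[4, 2:18] = 1
        assert bif.detect_bifurcations(line, bank) == []

    def test_detections_lie_on_skeleton(self, bank):
        sk = self._y_skeleton()
        for x, y in bif.detect_bifurcations(sk, bank):
            assert sk[y, x] == 1

    def test_translation_equivariance(self, bank):
        sk = np.zeros((40, 40), np.uint8)
        sk[5:20, 10:25] = self._y_skeleton()
        base = bif.detect_bifurcations(sk, bank)
        shifted = np.roll(np.roll(sk, 3, axis=0), 5, axis=1)
        moved = bif.detect_bifurcations(shifted, bank)
        assert moved == [(x + 5, y + 3) for x, y in base]

    def test_quarter_rotation_equivariance(self, bank):
        # diagonal X: the only candidate pixel is the centre, so the
        # detection is exactly equivariant (orthogonal-armed crossings
        # yield small candidate clusters whose suppression survivor is
        # raster-order dependent, equivariant only up to the window)
        n = 21
        sk = np.zeros((n, n), np.uint8)
        for k in range(1, 9):
            for sx in (-1, 1):
                for sy in (-1, 1):
                    sk[10 + sy * k, 10 + sx * k] = 1
        sk[10, 10] = 1
        base = bif.detect_bifurcations(sk, bank)
        assert base == [(10, 10)]
        rot = bif.detect_bifurcations(np.rot90(sk).copy(), bank)
        mapped = sorted((y, n - 1 - x) for x, y in base)
        assert sorted(rot) == mapped

    def test_synthetic_tree_junction_recovery(self, bank):
        from scipy.spatial.distance import cdist
        from retimosaic.preproc import thin
        from retimosaic.synthetic import generate_tree
        scene = generate_tree(seed=12, n_branch_events=10,
                              canvas_size=(500, 400))
        pts = bif.detect_bifurcations(thin(scene.vessel_mask), bank)
        gt = np.asarray(scene.bifurcations_gt)
        d = cdist(np.asarray(pts, dtype=float), gt)
        assert len(pts) == 10
        assert d.min(axis=0).max() <= 2.0
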