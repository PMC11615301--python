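"""Skeleton accounting, filamentous factor, local thickness, lengths."""

import math

import numpy as np
import pytest

import mitomorph as mm
from conftest import as_mask, rasterized_disk

SQRT2 = math.sqrt(2.0)


# ---- hand-constructed skeleton grids ----------------------------------

def straight_line(n=10):
    arr = np.zeros((5, n + 4), bool)
    arr[2, 2:2 + n] = True
    return arr


def symmetric_y(arm=10):
    arr = np.zeros((2 * arm + 5, 2 * arm + 5), bool)
    c = arm + 2
    arr[c, 2:c + 1] = True  # horizontal arm into the centre
    for i in range(1, arm + 1):
        arr[c - i, c + i] = True
        arr[c + i, c + i] = True
    return arr


def x_cross(arm=10):
    n = 2 * arm + 1
    arr = np.zeros((n, n), bool)
    for i in range(n):
        arr[i, i] = True
        arr[i, n - 1 - i] = True
    return arr


def diamond():
    arr = np.zeros((5, 5), bool)
    for y, x in [(0, 2), (1, 1), (1, 3), (2, 0), (2, 4), (3, 1), (3, 3), (4, 2)]:
        arr[y, x] = True
    return arr


# ---- skeletonization ---------------------------------------------------

def test_skeletonize_single_pixel_is_fixed_point():
    arr = np.zeros((5, 5), bool)
    arr[2, 2] = True
    assert np.array_equal(mm.skeletonize_fragment(as_mask(arr)).pixels, arr)


def test_skeletonize_bar_gives_one_px_line():
    bar = np.zeros((7, 25), bool)
    bar[2:5, 2:23] = True  # 3 x 21
    skel = mm.skeletonize_fragment(as_mask(bar))
    s = mm.analyze_skeleton(skel)
    assert (s.n_junctions, s.n_branches, s.n_endpoints) == (0, 1, 2)
    assert 18 <= s.total_skeleton_length <= 21


def test_skeletonize_annulus_keeps_cycle():
    gy, gx = np.mgrid[:40, :40]
    r2 = (gy - 20) ** 2 + (gx - 20) ** 2
    ann = (r2 <= 15 ** 2) & (r2 >= 8 ** 2)
    s = mm.analyze_skeleton(mm.skeletonize_fragment(as_mask(ann)))
    # exactly one cycle: a single branch with no endpoints and no junctions
    assert (s.n_junctions, s.n_branches, s.n_endpoints) == (0, 1, 0)


# ---- skeleton graph accounting -----------------------------------------

def test_analyze_line():
    s = mm.analyze_skeleton(as_mask(straight_line(10)))
    assert (s.n_junctions, s.n_branches, s.n_endpoints) == (0, 1, 2)
    assert s.total_skeleton_length == pytest.approx(9.0)
    assert s.longest_path_length == pytest.approx(9.0)


def test_analyze_symmetric_y():
    s = mm.analyze_skeleton(as_mask(symmetric_y(10)))
    assert (s.n_junctions, s.n_branches, s.n_endpoints) == (1, 3, 3)
    assert s.total_skeleton_length == pytest.approx(10 + 2 * 10 * SQRT2)
    assert s.longest_path_length == pytest.approx(2 * 10 * SQRT2)


def test_analyze_diamond_cycle():
    s = mm.analyze_skeleton(as_mask(diamond()))
    assert (s.n_junctions, s.n_branches, s.n_endpoints) == (0, 1, 0)


def test_analyze_rejects_unthinned_input():
    arr = np.zeros((6, 6), bool)
    arr[2:4, 2:4] = True
    with pytest.raises(ValueError, match="skeleton"):
        mm.analyze_skeleton(as_mask(arr))


def test_tree_edge_count_consistency():
    """Acyclic one-component skeletons satisfy B = E + J − 1 (tree edges)."""
    for arr in (straight_line(8), symmetric_y(6), x_cross(7)):
        s = mm.analyze_skeleton(as_mask(arr))
        assert s.n_branches == s.n_endpoints + s.n_junctions - 1


def test_pixel_size_scales_lengths():
    s1 = mm.analyze_skeleton(as_mask(straight_line(10), pixel_size=1.0))
    s2 = mm.analyze_skeleton(as_mask(straight_line(10), pixel_size=0.1))
    assert s2.total_skeleton_length == pytest.approx(0.1 * s1.total_skeleton_length)


# ---- filamentous factor -------------------------------------------------

def test_ff_worked_skeletons():
    line = mm.analyze_skeleton(as_mask(straight_line(10)))
    y = mm.analyze_skeleton(as_mask(symmetric_y(10)))
    x = mm.analyze_skeleton(as_mask(x_cross(10)))
    loop = mm.analyze_skeleton(as_mask(diamond()))
    assert mm.filamentous_factor([line]) == pytest.approx(0.5)
    assert mm.filamentous_factor([y]) == pytest.approx(4 / 3)
    assert mm.filamentous_factor([x]) == pytest.approx(5 / 4)
    assert mm.filamentous_factor([loop]) == pytest.approx(1.0)  # ΣE=0 guard
    assert math.isnan(mm.filamentous_factor([]))


def test_ff_monotone_in_branching():
    """Adding a branch (holding endpoints fixed or growing them less)
    never lowers FF: compare line, Y, and double-Y."""
    line = mm.analyze_skeleton(as_mask(straight_line(12)))
    y = mm.analyze_skeleton(as_mask(symmetric_y(6)))
    assert mm.filamentous_factor([y]) > mm.filamentous_factor([line])
    # aggregate over several fragments
    assert mm.filamentous_factor([y, y]) > mm.filamentous_factor([line, line])


def test_branching_counts():
    line = mm.analyze_skeleton(as_mask(straight_line(10)))
    x = mm.analyze_skeleton(as_mask(x_cross(10)))
    assert mm.branching_counts([line, line]) == (0, 2, 4, 2)
    assert mm.branching_counts([x]) == (1, 4, 4, 1)
    assert mm.branching_counts([]) == (0, 0, 0, 0)


# ---- fragment length ----------------------------------------------------

def test_fragment_length_modes():
    y = mm.analyze_skeleton(as_mask(symmetric_y(10)))
    assert mm.fragment_length(y, 100.0, "total") == pytest.approx(10 + 20 * SQRT2)
    assert mm.fragment_length(y, 100.0, "longest_path") == pytest.approx(20 * SQRT2)
    with pytest.raises(ValueError):
        mm.fragment_length(y, 100.0, "bogus")


def test_fragment_length_fallback_for_tiny_skeletons():
    single = np.zeros((5, 5), bool)
    single[2, 2] = True
    s = mm.analyze_skeleton(as_mask(single))
    area = 12.0
    assert mm.fragment_length(s, area) == pytest.approx(2 * math.sqrt(area / math.pi))


def test_tube_length_within_skeleton_end_bias():
    """A straight 100x5 tube: skeleton ends erode by about width/2 each."""
    tube = np.zeros((11, 106), bool)
    tube[3:8, 3:103] = True
    labels = mm.label_fragments(as_mask(tube))
    s = mm.summarize_fragments(labels)[0]
    length = mm.fragment_length(s, float(tube.sum()))
    assert 90 <= length <= 100


# ---- local thickness ----------------------------------------------------

def brute_force_thickness(fg: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Exhaustive largest-inscribed-disk search (integer arithmetic)."""
    fg = fg.astype(bool)
    out = np.zeros(fg.shape, float)
    ys, xs = np.nonzero(fg)
    if len(ys) == 0:
        return out
    bys, bxs = np.nonzero(~fg)
    pts = np.column_stack([ys, xs]).astype(np.int64)
    if len(bys):
        bg = np.column_stack([bys, bxs]).astype(np.int64)
        d2 = ((pts[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
        r2 = d2.min(axis=1)
    else:
        r2 = np.full(len(pts), fg.shape[0] ** 2 + fg.shape[1] ** 2, np.int64)
    pair = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    covered = pair < r2[None, :]
    best = np.where(covered, r2[None, :], 0).max(axis=1)
    out[ys, xs] = 2.0 * (np.sqrt(best) - 0.5) * pixel_size
    return out


def test_thickness_matches_brute_force_exactly():
    rng = np.random.default_rng(7)
    fixtures = [rng.random((24, 24)) > 0.55 for _ in range(4)]
    fixtures.append(rasterized_disk(9))
    bar = np.zeros((20, 40), bool)
    bar[4:15, :] = True
    fixtures.append(bar)
    fixtures.append(np.zeros((8, 8), bool))
    for fg in fixtures:
        got = mm.local_thickness(as_mask(fg)).pixels
        want = brute_force_thickness(fg)
        assert np.array_equal(got, want)


def test_thickness_of_strip_equals_width():
    bar = np.zeros((15, 60), bool)
    bar[2:13, :] = True  # 11 px wide
    t = mm.local_thickness(as_mask(bar)).pixels
    assert t[7, 30] == pytest.approx(11.0)


def test_thickness_of_disk_near_diameter():
    disk = rasterized_disk(25)
    t = mm.local_thickness(as_mask(disk)).pixels
    assert t.max() == pytest.approx(50.0, abs=1.5)
    assert np.all(t[~disk] == 0)


def test_thickness_zero_on_background_and_scales():
    bar = np.zeros((9, 20), bool)
    bar[3:6, :] = True
    t1 = mm.local_thickness(as_mask(bar, pixel_size=1.0)).pixels
    t2 = mm.local_thickness(as_mask(bar, pixel_size=0.5)).pixels
    assert np.allclose(t2, 0.5 * t1)
    assert np.all(t1[~bar] == 0)


def test_phantom_thickness_recovers_generating_width(tubular_phantom):
    out = tubular_phantom
    t = mm.local_thickness(out.truth_mask).pixels
    nz = t[t > 0]
    assert np.median(nz) == pytest.approx(5.0, rel=0.15)


def test_phantom_length_recovers_centerline():
    from mitomorph.phantom import PhantomSpec, generate_phantom
    out = generate_phantom(PhantomSpec.for_regime(
        "tubular", seed=5, gaussian_noise_sd=0.0, n_branches_per_fragment=(0, 0)))
    stats = out.truth_stats.set_index("fragment_id")
    for s in mm.summarize_fragments(out.truth_fragments):
        true_len = stats.loc[s.label, "centerline_length_px"]
        if true_len < 10 * 5.0:
            continue  # bias bound only holds for long, unbranched tubes
        assert s.longest_path_length == pytest.approx(true_len, rel=0.10)
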