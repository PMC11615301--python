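"""Phantom generator: determinism, ground-truth geometry, regime contrast."""

import numpy as np
import pytest
from scipy import ndimage

import mitomorph as mm
from mitomorph.phantom import PhantomSpec, _ghost_spots, generate_phantom, truth_summary
from mitomorph.pipeline import fragment_table


def test_seeded_determinism_bit_identical():
    spec = PhantomSpec.for_regime("spherical", seed=7, height=256, width=256)
    a = generate_phantom(spec)
    b = generate_phantom(spec)
    assert np.array_equal(a.image.pixels, b.image.pixels)
    assert np.array_equal(a.truth_fragments.pixels, b.truth_fragments.pixels)
    assert np.array_equal(a.cell_mask.pixels, b.cell_mask.pixels)
    assert a.truth_stats.equals(b.truth_stats)


def test_adding_cells_keeps_existing_cells():
    few = generate_phantom(PhantomSpec.for_regime("spherical", seed=3, n_cells=2))
    more = generate_phantom(PhantomSpec.for_regime("spherical", seed=3, n_cells=4))
    for lab in (1, 2):
        assert np.array_equal(few.cell_mask.pixels == lab,
                              more.cell_mask.pixels == lab)


def test_truth_mask_consistency(tubular_phantom):
    out = tubular_phantom
    assert np.array_equal(out.truth_mask.pixels, out.truth_fragments.pixels > 0)
    # every truth fragment lies inside exactly one cell
    for fid in out.truth_fragments.labels():
        cells_under = np.unique(out.cell_mask.pixels[out.truth_fragments.pixels == fid])
        assert len(cells_under) == 1 and cells_under[0] > 0


def test_noiseless_centerline_is_bright(tubular_phantom):
    out = tubular_phantom
    spec_bg, spec_peak = 2000.0, 20000.0
    # every truth pixel reaches at least half peak above background; the
    # centerline (profile maximum) reaches at least ~the full peak
    vals = out.image.pixels[out.truth_mask.pixels].astype(float)
    assert vals.min() >= spec_bg + 0.5 * spec_peak - 1  # rounding slack
    assert out.image.pixels.max() >= spec_bg + 0.95 * spec_peak


def test_ghost_spots_exact_count_disjoint_from_truth():
    spec = PhantomSpec.for_regime("noisy_background", seed=9, n_ghost_spots=10)
    out = generate_phantom(spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=9, spawn_key=(4,)))
    layer = _ghost_spots(spec, out.truth_mask.pixels, rng)
    bright = layer >= 0.5 * 0.9 * spec.tube_intensity
    _, n = ndimage.label(bright, structure=np.ones((3, 3)))
    assert n == 10
    assert not np.any(bright & out.truth_mask.pixels)


def test_truth_summary_by_construction():
    out = generate_phantom(PhantomSpec.for_regime("spherical", seed=2))
    stats = truth_summary(out)
    assert set(stats["shape_class"]) == {"sphere"}
    assert (stats["centerline_length_px"] == 0).all()
    assert (stats["width_px"] >= 1.1 * 5.0).all()  # swollen vs tube width
    empty = generate_phantom(PhantomSpec.for_regime("tubular", seed=1, n_cells=0))
    assert len(truth_summary(empty)) == 0


def test_impossible_geometry_rejected():
    with pytest.raises(ValueError, match="tube width"):
        PhantomSpec(tube_width_px=50.0, cell_radius_px=(20.0, 30.0))


def test_regime_separation_directionality(tubular_phantom, spherical_phantom):
    """Tubular networks are longer and less circular than collapsed spheres."""
    cfg = mm.PipelineConfig()
    stats = {}
    for name, out in (("tubular", tubular_phantom), ("spherical", spherical_phantom)):
        df, _, summaries = fragment_table(out.truth_mask, out.image, cfg)
        stats[name] = (df["length"].mean(), df["circularity"].mean(),
                       mm.filamentous_factor(summaries))
    assert stats["tubular"][0] > stats["spherical"][0]
    assert stats["spherical"][1] > stats["tubular"][1]
    assert stats["tubular"][2] > stats["spherical"][2]


def test_noise_cannot_improve_best_sweep_dice():
    """Mean best-achievable Dice over a threshold sweep is non-increasing
    in the generator's noise level (10 seeds per level)."""
    levels = [0.0, 2000.0, 6000.0]
    cfg = mm.ThresholdSweepConfig(background_radius_px=0, median_radius_px=1,
                                  opening_radius_px=0,
                                  thresholds=np.linspace(4000, 20000, 12).tolist())
    mean_best = []
    for sd in levels:
        best = []
        for seed in range(10):
            out = generate_phantom(PhantomSpec.for_regime(
                "tubular", seed=seed, gaussian_noise_sd=sd,
                height=256, width=256, n_cells=2))
            img = mm.preprocess(out.image, cfg)
            sweep = mm.sweep_thresholds(img, cfg)
            best.append(max(mm.dice_score(c, out.truth_mask)
                            for c in sweep.candidates))
        mean_best.append(np.mean(best))
    assert mean_best[0] >= mean_best[1] >= mean_best[2]
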