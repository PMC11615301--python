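"""Synthetic fluorescence phantoms of yeast mitochondria.

The generator draws yeast cells as non-overlapping ellipses and renders
mitochondria inside them in one of four regimes:

* ``tubular`` — the physiological state: smooth branched polyline trees
  hugging the cell cortex, rendered with a Gaussian cross-section of a
  given full-width-half-maximum (FWHM),
* ``spherical`` — the oxidative-stress collapse: well-separated swollen
  disks,
* ``web`` — the fission-deficient hyperfused state: a cortical ring with
  chords, i.e. a skeleton graph with cycles,
* ``noisy_background`` — tubular mitochondria plus dim autofluorescent
  unlabelled cells and small bright artefactual spots that lie outside
  the ground truth, mimicking images with high background noise.

Ground truth is defined before any noise is added, by thresholding each
fragment's noiseless profile at half its peak amplitude (the FWHM
convention), which makes the truth tube width equal the generating FWHM.
Every source of randomness derives from ``spec.seed`` through per-purpose
and per-cell substreams, so output is bit-identical for a fixed spec and
adding cells does not reshuffle existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import ndimage

from .io import BinaryMask, Image2D, LabelMask

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

REGIMES = ("tubular", "spherical", "web", "noisy_background")


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom image."""

    regime: str = "tubular"
    n_cells: int = 6
    cell_radius_px: tuple[float, float] = (40.0, 60.0)
    tube_width_px: float = 5.0  # FWHM of the tube cross-section
    tube_intensity: float = 20000.0  # peak amplitude above background (16-bit)
    n_fragments_per_cell: tuple[int, int] = (2, 3)
    n_branches_per_fragment: tuple[int, int] = (1, 2)  # tubular regime only
    background_level: float = 2000.0
    gaussian_noise_sd: float = 800.0
    n_autofluorescent_blobs: int = 4
    n_ghost_spots: int = 8
    seed: int = 0
    height: int = 512
    width: int = 512

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.tube_width_px < 1:
            raise ValueError("tube_width_px must be >= 1")
        if self.tube_width_px > min(self.cell_radius_px):
            raise ValueError("tube width exceeds cell radius: geometrically impossible")
        if self.background_level + self.tube_intensity > 65535:
            raise ValueError("intensities exceed the 16-bit range")
        if self.n_cells < 0 or self.height < 16 or self.width < 16:
            raise ValueError("invalid geometry")

    @classmethod
    def for_regime(cls, regime: str, **overrides) -> "PhantomSpec":
        """Regime-tuned defaults (fragment counts, widths)."""
        base = {
            "tubular": dict(n_fragments_per_cell=(2, 3)),
            "spherical": dict(n_fragments_per_cell=(5, 8)),
            "web": dict(n_fragments_per_cell=(1, 1)),
            "noisy_background": dict(n_fragments_per_cell=(2, 3)),
        }[regime]
        base.update(overrides)
        return cls(regime=regime, **base)


@dataclass
class PhantomOutput:
    """Image plus all ground-truth artefacts of one phantom."""

    image: Image2D
    truth_mask: BinaryMask
    cell_mask: LabelMask
    truth_fragments: LabelMask
    truth_stats: pd.DataFrame


@dataclass
class _Cell:
    cy: float
    cx: float
    a: float  # semi-axis along x
    b: float  # semi-axis along y
    label: int


@dataclass
class _Fragment:
    cell_label: int
    shape_class: str  # tube | sphere | web
    polylines: list[np.ndarray]  # each (N, 2) float (y, x), finely sampled
    width: float  # FWHM in px
    centerline_length: float  # px


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _place_cells(spec: PhantomSpec) -> list[_Cell]:
    cells: list[_Cell] = []
    r_lo, r_hi = spec.cell_radius_px
    for i in range(spec.n_cells):
        rng = _rng(spec.seed, 1, i)
        placed = False
        for _ in range(300):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            margin = max(a, b) + 2
            if 2 * margin >= min(spec.height, spec.width):
                continue
            cy = rng.uniform(margin, spec.height - margin)
            cx = rng.uniform(margin, spec.width - margin)
            ok = all(math.hypot(cy - c.cy, cx - c.cx) > max(a, b) + max(c.a, c.b) + 4
                     for c in cells)
            if ok:
                cells.append(_Cell(cy, cx, a, b, label=len(cells) + 1))
                placed = True
                break
        if not placed:
            # crowded canvas: this cell is dropped rather than overlapped
            continue
    return cells


def _ellipse_point(cell: _Cell, rho: float, theta: float) -> tuple[float, float]:
    return (cell.cy + rho * cell.b * math.sin(theta),
            cell.cx + rho * cell.a * math.cos(theta))


def _sample_arc(cell: _Cell, rho: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    ys = cell.cy + rho * cell.b * np.sin(thetas)
    xs = cell.cx + rho * cell.a * np.cos(thetas)
    return np.column_stack([ys, xs])


def _resample(points: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline to roughly uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        return points[:1]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(math.ceil(total / step)) + 1)
    t = np.linspace(0, total, n)
    ys = np.interp(t, cum, points[:, 0])
    xs = np.interp(t, cum, points[:, 1])
    return np.column_stack([ys, xs])


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _tubular_fragments(spec: PhantomSpec, cell: _Cell,
                       rng: np.random.Generator) -> list[_Fragment]:
    lo, hi = spec.n_fragments_per_cell
    n = int(rng.integers(lo, hi + 1))
    frags = []
    if n == 0:
        return frags
    r_min = min(cell.a, cell.b)
    rho_max = min(0.85, 1.0 - (spec.tube_width_px / 2 + 3.0) / r_min)
    rho_max = max(rho_max, 0.3)
    sector = 2 * math.pi / n
    # angular half-gap keeping neighbouring arcs >= width + 3 px apart
    gap = (spec.tube_width_px + 4.0) / (2 * rho_max * r_min)
    for k in range(n):
        theta0 = k * sector + gap + rng.uniform(0, 0.1 * sector)
        theta1 = (k + 1) * sector - gap - rng.uniform(0, 0.1 * sector)
        if theta1 <= theta0:
            theta1 = theta0 + 0.2
        m = max(8, int((theta1 - theta0) / 0.02))
        thetas = np.linspace(theta0, theta1, m)
        # smooth radial wobble around the cortex
        wobble = np.cumsum(rng.normal(0, 0.004, m))
        wobble -= np.linspace(wobble[0], wobble[-1], m)
        rho = np.clip(rng.uniform(0.78, 0.95) * rho_max + wobble, 0.3, rho_max)
        main = _resample(_sample_arc(cell, rho, thetas))
        polylines = [main]
        length = _polyline_length(main)
        # inward side branches create junctions (branched tubular network)
        b_lo, b_hi = spec.n_branches_per_fragment
        n_branch = int(rng.integers(b_lo, b_hi + 1))
        for _ in range(n_branch):
            j = int(rng.integers(m // 4, 3 * m // 4))
            py, px = _ellipse_point(cell, float(rho[j]), float(thetas[j]))
            # head towards the cell centre (stays inside this sector)
            vy, vx = cell.cy - py, cell.cx - px
            norm = math.hypot(vy, vx)
            if norm < 1e-6:
                continue
            blen = min(rng.uniform(8, 18), 0.45 * norm)
            bend = rng.uniform(-0.25, 0.25)
            c, s = math.cos(bend), math.sin(bend)
            dy, dx = (c * vy - s * vx) / norm, (s * vy + c * vx) / norm
            branch = _resample(np.array([[py, px],
                                         [py + dy * blen, px + dx * blen]]))
            polylines.append(branch)
            length += _polyline_length(branch)
        frags.append(_Fragment(cell.label, "tube", polylines,
                               spec.tube_width_px, length))
    return frags


def _spherical_fragments(spec: PhantomSpec, cell: _Cell,
                         rng: np.random.Generator) -> list[_Fragment]:
    lo, hi = spec.n_fragments_per_cell
    n = int(rng.integers(lo, hi + 1))
    frags: list[_Fragment] = []
    centers: list[tuple[float, float, float]] = []
    r_min = min(cell.a, cell.b)
    for _ in range(n):
        for _try in range(200):
            width = rng.uniform(1.1, 1.7) * spec.tube_width_px  # swollen
            rho_max = max(0.2, 1.0 - (width / 2 + 3.0) / r_min)
            rho = math.sqrt(rng.uniform(0, 1)) * rho_max
            theta = rng.uniform(0, 2 * math.pi)
            py, px = _ellipse_point(cell, rho, theta)
            ok = all(math.hypot(py - y0, px - x0) > (width + w0) / 2 + 4
                     for y0, x0, w0 in centers)
            if ok:
                centers.append((py, px, width))
                frags.append(_Fragment(cell.label, "sphere",
                                       [np.array([[py, px]])], width, 0.0))
                break
    return frags


def _web_fragments(spec: PhantomSpec, cell: _Cell,
                   rng: np.random.Generator) -> list[_Fragment]:
    r_min = min(cell.a, cell.b)
    rho_max = min(0.85, 1.0 - (spec.tube_width_px / 2 + 3.0) / r_min)
    rho_ring = rng.uniform(0.8, 0.95) * rho_max
    m = max(32, int(2 * math.pi / 0.02))
    thetas = np.linspace(0, 2 * math.pi, m)
    ring = _resample(_sample_arc(cell, np.full(m, rho_ring), thetas))
    polylines = [ring]
    length = _polyline_length(ring)
    # chords across the ring close cycles
    n_chords = int(rng.integers(2, 4))
    for _ in range(n_chords):
        t0 = rng.uniform(0, 2 * math.pi)
        t1 = t0 + rng.uniform(0.35 * math.pi, 0.8 * math.pi) * rng.choice([-1, 1])
        p0 = _ellipse_point(cell, rho_ring, t0)
        p1 = _ellipse_point(cell, rho_ring, t1)
        chord = _resample(np.array([p0, p1]))
        polylines.append(chord)
        length += _polyline_length(chord)
    return [_Fragment(cell.label, "web", polylines, spec.tube_width_px, length)]


def _render_fragment(frag: _Fragment, spec: PhantomSpec,
                     canvas: np.ndarray, best: np.ndarray,
                     labels: np.ndarray, frag_id: int) -> None:
    """Render one fragment's Gaussian profile into the shared canvases.

    ``canvas`` keeps the max-composited signal, ``best`` the per-pixel
    strongest profile, ``labels`` the winning fragment id where the
    profile is at least half the peak.
    """
    pts = np.concatenate(frag.polylines, axis=0)
    sigma = frag.width * FWHM_TO_SIGMA
    cut = 4.0 * sigma
    y0 = max(0, int(math.floor(pts[:, 0].min() - cut)))
    y1 = min(spec.height, int(math.ceil(pts[:, 0].max() + cut)) + 1)
    x0 = max(0, int(math.floor(pts[:, 1].min() - cut)))
    x1 = min(spec.width, int(math.ceil(pts[:, 1].max() + cut)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    gy, gx = np.mgrid[y0:y1, x0:x1]
    grid = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    d, _ = cKDTree(pts).query(grid, k=1, distance_upper_bound=cut)
    d = d.reshape(gy.shape)
    profile = np.where(np.isfinite(d),
                       spec.tube_intensity * np.exp(-d ** 2 / (2 * sigma ** 2)),
                       0.0)
    window = canvas[y0:y1, x0:x1]
    np.maximum(window, profile, out=window)
    half = profile >= 0.5 * spec.tube_intensity
    bwin = best[y0:y1, x0:x1]
    lwin = labels[y0:y1, x0:x1]
    take = half & (profile > bwin)
    lwin[take] = frag_id
    np.maximum(bwin, np.where(half, profile, 0.0), out=bwin)


def _ellipse_mask(cell: _Cell, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    y0 = max(0, int(cell.cy - cell.b - 2)); y1 = min(h, int(cell.cy + cell.b + 3))
    x0 = max(0, int(cell.cx - cell.a - 2)); x1 = min(w, int(cell.cx + cell.a + 3))
    gy, gx = np.mgrid[y0:y1, x0:x1]
    inside = (((gx - cell.cx) / cell.a) ** 2 + ((gy - cell.cy) / cell.b) ** 2) <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _ghost_spots(spec: PhantomSpec, truth: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Bright artefactual spots, each a single component disjoint from truth."""
    layer = np.zeros((spec.height, spec.width), dtype=float)
    width = 3.0
    sigma = width * FWHM_TO_SIGMA
    # keep spot half-max disks clear of the truth and of each other
    clearance = ndimage.binary_dilation(truth, iterations=int(width + 4))
    centers: list[tuple[float, float]] = []
    placed = 0
    attempts = 0
    while placed < spec.n_ghost_spots and attempts < 5000:
        attempts += 1
        py = rng.uniform(4, spec.height - 4)
        px = rng.uniform(4, spec.width - 4)
        if clearance[int(py), int(px)]:
            continue
        if any(math.hypot(py - y0, px - x0) < 4 * width for y0, x0 in centers):
            continue
        centers.append((py, px))
        y0 = max(0, int(py - 4 * sigma)); y1 = min(spec.height, int(py + 4 * sigma) + 1)
        x0 = max(0, int(px - 4 * sigma)); x1 = min(spec.width, int(px + 4 * sigma) + 1)
        gy, gx = np.mgrid[y0:y1, x0:x1]
        d2 = (gy - py) ** 2 + (gx - px) ** 2
        spot = 0.9 * spec.tube_intensity * np.exp(-d2 / (2 * sigma ** 2))
        np.maximum(layer[y0:y1, x0:x1], spot, out=layer[y0:y1, x0:x1])
        placed += 1
    if placed < spec.n_ghost_spots:
        raise ValueError("could not place all ghost spots disjoint from truth")
    return layer


def _autofluorescent_halos(spec: PhantomSpec, cells: list[_Cell],
                           rng: np.random.Generator) -> np.ndarray:
    """Dim whole-cell halos from unlabelled/dead cells."""
    layer = np.zeros((spec.height, spec.width), dtype=float)
    r_lo, r_hi = spec.cell_radius_px
    placed: list[_Cell] = []
    attempts = 0
    while len(placed) < spec.n_autofluorescent_blobs and attempts < 2000:
        attempts += 1
        a = rng.uniform(0.6 * r_lo, 0.8 * r_hi)
        b = rng.uniform(0.6 * r_lo, 0.8 * r_hi)
        margin = max(a, b) + 2
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        ok = all(math.hypot(cy - c.cy, cx - c.cx) > max(a, b) + max(c.a, c.b) + 4
                 for c in cells + placed)
        if not ok:
            continue
        ghost = _Cell(cy, cx, a, b, label=0)
        placed.append(ghost)
        mask = _ellipse_mask(ghost, layer.shape)
        layer[mask] = np.maximum(layer[mask], 0.12 * spec.tube_intensity)
    return ndimage.gaussian_filter(layer, sigma=3.0)


def generate_phantom(spec: PhantomSpec, pixel_size: float = 1.0) -> PhantomOutput:
    """Generate one phantom image with ground truth."""
    cells = _place_cells(spec)
    h, w = spec.height, spec.width
    signal = np.zeros((h, w), dtype=float)
    best = np.zeros((h, w), dtype=float)
    frag_labels = np.zeros((h, w), dtype=np.int64)

    base_regime = "tubular" if spec.regime == "noisy_background" else spec.regime
    fragments: list[_Fragment] = []
    for cell in cells:
        rng = _rng(spec.seed, 2, cell.label)
        if base_regime == "tubular":
            fragments.extend(_tubular_fragments(spec, cell, rng))
        elif base_regime == "spherical":
            fragments.extend(_spherical_fragments(spec, cell, rng))
        else:
            fragments.extend(_web_fragments(spec, cell, rng))

    rows = []
    for fid, frag in enumerate(fragments, start=1):
        _render_fragment(frag, spec, signal, best, frag_labels, fid)
        rows.append(dict(fragment_id=fid, cell_label=frag.cell_label,
                         shape_class=frag.shape_class,
                         centerline_length_px=frag.centerline_length,
                         width_px=frag.width))
    truth = frag_labels > 0

    noiseless = spec.background_level + signal
    if spec.regime == "noisy_background":
        halo_rng = _rng(spec.seed, 3)
        spot_rng = _rng(spec.seed, 4)
        noiseless = noiseless + _autofluorescent_halos(spec, cells, halo_rng)
        noiseless = np.maximum(noiseless,
                               spec.background_level + _ghost_spots(spec, truth, spot_rng))

    noise_rng = _rng(spec.seed, 5)
    img = noiseless
    if spec.gaussian_noise_sd > 0:
        img = img + noise_rng.normal(0, spec.gaussian_noise_sd, size=(h, w))
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    cell_pixels = np.zeros((h, w), dtype=np.int64)
    for cell in cells:
        mask = _ellipse_mask(cell, (h, w))
        cell_pixels[mask & (cell_pixels == 0)] = cell.label

    stats_cols = ["fragment_id", "cell_label", "shape_class",
                  "centerline_length_px", "width_px"]
    stats = pd.DataFrame(rows, columns=stats_cols)
    return PhantomOutput(
        image=Image2D(img, pixel_size=pixel_size, name=f"phantom_{spec.regime}_s{spec.seed}"),
        truth_mask=BinaryMask(truth, pixel_size=pixel_size, provenance="phantom"),
        cell_mask=LabelMask(cell_pixels, pixel_size=pixel_size),
        truth_fragments=LabelMask(frag_labels, pixel_size=pixel_size),
        truth_stats=stats,
    )


def truth_summary(out: PhantomOutput) -> pd.DataFrame:
    """Per-fragment generating parameters (length, width, shape class)."""
    return out.truth_stats.copy()
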