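"""Synthetic IFISH scenes with exported ground truth.

The generator emulates the image properties that make tissue IFISH hard to
quantify: densely packed elliptical nuclei with touching boundaries,
ring-like membrane staining that may be incomplete (broken arcs), small
high-intensity FISH spots (isolated or, for amplified cells, clustered),
spatially varying background/autofluorescence, and Poisson-Gaussian sensor
noise.  Every scene exports pixel-accurate ground truth (nucleus and cell
label maps, a spot table and per-cell records), so each pipeline stage can
be scored against planted truth without external data.

It deliberately does *not* emulate tissue texture, sectioning artefacts,
out-of-focus light or chromatic shift; results on synthetic scenes bound
what the pipeline can do under controlled conditions, not its performance
on patient material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .io_background import ImageStack

#: half-maximum area of a rendered FISH spot (px); one probe signal
SPOT_AREA = 20.0

#: half-max radius -> Gaussian sigma: r_half = sigma * sqrt(2 ln 2)
_HALF_MAX = math.sqrt(2.0 * math.log(2.0))


def spot_sigma(area: float = SPOT_AREA) -> float:
    """Gaussian sigma whose half-maximum footprint has the given area."""
    return math.sqrt(area / math.pi) / _HALF_MAX


@dataclass
class CellType:
    """One phenotype population: geometry and stain levels."""

    name: str = "cell"
    fraction: float = 1.0
    radius_scale: float = 1.0
    nuclear_level: float = 0.45   # ER-like nuclear stain amplitude
    membrane_level: float = 0.55  # HER2-like ring amplitude


@dataclass
class SceneSpec:
    """Parameters of one synthetic IFISH scene.

    Defaults describe a 40x field: ~50 epithelial nuclei of mean radius
    26 px (area ≈ 2100 px², inside the tool's 250-3000 px working range at
    this magnification), moderate autofluorescence background and shot
    noise typical of FFPE epifluorescence.
    """

    n_cells: int = 50
    height: int = 600
    width: int = 600
    radius_mean: float = 26.0
    radius_sd: float = 3.0
    aspect_min: float = 0.7
    touching_fraction: float = 0.0
    membrane_completeness: float = 1.0
    spots_per_cell: int | tuple[int, int] | None = 4
    amplified_fraction: float = 0.0
    background: str = "constant"   # constant | gradient | field
    background_level: float = 0.10
    background_level_hi: float | None = None
    gaussian_sd: float = 0.01
    poisson: bool = True
    photons: float = 400.0
    magnification: int = 40
    seed: int = 0
    cell_types: list[CellType] = field(default_factory=list)
    dapi_level: float = 0.8
    spot_level: float = 0.8
    territory_scale: float = 1.35

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.membrane_completeness <= 1.0:
            raise ValueError("membrane_completeness must lie in [0, 1]")
        if not self.cell_types:
            self.cell_types = [CellType()]
        total = sum(t.fraction for t in self.cell_types)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("cell-type fractions must sum to 1")


@dataclass
class _Nucleus:
    row: float
    col: float
    a: float          # semi-major (px)
    b: float          # semi-minor (px)
    theta: float
    cell_type: CellType
    label: int = 0


def _elliptical_distance(
    shape: tuple[int, int], nuc: _Nucleus, scale: float = 1.0
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Normalised elliptical distance to a nucleus on its bounding window."""
    a, b = nuc.a * scale, nuc.b * scale
    r = max(a, b) + 2
    r0 = max(0, int(nuc.row - r))
    r1 = min(shape[0], int(nuc.row + r) + 1)
    c0 = max(0, int(nuc.col - r))
    c1 = min(shape[1], int(nuc.col + r) + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy = rows - nuc.row
    dx = cols - nuc.col
    ct, st = math.cos(nuc.theta), math.sin(nuc.theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return d, (slice(r0, r1), slice(c0, c1))


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> list[_Nucleus]:
    """Dart-throwing placement with controlled touching pairs."""
    type_draw = rng.choice(
        len(spec.cell_types),
        size=spec.n_cells,
        p=[t.fraction for t in spec.cell_types],
    )
    n_touch = int(round(spec.touching_fraction * spec.n_cells))
    n_pairs = n_touch // 2
    placed: list[_Nucleus] = []

    def sample_geometry(i: int) -> tuple[float, float, float, CellType]:
        ct = spec.cell_types[type_draw[i]]
        r = max(6.0, rng.normal(spec.radius_mean, spec.radius_sd)) * ct.radius_scale
        aspect = rng.uniform(spec.aspect_min, 1.0)
        a = r / math.sqrt(aspect)
        b = r * math.sqrt(aspect)
        return a, b, rng.uniform(0, math.pi), ct

    def collides(row: float, col: float, rad: float, ignore: int = -1) -> bool:
        for k, n in enumerate(placed):
            if k == ignore:
                continue
            req = rad + max(n.a, n.b) + 4.0
            if (row - n.row) ** 2 + (col - n.col) ** 2 < req**2:
                return True
        return False

    max_tries = 4000
    idx = 0
    for _ in range(n_pairs):
        for attempt in range(max_tries):
            a1, b1, t1, ct1 = sample_geometry(idx)
            a2, b2, t2, ct2 = sample_geometry(idx + 1)
            r1, r2 = max(a1, b1), max(a2, b2)
            margin = r1 + r2 + 4
            row = rng.uniform(margin, spec.height - margin)
            col = rng.uniform(margin, spec.width - margin)
            ang = rng.uniform(0, 2 * math.pi)
            # abutting partner: centres at ~95% of the radius sum
            d = 0.95 * ((a1 + b1) / 2 + (a2 + b2) / 2)
            row2 = row + d * math.sin(ang)
            col2 = col + d * math.cos(ang)
            if collides(row, col, r1) or collides(row2, col2, r2):
                continue
            placed.append(_Nucleus(row, col, a1, b1, t1, ct1))
            placed.append(_Nucleus(row2, col2, a2, b2, t2, ct2))
            idx += 2
            break
        else:
            raise RuntimeError(
                f"cannot place {spec.n_cells} nuclei; achieved {len(placed)}"
            )
    while idx < spec.n_cells:
        for attempt in range(max_tries):
            a, b, t, ct = sample_geometry(idx)
            r = max(a, b)
            row = rng.uniform(r + 2, spec.height - r - 2)
            col = rng.uniform(r + 2, spec.width - r - 2)
            if collides(row, col, r):
                continue
            placed.append(_Nucleus(row, col, a, b, t, ct))
            idx += 1
            break
        else:
            raise RuntimeError(
                f"cannot place {spec.n_cells} nuclei; achieved {len(placed)}"
            )
    for i, n in enumerate(placed, start=1):
        n.label = i
    return placed


def _background_field(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    lvl = spec.background_level
    if spec.background == "constant":
        return np.full((spec.height, spec.width), lvl)
    if spec.background == "gradient":
        hi = spec.background_level_hi
        if hi is None:
            hi = 2.0 * lvl
        ramp = np.linspace(lvl, hi, spec.width)
        return np.tile(ramp, (spec.height, 1))
    if spec.background == "field":
        noise = rng.normal(0.0, 1.0, (spec.height, spec.width))
        smooth = ndi.gaussian_filter(noise, sigma=min(spec.height, spec.width) / 8)
        smooth = (smooth - smooth.min()) / max(float(np.ptp(smooth)), 1e-12)
        return lvl * (0.5 + smooth)
    raise ValueError(f"unknown background model {spec.background!r}")


def _apply_noise(
    img: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    out = img
    if spec.poisson:
        out = rng.poisson(np.clip(out, 0, None) * spec.photons) / spec.photons
    if spec.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


def _sample_spot_count(
    spec: SceneSpec, rng: np.random.Generator
) -> int:
    s = spec.spots_per_cell
    if s is None:
        return 0
    if isinstance(s, tuple):
        return int(rng.integers(s[0], s[1] + 1))
    return int(s)


def _place_spots_in_nucleus(
    nuc: _Nucleus, k: int, rng: np.random.Generator, min_sep: float
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    ct, st = math.cos(nuc.theta), math.sin(nuc.theta)
    inner_a = max(2.0, nuc.a - 4.0)
    inner_b = max(2.0, nuc.b - 4.0)
    for _ in range(2000):
        if len(pts) == k:
            break
        # uniform in the eroded ellipse
        u = rng.uniform(-1, 1)
        v = rng.uniform(-1, 1)
        if u * u + v * v > 1:
            continue
        dx = u * inner_a * ct - v * inner_b * st
        dy = u * inner_a * st + v * inner_b * ct
        r, c = nuc.row + dy, nuc.col + dx
        if all((r - p[0]) ** 2 + (c - p[1]) ** 2 >= min_sep**2 for p in pts):
            pts.append((r, c))
    if len(pts) < k:
        raise RuntimeError(f"cannot place {k} spots in nucleus {nuc.label}")
    return pts


def generate_scene(spec: SceneSpec):
    """Render one scene and its ground truth.

    Returns
    -------
    stack : ImageStack
        Channels DAPI, ER (nuclear), HER2 (membrane), HER2-FISH (spots).
    nuclei : ndarray
        Ground-truth nucleus label map.
    cells : ndarray
        Ground-truth cell-territory label map (same labels as nuclei).
    spots : pandas.DataFrame
        One row per planted signal: cell, row, col, area, amplified.
    records : pandas.DataFrame
        One row per cell: label, centroid, geometry, type, planted stain
        levels, true copy number (22 codes an amplified cluster).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    nuclei_map = np.zeros(shape, dtype=np.int32)
    best_d = np.full(shape, np.inf)

    if spec.n_cells == 0:
        bg = _background_field(spec, rng)
        channels = [
            _apply_noise(bg * f, spec, rng) for f in (0.5, 1.0, 1.0, 0.5)
        ]
        stack = ImageStack(
            channels=channels,
            stains=["DAPI", "nuclear", "membrane", "spot"],
            magnification=spec.magnification,
            names=["DAPI", "ER", "HER2", "HER2-FISH"],
        )
        empty_spots = pd.DataFrame(
            columns=["cell", "row", "col", "area", "amplified"]
        )
        empty_cells = pd.DataFrame(
            columns=[
                "label", "row", "col", "area", "cell_type",
                "nuclear_level", "membrane_level", "copies", "completeness",
            ]
        )
        return stack, nuclei_map, nuclei_map.copy(), empty_spots, empty_cells

    nuclei = _place_nuclei(spec, rng)

    # --- label maps: pixel goes to the nucleus with the smallest
    # normalised elliptical distance (resolves abutting-pair overlaps)
    for nuc in nuclei:
        d, win = _elliptical_distance(shape, nuc)
        inside = d <= 1.0
        closer = inside & (d < best_d[win])
        nuclei_map[win][closer] = nuc.label
        best_d[win][closer] = d[closer]

    cells_map = np.zeros(shape, dtype=np.int32)
    best_d_cell = np.full(shape, np.inf)
    for nuc in nuclei:
        d, win = _elliptical_distance(shape, nuc, scale=spec.territory_scale)
        inside = d <= 1.0
        closer = inside & (d < best_d_cell[win])
        cells_map[win][closer] = nuc.label
        best_d_cell[win][closer] = d[closer]

    # --- DAPI: per-nucleus dome (peak at centre, saddle between partners)
    dapi = np.zeros(shape)
    peaks = rng.uniform(0.75, 1.0, len(nuclei)) * spec.dapi_level
    for nuc, peak in zip(nuclei, peaks):
        d, win = _elliptical_distance(shape, nuc)
        dome = np.where(d <= 1.0, peak * (1.0 - 0.6 * d**2), 0.0)
        np.maximum(dapi[win], dome, out=dapi[win])

    # --- ER-like nuclear stain: flat per-cell level inside the nucleus
    er = np.zeros(shape)
    for nuc in nuclei:
        er[nuclei_map == nuc.label] = nuc.cell_type.nuclear_level

    # --- HER2-like membrane ring with arc completeness
    her2 = np.zeros(shape)
    ring_lo, ring_hi = 0.92, 1.08
    completeness: dict[int, float] = {}
    for nuc in nuclei:
        c = spec.membrane_completeness
        completeness[nuc.label] = c
        if c <= 0:
            continue
        d, win = _elliptical_distance(shape, nuc, scale=spec.territory_scale)
        band = (d >= ring_lo) & (d <= ring_hi) & (cells_map[win] == nuc.label)
        if c < 1.0:
            rows, cols = np.mgrid[win[0], win[1]]
            ang = np.arctan2(rows - nuc.row, cols - nuc.col)
            gap_total = (1.0 - c) * 2 * math.pi
            n_gaps = int(rng.integers(1, 4))
            cuts = rng.uniform(-math.pi, math.pi, n_gaps)
            widths = rng.dirichlet(np.ones(n_gaps)) * gap_total
            keep = np.ones_like(ang, dtype=bool)
            for cut, w in zip(cuts, widths):
                diff = np.angle(np.exp(1j * (ang - cut)))
                keep &= np.abs(diff) > w / 2
            band &= keep
        her2[win][band] = np.maximum(
            her2[win][band], nuc.cell_type.membrane_level
        )

    # --- FISH spots
    fish = np.zeros(shape)
    sigma = spot_sigma(SPOT_AREA)
    r_half = sigma * _HALF_MAX
    spot_rows = []
    copies: dict[int, int] = {}
    amp_draw = rng.uniform(size=len(nuclei)) < spec.amplified_fraction

    def render_gaussian(row: float, col: float, amp: float, sig: float) -> None:
        r = int(math.ceil(4 * sig))
        r0, r1 = max(0, int(row) - r), min(shape[0], int(row) + r + 1)
        c0, c1 = max(0, int(col) - r), min(shape[1], int(col) + r + 1)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        g = amp * np.exp(-(((rows - row) ** 2 + (cols - col) ** 2) / (2 * sig**2)))
        np.maximum(fish[r0:r1, c0:c1], g, out=fish[r0:r1, c0:c1])

    for nuc, amplified in zip(nuclei, amp_draw):
        if amplified:
            # contiguous cluster: one broad blob whose half-max area
            # exceeds the countability plateau (~400 px)
            cluster_area = rng.uniform(450.0, 600.0)
            sig_c = spot_sigma(cluster_area)
            render_gaussian(nuc.row, nuc.col, spec.spot_level, sig_c)
            copies[nuc.label] = 22
            spot_rows.append(
                dict(cell=nuc.label, row=nuc.row, col=nuc.col,
                     area=cluster_area, amplified=True)
            )
            continue
        k = _sample_spot_count(spec, rng)
        copies[nuc.label] = k
        if k == 0:
            continue
        pts = _place_spots_in_nucleus(nuc, k, rng, min_sep=2 * r_half + 3.0)
        for r, c in pts:
            render_gaussian(r, c, spec.spot_level, sigma)
            spot_rows.append(
                dict(cell=nuc.label, row=r, col=c, area=SPOT_AREA,
                     amplified=False)
            )

    # --- composite with background and sensor noise
    bg = _background_field(spec, rng)
    channels = [
        _apply_noise(dapi + 0.5 * bg, spec, rng),
        _apply_noise(er + bg, spec, rng),
        _apply_noise(her2 + bg, spec, rng),
        _apply_noise(fish + 0.5 * bg, spec, rng),
    ]
    stack = ImageStack(
        channels=channels,
        stains=["DAPI", "nuclear", "membrane", "spot"],
        magnification=spec.magnification,
        names=["DAPI", "ER", "HER2", "HER2-FISH"],
    )

    spots_df = pd.DataFrame(
        spot_rows, columns=["cell", "row", "col", "area", "amplified"]
    )
    records = pd.DataFrame(
        [
            dict(
                label=nuc.label,
                row=nuc.row,
                col=nuc.col,
                area=float((nuclei_map == nuc.label).sum()),
                cell_type=nuc.cell_type.name,
                nuclear_level=nuc.cell_type.nuclear_level,
                membrane_level=nuc.cell_type.membrane_level,
                copies=copies.get(nuc.label, 0),
                completeness=completeness.get(nuc.label, 1.0),
            )
            for nuc in nuclei
        ]
    )
    return stack, nuclei_map, cells_map, spots_df, records


# ---------------------------------------------------------------------------
# synthetic fragment training sets for the linear classifiers
# ---------------------------------------------------------------------------


def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    r = int(math.ceil(max(a, b))) + 2
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _features_of_mask(
    mask: np.ndarray, theoretical_area: float, theoretical_perimeter: float
) -> np.ndarray:
    from .nuclear_seg import fragment_features

    lab = mask.astype(np.uint8)
    region = measure.regionprops(lab)[0]
    return fragment_features(region, theoretical_area, theoretical_perimeter)


def generate_fragments(
    n: int,
    seed: int = 0,
    *,
    kind: str = "nuclear",
    theoretical_area: float = 5000.0,
    theoretical_perimeter: float | None = None,
):
    """Labelled synthetic fragments for training the linear classifiers.

    ``kind="nuclear"`` yields optimal / undersegmented / oversegmented
    watershed-fragment archetypes (single ellipses, abutting or fused
    pairs, chord-cut pieces); ``kind="spot"`` yields optimal / too_small /
    too_large spot archetypes with the two intensity features appended.
    Classes are balanced (n need not be divisible by the class count; the
    remainder goes to the first classes).

    Returns ``(X, y)``: feature matrix and class-label list.
    """
    if theoretical_perimeter is None:
        theoretical_perimeter = 2.0 * math.sqrt(math.pi * theoretical_area)
    rng = np.random.default_rng(seed)
    if kind == "nuclear":
        classes = ("optimal", "undersegmented", "oversegmented")
    elif kind == "spot":
        classes = ("optimal", "too_small", "too_large")
    else:
        raise ValueError(f"unknown fragment kind {kind!r}")
    if n < len(classes):
        raise ValueError(f"need at least {len(classes)} fragments")
    counts = [n // len(classes)] * len(classes)
    for i in range(n % len(classes)):
        counts[i] += 1

    X: list[np.ndarray] = []
    y: list[str] = []
    r_ref = math.sqrt(theoretical_area / math.pi)

    def ellipse(area_factor: float) -> np.ndarray:
        aspect = rng.uniform(0.6, 1.0)
        r = r_ref * math.sqrt(area_factor)
        a = r / math.sqrt(aspect)
        b = r * math.sqrt(aspect)
        return _ellipse_mask(a, b, rng.uniform(0, math.pi))

    if kind == "nuclear":
        for cls, m in zip(classes, counts):
            for _ in range(m):
                if cls == "optimal":
                    mask = ellipse(rng.uniform(0.5, 1.6))
                elif cls == "undersegmented":
                    # fused pair: two ellipses at 60-95% separation
                    m1 = ellipse(rng.uniform(0.6, 1.2))
                    m2 = ellipse(rng.uniform(0.6, 1.2))
                    h = max(m1.shape[0], m2.shape[0])
                    w1, w2 = m1.shape[1], m2.shape[1]
                    sep = rng.uniform(0.6, 0.95)
                    off = int(sep * (w1 + w2) / 2)
                    W = w1 + off + w2
                    canvas = np.zeros((h + 2, W), dtype=bool)
                    canvas[: m1.shape[0], :w1] |= m1
                    canvas[: m2.shape[0], off : off + w2] |= m2
                    lab, nlab = ndi.label(canvas)
                    if nlab != 1:  # pieces did not fuse; retry as overlap
                        canvas = np.zeros((h + 2, w1 + w2), dtype=bool)
                        canvas[: m1.shape[0], :w1] |= m1
                        canvas[: m2.shape[0], w1 // 2 : w1 // 2 + w2] |= m2
                    mask = canvas
                else:  # oversegmented: chord-cut piece of an ellipse
                    full = ellipse(rng.uniform(0.8, 1.4))
                    frac = rng.uniform(0.15, 0.55)
                    cols = np.cumsum(full.sum(axis=0)) / max(full.sum(), 1)
                    cut = int(np.searchsorted(cols, frac))
                    piece = full.copy()
                    piece[:, cut:] = False
                    lab, nlab = ndi.label(piece)
                    if nlab > 1:
                        sizes = ndi.sum(piece, lab, range(1, nlab + 1))
                        piece = lab == (1 + int(np.argmax(sizes)))
                    mask = piece
                if not mask.any():
                    mask = ellipse(0.3)
                X.append(
                    _features_of_mask(mask, theoretical_area, theoretical_perimeter)
                )
                y.append(cls)
        return np.array(X), y

    # spot fragments: features are the 10 morphology values plus mean and
    # minimum intensity inside the candidate footprint
    from .spot_detect import SPOT_FEATURES  # noqa: F401  (feature order)

    for cls, m in zip(classes, counts):
        for _ in range(m):
            if cls == "optimal":
                mask = ellipse(rng.uniform(0.7, 1.5))
                mean_i, min_i = rng.uniform(0.5, 0.9), rng.uniform(0.3, 0.5)
            elif cls == "too_small":
                mask = ellipse(rng.uniform(0.05, 0.4))
                mean_i, min_i = rng.uniform(0.2, 0.6), rng.uniform(0.1, 0.4)
            else:  # too_large: elongated smear
                aspect = rng.uniform(0.15, 0.4)
                r = r_ref * math.sqrt(rng.uniform(3.0, 8.0))
                mask = _ellipse_mask(
                    r / math.sqrt(aspect), r * math.sqrt(aspect),
                    rng.uniform(0, math.pi),
                )
                mean_i, min_i = rng.uniform(0.2, 0.7), rng.uniform(0.05, 0.3)
            feats = _features_of_mask(
                mask, theoretical_area, theoretical_perimeter
            )
            X.append(np.concatenate([feats, [mean_i, min_i]]))
            y.append(cls)
    return np.array(X), y
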