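"""Nuclear segmentation from the DAPI channel.

The segmentation strategy is an *iterative* H-minima watershed: the DAPI
image is inverted, regional minima shallower than a depth ``h`` are
suppressed, and a watershed is flooded inside a foreground mask.  A large
``h`` under-fragments (touching nuclei merge), a small ``h``
over-fragments; instead of picking one depth, the algorithm sweeps a ladder
of depths from deep to shallow, and after each sweep a linear discriminant
classifier triages every fragment into *optimal*, *undersegmented* or
*oversegmented* from ten morphological properties.  Optimal fragments are
frozen into the output and removed from the working mask; the remainder is
re-segmented at the next (shallower) depth, which splits merged clumps.

Residual oversegmentation is then repaired by a combinatorial merger: for
an oversegmented fragment ``f`` with neighbours ``g = {g1..gN}`` within a
radius ``r``, every union ``c = f ∪ (subset of g)`` is scored by

    S(c) = sum over features F of [ F(c) - mean_i F(c_i) ]

with F ∈ {solidity, negated relative deviation from the expected nucleus
area}; the union with the best strictly positive score replaces its parts,
otherwise ``f`` is kept.  A merge is accepted only when the whole looks
more like a single nucleus than its pieces do on average.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation, util
from skimage.filters import rank
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

log = logging.getLogger(__name__)

QUALITY_CLASSES = ("optimal", "undersegmented", "oversegmented")

#: feature order of the 10-vector used by the fragment classifier
FRAGMENT_FEATURES = (
    "solidity",
    "area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "axis_ratio",
    "circularity",
    "area_perimeter_ratio",
    "dev_theoretical_area",
    "dev_theoretical_perimeter",
)

# Expected nucleus geometry at 60x: the optimal working range is
# 2500-10000 px^2, summarised by its geometric mean; 20x/40x scale with the
# square of the magnification ratio.
THEORETICAL_AREA_60X = 5000.0


def theoretical_area(magnification: int) -> float:
    return THEORETICAL_AREA_60X * (magnification / 60.0) ** 2


def theoretical_perimeter(magnification: int) -> float:
    # circle-equivalent perimeter of the expected area
    return 2.0 * math.sqrt(math.pi * theoretical_area(magnification))


@dataclass
class SegParams:
    """Tunable parameters of the iterative nuclear segmentation."""

    h_min_fraction: float = 0.10
    h_max_fraction: float = 0.30
    n_depth_steps: int = 5
    min_fragment_area: int = 500
    theoretical_area: float = THEORETICAL_AREA_60X
    theoretical_perimeter: float = 2.0 * math.sqrt(math.pi * THEORETICAL_AREA_60X)
    merge_radius: float = 5.0
    entropy_radius: int = 4
    magnification: int = 60

    def __post_init__(self) -> None:
        if not 0 < self.h_min_fraction < self.h_max_fraction < 1:
            raise ValueError("need 0 < h_min_fraction < h_max_fraction < 1")
        if self.min_fragment_area <= 0:
            raise ValueError("min_fragment_area must be positive")

    @classmethod
    def for_magnification(cls, magnification: int, **overrides) -> "SegParams":
        """Defaults scaled from the 60x reference geometry."""
        scale = (magnification / 60.0) ** 2
        base = dict(
            min_fragment_area=max(25, int(round(500 * scale))),
            theoretical_area=theoretical_area(magnification),
            theoretical_perimeter=theoretical_perimeter(magnification),
            magnification=magnification,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Fragment:
    """One labelled region with its morphological feature vector."""

    label: int
    features: np.ndarray
    quality: str | None = None
    area: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)


def fragment_features(
    region, theoretical_area: float, theoretical_perimeter: float
) -> np.ndarray:
    """Ten morphological properties of one ``regionprops`` region.

    Deviations from the expected nucleus area/perimeter are expressed
    relative to the expected value, so feature scales are comparable across
    magnifications.
    """
    area = float(region.area)
    perimeter = float(max(region.perimeter, 1.0))
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    axis_ratio = minor / major if major > 0 else 1.0
    circularity = 4.0 * math.pi * area / perimeter**2
    return np.array(
        [
            float(region.solidity),
            area,
            perimeter,
            major,
            minor,
            axis_ratio,
            circularity,
            area / perimeter,
            (area - theoretical_area) / theoretical_area,
            (perimeter - theoretical_perimeter) / theoretical_perimeter,
        ]
    )


@lru_cache(maxsize=8)
def default_fragment_model(
    theoretical_area: float = THEORETICAL_AREA_60X,
    theoretical_perimeter: float | None = None,
) -> LinearDiscriminantAnalysis:
    """Shipped fragment-quality classifier.

    A linear discriminant trained on a deterministic synthetic fragment set
    (153 fragments, balanced over the three quality classes) generated at
    the requested nucleus scale.  Retrain with
    :func:`train_fragment_classifier` for other data.
    """
    from . import synth

    if theoretical_perimeter is None:
        theoretical_perimeter = 2.0 * math.sqrt(math.pi * theoretical_area)
    X, y = synth.generate_fragments(
        153,
        seed=0,
        theoretical_area=theoretical_area,
        theoretical_perimeter=theoretical_perimeter,
    )
    return train_fragment_classifier(X, y)


def train_fragment_classifier(X: np.ndarray, y) -> LinearDiscriminantAnalysis:
    """Fit the linear (LDA) fragment-quality classifier."""
    model = LinearDiscriminantAnalysis()
    model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model


def classify_fragment(features: np.ndarray, model=None) -> str:
    """Classify a 10-feature fragment as optimal/under-/oversegmented."""
    features = np.asarray(features, dtype=float)
    if features.shape != (len(FRAGMENT_FEATURES),):
        raise ValueError(f"expected {len(FRAGMENT_FEATURES)} features")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite fragment features")
    if model is None:
        model = default_fragment_model()
    return str(model.predict(features[None, :])[0])


def foreground_mask(dapi: np.ndarray, entropy_radius: int = 4) -> np.ndarray:
    """Cellular-foreground mask from combined local entropy and intensity.

    Both the local-entropy image (disk neighbourhood) and the intensity
    image are min-max normalised to [0, 1] and summed; Otsu's threshold on
    the combined image separates tissue from background.
    """
    dapi = np.asarray(dapi)
    if dapi.max() == dapi.min():
        warnings.warn("constant DAPI image: empty foreground", stacklevel=2)
        return np.zeros(dapi.shape, dtype=bool)
    norm = (dapi.astype(np.float64) - dapi.min()) / (dapi.max() - dapi.min())
    ent = rank.entropy(
        util.img_as_ubyte(norm), footprint=morphology.disk(entropy_radius)
    ).astype(np.float64)
    if ent.max() > ent.min():
        ent = (ent - ent.min()) / (ent.max() - ent.min())
    combined = norm + ent
    thr = filters.threshold_otsu(combined)
    mask = combined > thr
    return morphology.remove_small_holes(mask, max_size=64)


def _suppress_minima(inverted: np.ndarray, depth: float) -> np.ndarray:
    """H-minima transform: fill regional minima shallower than ``depth``."""
    seed = inverted + depth
    return morphology.reconstruction(seed, inverted, method="erosion")


def hminima_watershed(
    dapi: np.ndarray, mask: np.ndarray, depth: float
) -> np.ndarray:
    """Watershed of the inverted DAPI image after H-minima suppression.

    ``depth`` is an absolute intensity depth: basins shallower than it are
    suppressed, so they do not seed separate objects.  Labels are positive
    consecutive integers inside ``mask``; 0 elsewhere.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    dapi = np.asarray(dapi, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    inverted = dapi.max() - dapi
    filled = _suppress_minima(inverted, float(depth))
    markers, _ = ndi.label(
        morphology.local_minima(filled, connectivity=2) & mask,
        structure=np.ones((3, 3)),
    )
    labels = segmentation.watershed(filled, markers=markers, mask=mask)
    return relabel_consecutive(labels)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..n preserving order; 0 stays background."""
    labels = np.asarray(labels)
    out, _, _ = segmentation.relabel_sequential(labels)
    return out.astype(np.int32)


def measure_fragments(labels: np.ndarray, params: SegParams) -> list[Fragment]:
    frags = []
    for region in measure.regionprops(labels):
        feats = fragment_features(
            region, params.theoretical_area, params.theoretical_perimeter
        )
        frags.append(
            Fragment(
                label=int(region.label),
                features=feats,
                area=float(region.area),
                centroid=tuple(region.centroid),
            )
        )
    return frags


def iterative_segment(
    dapi: np.ndarray,
    params: SegParams | None = None,
    *,
    mask: np.ndarray | None = None,
    model=None,
) -> np.ndarray:
    """Segment nuclei by an iterative H-minima watershed with LDA triage.

    The suppression depth steps down a linear ladder from
    ``h_max_fraction`` to ``h_min_fraction`` of the foreground dynamic
    range (``n_depth_steps`` rungs).  At each depth, fragments classified
    *optimal* are frozen into the output and removed from the working mask;
    at the final depth all remaining large-enough fragments are kept.  The
    pooled result is passed through :func:`merge_oversegmented`, and
    fragments below ``min_fragment_area`` are discarded.

    Because depths are fractions of the dynamic range, the output is
    invariant to affine rescaling of the image intensities.
    """
    if params is None:
        params = SegParams()
    dapi = np.asarray(dapi, dtype=np.float64)
    if mask is None:
        mask = foreground_mask(dapi, params.entropy_radius)
    work = mask.copy()
    if model is None and work.any():
        model = default_fragment_model(
            params.theoretical_area, params.theoretical_perimeter
        )

    out = np.zeros(dapi.shape, dtype=np.int32)
    next_label = 1
    if not work.any():
        return out
    dyn_range = float(dapi[mask].max() - dapi[mask].min())
    if dyn_range <= 0:
        return out
    depths = np.linspace(
        params.h_max_fraction, params.h_min_fraction, params.n_depth_steps
    )

    quality: dict[int, str] = {}
    for step, frac in enumerate(depths):
        if not work.any():
            break
        labels = hminima_watershed(dapi, work, depth=float(frac) * dyn_range)
        if labels.max() == 0:
            continue
        last = step == len(depths) - 1
        # specks far below the size cut never survive; drop them before
        # classification, but keep mid-sized slivers as merge material
        floor = max(16, params.min_fragment_area // 8)
        for frag in measure_fragments(labels, params):
            if frag.area < (floor if last else params.min_fragment_area):
                continue
            q = classify_fragment(frag.features, model)
            if q == "optimal" or last:
                region = labels == frag.label
                out[region] = next_label
                quality[next_label] = q
                next_label += 1
                if not last:
                    work &= ~region

    out = merge_oversegmented(out, quality, params.merge_radius, params)
    # post-merge size filter
    for region in measure.regionprops(out):
        if region.area < params.min_fragment_area:
            out[out == region.label] = 0
    return relabel_consecutive(out)


# ---------------------------------------------------------------------------
# oversegmentation merger
# ---------------------------------------------------------------------------

#: beyond this many neighbours exhaustive subset scoring is replaced by
#: greedy pairwise merging with the same score
MAX_EXHAUSTIVE_NEIGHBOURS = 8


def _merge_features(mask: np.ndarray, params: SegParams) -> tuple[float, float]:
    """(solidity, negated relative area deviation) of one candidate union."""
    # a union of disjoint fragments may be disconnected; measured as one object
    area = float(mask.sum())
    hull = morphology.convex_hull_image(mask)
    solidity = area / float(hull.sum()) if hull.any() else 0.0
    dev = -abs(area - params.theoretical_area) / params.theoretical_area
    return solidity, dev


def score_union(
    member_masks: list[np.ndarray], params: SegParams
) -> float:
    """Morphological merge score of a candidate union.

    For each feature F (solidity; negated relative deviation from the
    expected area) the score adds F(union) minus the mean of F over the
    ``n`` constituent fragments.  Positive means the union is more
    nucleus-like than its parts are on average.
    """
    union = np.zeros_like(member_masks[0], dtype=bool)
    for m in member_masks:
        union |= m
    fu = _merge_features(union, params)
    parts = [_merge_features(m, params) for m in member_masks]
    n = len(member_masks)
    return sum(fu[k] - sum(p[k] for p in parts) / n for k in range(len(fu)))


def _boundary_distance_neighbours(
    labels: np.ndarray, radius: float
) -> dict[int, set[int]]:
    """Labels whose boundaries lie within ``radius`` px of each other."""
    out: dict[int, set[int]] = {}
    ids = [int(v) for v in np.unique(labels) if v > 0]
    for lab in ids:
        mask = labels == lab
        grown = morphology.dilation(
            mask, morphology.disk(max(1, int(math.ceil(radius))))
        )
        near = set(int(v) for v in np.unique(labels[grown]) if v not in (0, lab))
        out[lab] = near
    return out


def merge_oversegmented(
    labels: np.ndarray,
    quality: dict[int, str],
    r: float,
    params: SegParams,
) -> np.ndarray:
    """Repair oversegmentation by exhaustive subset scoring.

    Every fragment classified *oversegmented* is considered with each
    subset of its neighbours within radius ``r``; the union with the
    maximal strictly positive :func:`score_union` replaces its members.
    Ties break toward fewer merged fragments, then lowest subset index,
    so the result is deterministic.  With more than
    ``MAX_EXHAUSTIVE_NEIGHBOURS`` neighbours, greedy pairwise merging with
    the same score is used instead.
    """
    labels = labels.copy()
    over = [lab for lab, q in quality.items() if q == "oversegmented"]
    if not over:
        return labels
    neighbours = _boundary_distance_neighbours(labels, r)
    merged_away: set[int] = set()

    for f in sorted(over):
        if f in merged_away or f not in neighbours:
            continue
        gs = sorted(g for g in neighbours.get(f, ()) if g not in merged_away)
        if not gs:
            continue
        f_mask = labels == f
        g_masks = {g: labels == g for g in gs}

        if len(gs) <= MAX_EXHAUSTIVE_NEIGHBOURS:
            # subsets enumerated by increasing size then lexical order, and a
            # strictly-better score required to switch: ties resolve to the
            # smallest union first encountered, deterministically
            best_score, best_subset = 0.0, ()
            for size in range(1, len(gs) + 1):
                for subset in combinations(gs, size):
                    masks = [f_mask] + [g_masks[g] for g in subset]
                    s = score_union(masks, params)
                    if s > best_score:
                        best_score, best_subset = s, subset
            chosen = best_subset if best_score > 0 else ()
        else:
            # greedy: repeatedly absorb the single neighbour with the best
            # positive pairwise score
            chosen_set: set[int] = set()
            current = [f_mask]
            remaining = list(gs)
            while remaining:
                scored = [
                    (score_union(current + [g_masks[g]], params), g)
                    for g in remaining
                ]
                s, g = max(scored)
                if s <= 0:
                    break
                chosen_set.add(g)
                current.append(g_masks[g])
                remaining.remove(g)
            chosen = tuple(sorted(chosen_set))

        for g in chosen:
            labels[g_masks[g]] = f
            merged_away.add(g)
            quality[g] = "optimal"
        if chosen:
            quality[f] = "optimal"
    return relabel_consecutive(labels)


def seeded_watershed(
    dapi: np.ndarray,
    seeds: list[tuple[int, int]],
    *,
    mask: np.ndarray | None = None,
    depth_fraction: float = 0.1,
) -> np.ndarray:
    """Marker-controlled H-minima watershed from user-supplied seed points.

    Intended for images with few cells or poor contrast: one label per
    seed, each seed inside its own label.  Seeds falling in one basin after
    H-minima suppression would merge; duplicate seed coordinates are merged
    with a warning.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if not seeds:
        raise ValueError("at least one seed required")
    pts = []
    seen = set()
    for r, c in seeds:
        r, c = int(r), int(c)
        if not (0 <= r < dapi.shape[0] and 0 <= c < dapi.shape[1]):
            raise ValueError(f"seed ({r}, {c}) outside image")
        if (r, c) in seen:
            warnings.warn(f"duplicate seed ({r}, {c}) merged", stacklevel=2)
            continue
        seen.add((r, c))
        pts.append((r, c))
    if mask is None:
        mask = np.ones(dapi.shape, dtype=bool)
    inverted = dapi.max() - dapi
    dyn = float(inverted.max() - inverted.min())
    filled = _suppress_minima(inverted, depth_fraction * dyn) if dyn > 0 else inverted
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(pts, start=1):
        markers[r, c] = i
    labels = segmentation.watershed(filled, markers=markers, mask=mask)
    return relabel_consecutive(labels)
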