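"""Parameter-file-driven batch processing with resumable bundles.

Each input image is processed end-to-end with the default pipeline
(preprocessing, nuclear segmentation, membrane territories, spot
detection, per-cell measurement) and the results saved as a *bundle*: a
directory holding the label maps as 16-bit TIFFs, the spot and cell
tables as CSV, and a JSON manifest recording every parameter actually
used.  Bundles make runs resumable (existing bundles are skipped unless
forced) and are a pure function of the inputs and the parameter file.

Images larger than a pixel budget are sectioned into overlapping tiles
segmented independently; duplicate objects in overlaps are resolved by
larger-area precedence when the tiles are stitched.
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cell_features, io_background, membrane_seg, nuclear_seg, spot_detect

log = logging.getLogger(__name__)


@dataclass
class ParameterFile:
    """Schema-validated batch configuration (YAML/JSON)."""

    input_glob: str
    stains: list[str]
    magnification: int = 60
    names: list[str] | None = None
    output_dir: str = "ifish_out"
    saturation_fraction: float = 0.01
    ring_inner: int = 2
    ring_outer: int = 6
    background_mask: str | None = None
    seg: dict = field(default_factory=dict)
    spots: dict = field(default_factory=dict)
    membrane: dict = field(default_factory=dict)
    thresholds: list[dict] = field(default_factory=list)
    max_pixels: int = 12_000_000
    tile_overlap: float = 0.10
    use_spot_classifier: bool = False

    def __post_init__(self) -> None:
        if not self.stains:
            raise ValueError("stains must be given")
        if self.stains.count("DAPI") != 1:
            raise ValueError("exactly one DAPI stain required")
        if self.names is not None and len(self.names) != len(self.stains):
            raise ValueError("names must match stains")
        if self.max_pixels <= 0:
            raise ValueError("max_pixels must be positive")
        if not 0 <= self.tile_overlap < 0.5:
            raise ValueError("tile_overlap must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterFile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def seg_params(self) -> nuclear_seg.SegParams:
        return nuclear_seg.SegParams.for_magnification(
            self.magnification, **self.seg
        )

    def spot_params(self) -> spot_detect.SpotParams:
        return spot_detect.SpotParams.for_magnification(
            self.magnification, **self.spots
        )


def tile_image(
    stack: io_background.ImageStack,
    max_pixels: int,
    overlap: float = 0.10,
):
    """Section a stack into overlapping tiles of at most ``max_pixels``.

    Returns ``(tiles, plan)`` where each tile is an
    ``(ImageStack, (row_offset, col_offset))`` pair and the plan records
    the grid; the tile pixel union covers the frame exactly.
    """
    if max_pixels <= 0:
        raise ValueError("max_pixels must be positive")
    h, w = stack.shape
    if h * w <= max_pixels:
        return (
            [(stack, (0, 0))],
            dict(grid=(1, 1), tile_shape=(h, w), overlap=0),
        )
    # near-square grid with the fewest tiles that fits the budget
    n_tiles = int(np.ceil(h * w / max_pixels))
    n_rows = max(1, int(round(np.sqrt(n_tiles * h / w))))
    n_cols = int(np.ceil(n_tiles / n_rows))
    while True:
        th = int(np.ceil(h / n_rows))
        tw = int(np.ceil(w / n_cols))
        ov_r = int(round(overlap * th))
        ov_c = int(round(overlap * tw))
        if (th + 2 * ov_r) * (tw + 2 * ov_c) <= max_pixels:
            break
        if th >= tw:
            n_rows += 1
        else:
            n_cols += 1
    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            r0 = max(0, i * th - ov_r)
            r1 = min(h, (i + 1) * th + ov_r)
            c0 = max(0, j * tw - ov_c)
            c1 = min(w, (j + 1) * tw + ov_c)
            sub = io_background.ImageStack(
                channels=[c[r0:r1, c0:c1] for c in stack.channels],
                stains=list(stack.stains),
                magnification=stack.magnification,
                names=list(stack.names),
            )
            tiles.append((sub, (r0, c0)))
    return tiles, dict(
        grid=(n_rows, n_cols), tile_shape=(th, tw), overlap=(ov_r, ov_c)
    )


def stitch_labels(
    pieces: list[tuple[np.ndarray, tuple[int, int]]], shape: tuple[int, int]
) -> np.ndarray:
    """Merge tile label maps; duplicates resolved by larger-area precedence.

    Objects from different tiles that overlap in the frame are considered
    duplicate detections of one cell; the larger object wins and the
    smaller is discarded entirely.
    """
    canvas = np.zeros(shape, dtype=np.int32)
    area_of: dict[int, int] = {}
    next_label = 0
    for labels, (r0, c0) in pieces:
        labels = np.asarray(labels)
        h, w = labels.shape
        window = (slice(r0, r0 + h), slice(c0, c0 + w))
        for lab in np.unique(labels):
            if lab == 0:
                continue
            obj = labels == lab
            area = int(obj.sum())
            existing = np.unique(canvas[window][obj])
            existing = existing[existing > 0]
            losers = [e for e in existing if area_of[int(e)] < area]
            winners = [e for e in existing if area_of[int(e)] >= area]
            if winners:
                continue  # a bigger (or equal) earlier object claims this cell
            for e in losers:
                canvas[canvas == e] = 0
                area_of.pop(int(e), None)
            next_label += 1
            view = canvas[window]
            view[obj & (view == 0)] = next_label
            area_of[next_label] = int((canvas == next_label).sum())
    return nuclear_seg.relabel_consecutive(canvas)


def process_image(
    stack: io_background.ImageStack, params: ParameterFile
) -> dict:
    """Run the default pipeline on one stack; returns the result bundle."""
    seg_params = params.seg_params()
    spot_params = params.spot_params()

    h, w = stack.shape
    if h * w > params.max_pixels:
        tiles, _ = tile_image(stack, params.max_pixels, params.tile_overlap)
        pieces = []
        for sub, offset in tiles:
            lab = nuclear_seg.iterative_segment(sub.dapi, seg_params)
            pieces.append((lab, offset))
        nuclei = stitch_labels(pieces, stack.shape)
    else:
        nuclei = nuclear_seg.iterative_segment(stack.dapi, seg_params)

    membranes = None
    if "membrane" in stack.stains and nuclei.max() > 0:
        mem_channel = stack.channels[stack.stains.index("membrane")]
        membranes = membrane_seg.membrane_segment(
            mem_channel,
            nuclei,
            barrier_percentile=params.membrane.get("barrier_percentile", 95.0),
        )
        refine_iters = int(params.membrane.get("refine_iterations", 0))
        if refine_iters:
            membranes = membrane_seg.refine_contours(
                membranes,
                mem_channel,
                method=params.membrane.get("refine_method", "chan_vese"),
                iterations=refine_iters,
                nuclei=nuclei,
            )

    spot_lists: dict[str, list[spot_detect.Spot]] = {}
    for name, kind, channel in zip(stack.names, stack.stains, stack.channels):
        if kind == "spot":
            spot_lists[name] = spot_detect.detect_spots(
                channel,
                nuclei,
                spot_params,
                use_classifier=params.use_spot_classifier,
            )

    # background: explicit mask if configured, else the non-cell area
    if params.background_mask:
        bg_mask = io_background.load_mask(params.background_mask)
    else:
        bg_mask = nuclei == 0
    backgrounds: dict[str, io_background.BackgroundEstimate] = {}
    for name, kind, channel in zip(stack.names, stack.stains, stack.channels):
        if not bg_mask.any():
            continue
        gmean = io_background.global_background(channel, bg_mask)
        if kind in ("nuclear", "DAPI") and nuclei.max() > 0:
            est = io_background.ring_background(
                channel, nuclei, params.ring_inner, params.ring_outer
            )
            est = io_background.BackgroundEstimate(
                global_mean=gmean, per_label=est.per_label
            )
        else:
            est = io_background.BackgroundEstimate(global_mean=gmean)
        backgrounds[name] = est

    first_spot = next(iter(spot_lists), None)
    records = cell_features.map_segments(
        nuclei,
        membranes,
        spot_lists.get(first_spot) if first_spot else None,
        spot_channel=first_spot or "FISH",
        spot_params=spot_params,
    )
    # additional spot channels
    for name, spots in spot_lists.items():
        if name == first_spot:
            continue
        per_cell: dict[int, float] = {}
        for s in spots:
            if s.nucleus is not None:
                per_cell[s.nucleus] = per_cell.get(s.nucleus, 0.0) + s.area
        for rec in records:
            area = per_cell.get(rec.nucleus_label, 0.0)
            rec.spot_area[name] = area
            rec.copies[name] = spot_detect.estimate_copies(area, spot_params)
    records = cell_features.measure_cells(
        records, stack, backgrounds, nuclei=nuclei, membranes=membranes
    )
    thresholds = None
    if params.thresholds:
        rules = [cell_features.ThresholdRule(**r) for r in params.thresholds]
        thresholds = cell_features.apply_thresholds(records, rules)
    return dict(
        nuclei=nuclei,
        membranes=membranes,
        spots=spot_lists,
        backgrounds=backgrounds,
        records=records,
        thresholds=thresholds,
        seg_params=seg_params,
        spot_params=spot_params,
    )


def _spots_frame(spot_lists: dict[str, list[spot_detect.Spot]]) -> pd.DataFrame:
    rows = []
    for name, spots in spot_lists.items():
        for s in spots:
            rows.append(
                dict(
                    channel=name,
                    label=s.label,
                    row=s.centroid[0],
                    col=s.centroid[1],
                    area=s.area,
                    mean_intensity=s.mean_intensity,
                    min_intensity=s.min_intensity,
                    spot_class=s.spot_class or "",
                    nucleus=s.nucleus if s.nucleus is not None else -1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "channel", "label", "row", "col", "area",
            "mean_intensity", "min_intensity", "spot_class", "nucleus",
        ],
    )


def save_bundle(out_dir: str | Path, stem: str, result: dict) -> Path:
    """Write one image's result bundle (TIFF label maps, CSVs, manifest)."""
    bundle = Path(out_dir) / stem
    bundle.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        bundle / "nuclei.tiff",
        result["nuclei"].astype(np.uint16),
        photometric="minisblack",
    )
    if result["membranes"] is not None:
        tifffile.imwrite(
            bundle / "membranes.tiff",
            result["membranes"].labels.astype(np.uint16),
            photometric="minisblack",
        )
        pd.DataFrame(
            sorted(result["membranes"].owner.items()),
            columns=["membrane", "nucleus"],
        ).to_csv(bundle / "owners.csv", index=False)
    _spots_frame(result["spots"]).to_csv(bundle / "spots.csv", index=False)
    cell_features.records_to_frame(result["records"]).to_csv(
        bundle / "cells.csv", index=False
    )
    if result["thresholds"] is not None:
        result["thresholds"].to_csv(bundle / "thresholds.csv", index=False)
    manifest = dict(
        image=stem,
        n_cells=len(result["records"]),
        seg_params=dataclasses.asdict(result["seg_params"]),
        spot_params=dataclasses.asdict(result["spot_params"]),
    )
    with open(bundle / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle


def run_batch(params: ParameterFile, force: bool = False) -> dict[str, Path]:
    """Process every image matching the input glob into result bundles.

    Existing bundles (a present ``manifest.json``) are skipped unless
    ``force``.  Per-image failures are logged and skipped; the returned
    mapping holds only the successful bundles.  Raises ``RuntimeError`` at
    the end if any image failed.
    """
    paths = sorted(globmod.glob(params.input_glob))
    if not paths:
        raise FileNotFoundError(f"no inputs match {params.input_glob!r}")
    bundles: dict[str, Path] = {}
    failures: list[str] = []
    for path in paths:
        stem = Path(path).stem
        bundle_dir = Path(params.output_dir) / stem
        if (bundle_dir / "manifest.json").exists() and not force:
            log.info("skipping %s: bundle exists", stem)
            bundles[stem] = bundle_dir
            continue
        try:
            stack = io_background.load_stack(
                path, params.stains, params.magnification, names=params.names
            )
            result = process_image(stack, params)
            bundles[stem] = save_bundle(params.output_dir, stem, result)
            log.info("processed %s: %d cells", stem, len(result["records"]))
        except Exception:
            log.exception("failed to process %s", path)
            failures.append(path)
    if failures:
        raise RuntimeError(f"{len(failures)} image(s) failed: {failures}")
    return bundles
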