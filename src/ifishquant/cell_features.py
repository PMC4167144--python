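"""Per-cell linking, measurement, editing, classification and topology maps.

After the three compartments are segmented, every nucleus is linked to its
membrane territory and contained FISH signals to form one record per cell.
Records carry raw, globally background-adjusted and per-nucleus
ring-adjusted intensities, nuclear morphology, a membrane-completeness
proxy (the coefficient of variation of intensity along the membrane band:
complete rings vary less than broken ones), spot area and copy number.

Cell typing is a one-vs-all linear-kernel SVM trained on a user-labelled
subset (morphology only, or morphology plus adjusted intensities and spot
area).  Global intensity thresholds split cells into marker-positive /
negative categories, and topology maps render the relative ratio
a/(a+b) of two stains at each cell's footprint, preserving spatial
context.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw, measure
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io_background import BackgroundEstimate, ImageStack
from .membrane_seg import MembraneMap
from .spot_detect import Spot, SpotParams, estimate_copies

log = logging.getLogger(__name__)

MAX_CELL_CLASSES = 4

MORPHOLOGY_FEATURES = (
    "area",
    "perimeter",
    "solidity",
    "axis_major",
    "axis_minor",
    "eccentricity",
)


class MappingError(ValueError):
    """Inconsistent compartment mapping (e.g. two nuclei in one membrane)."""


@dataclass
class CellRecord:
    """One cell's linked nucleus/membrane/spot measurements."""

    cell_id: int
    nucleus_label: int
    membrane_label: int | None = None
    centroid: tuple[float, float] = (0.0, 0.0)
    area: float = 0.0
    perimeter: float = 0.0
    solidity: float = 0.0
    axis_major: float = 0.0
    axis_minor: float = 0.0
    eccentricity: float = 0.0
    raw: dict[str, float] = field(default_factory=dict)
    global_adj: dict[str, float] = field(default_factory=dict)
    ring_adj: dict[str, float] = field(default_factory=dict)
    membrane_cov: dict[str, float] = field(default_factory=dict)
    spot_area: dict[str, float] = field(default_factory=dict)
    copies: dict[str, int] = field(default_factory=dict)
    cell_class: str | None = None


@dataclass
class ThresholdRule:
    """One marker-positivity rule: stain, cutoff and adjustment mode."""

    stain: str
    cutoff: float
    mode: str = "global"  # raw | global | ring

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")
        if self.mode not in ("raw", "global", "ring"):
            raise ValueError("mode must be raw, global or ring")


def map_segments(
    nuclei: np.ndarray,
    membranes: MembraneMap | None,
    spots: list[Spot] | None = None,
    spot_channel: str = "FISH",
    spot_params: SpotParams | None = None,
) -> list[CellRecord]:
    """Link each nucleus to its membrane territory and contained spots.

    Raises :class:`MappingError` when two nuclei map to the same membrane
    region, naming the offending labels; membranes owning no nucleus are
    dropped with a warning.
    """
    nuclei = np.asarray(nuclei)
    labels = [int(v) for v in np.unique(nuclei) if v > 0]
    mem_of_nucleus: dict[int, int] = {}
    if membranes is not None:
        seen: dict[int, int] = {}
        for mem_label, nuc_label in membranes.owner.items():
            if nuc_label in seen and seen[nuc_label] != mem_label:
                raise MappingError(
                    f"nucleus {nuc_label} owned by membranes "
                    f"{seen[nuc_label]} and {mem_label}"
                )
            seen[nuc_label] = mem_label
        # a membrane region containing >= 2 nucleus majorities is ambiguous
        for mem_label in membranes.owner:
            region = membranes.labels == mem_label
            inside = []
            for lab in labels:
                nuc_mask = nuclei == lab
                if (nuc_mask & region).sum() > 0.5 * nuc_mask.sum():
                    inside.append(lab)
            if len(inside) >= 2:
                raise MappingError(
                    f"membrane {mem_label} contains nuclei {sorted(inside)}"
                )
        mem_of_nucleus = {v: k for k, v in membranes.owner.items()}
        orphan = set(membranes.owner) - set(mem_of_nucleus.values())
        for m in sorted(orphan):
            warnings.warn(f"membrane {m} matches no nucleus; dropped", stacklevel=2)

    if spot_params is None:
        spot_params = SpotParams()
    spot_area: dict[int, float] = {}
    for s in spots or []:
        if s.nucleus is not None:
            spot_area[s.nucleus] = spot_area.get(s.nucleus, 0.0) + s.area

    records = []
    for cid, lab in enumerate(labels, start=1):
        rec = CellRecord(
            cell_id=cid,
            nucleus_label=lab,
            membrane_label=mem_of_nucleus.get(lab),
        )
        area = spot_area.get(lab, 0.0)
        rec.spot_area[spot_channel] = area
        rec.copies[spot_channel] = estimate_copies(area, spot_params)
        records.append(rec)
    return records


def measure_cells(
    records: list[CellRecord],
    stack: ImageStack,
    backgrounds: dict[str, BackgroundEstimate] | None = None,
    *,
    nuclei: np.ndarray,
    membranes: MembraneMap | None = None,
    band_width: int = 2,
) -> list[CellRecord]:
    """Fill intensity and morphology fields of every record in place.

    Per stain: nuclear stains (and DAPI) are read over the nucleus region;
    membrane stains over the membrane band (the territory boundary dilated
    by ``band_width``).  Global-adjusted = raw - global mean, clamped at 0;
    ring-adjusted (nuclear stains only) = raw - the per-nucleus annulus
    background, clamped at 0.  The membrane coefficient of variation
    (std/mean over the band) is a completeness proxy.
    """
    nuclei = np.asarray(nuclei)
    props = {
        int(r.label): r for r in measure.regionprops(nuclei)
    }
    backgrounds = backgrounds or {}
    bands: dict[int, np.ndarray] = {}
    for rec in records:
        region = props.get(rec.nucleus_label)
        if region is None:
            continue
        rec.centroid = tuple(region.centroid)
        rec.area = float(region.area)
        rec.perimeter = float(region.perimeter)
        rec.solidity = float(region.solidity)
        rec.axis_major = float(region.axis_major_length)
        rec.axis_minor = float(region.axis_minor_length)
        rec.eccentricity = float(region.eccentricity)
        nuc_mask = nuclei == rec.nucleus_label
        for name, kind, channel in zip(stack.names, stack.stains, stack.channels):
            bg = backgrounds.get(name)
            if kind == "membrane" and membranes is not None and rec.membrane_label:
                if rec.membrane_label not in bands:
                    bands[rec.membrane_label] = membranes.band(
                        rec.membrane_label, band_width
                    )
                sel = bands[rec.membrane_label]
                vals = channel[sel]
                if vals.size:
                    mean = float(vals.mean())
                    rec.raw[name] = mean
                    rec.membrane_cov[name] = (
                        float(vals.std() / mean) if mean > 0 else float("nan")
                    )
            else:
                vals = channel[nuc_mask]
                rec.raw[name] = float(vals.mean()) if vals.size else float("nan")
            if bg is not None and name in rec.raw:
                rec.global_adj[name] = max(rec.raw[name] - bg.global_mean, 0.0)
                if kind in ("nuclear", "DAPI") and bg.per_label:
                    local = bg.per_label.get(rec.nucleus_label, bg.global_mean)
                    rec.ring_adj[name] = max(rec.raw[name] - local, 0.0)
    return records


# ---------------------------------------------------------------------------
# programmatic label editing (scissors / glue / trash / paint / erase)
# ---------------------------------------------------------------------------


def _rasterize_polyline(points, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = [(int(round(r)), int(round(c))) for r, c in points]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def edit_labels(labels: np.ndarray, edits: list[dict]) -> np.ndarray:
    """Apply an ordered edit script to a label map.

    Supported operations (JSON-friendly dicts, replacing the interactive
    scissors/glue/trash/paint/erase tools):

    - ``{"op": "cut", "label": a, "path": [[r, c], ...]}`` - split label
      ``a`` along the rasterised polyline into its connected remainders.
    - ``{"op": "glue", "a": a, "b": b}`` - merge ``b`` into ``a``.
    - ``{"op": "trash", "label": a}`` - delete label ``a``.
    - ``{"op": "paint", "polygon": [[r, c], ...]}`` - add a new labelled
      region over the polygon (background pixels only).
    - ``{"op": "erase", "polygon": [[r, c], ...]}`` - clear pixels.

    Edits apply in order and deterministically; new labels continue from
    the current maximum.
    """
    out = np.asarray(labels).copy()
    for edit in edits:
        op = edit.get("op")
        if op == "cut":
            lab = int(edit["label"])
            if not (out == lab).any():
                raise MappingError(f"cut references missing label {lab}")
            line = _rasterize_polyline(edit["path"], out.shape)
            region = out == lab
            remainder = region & ~line
            comps, n = ndi.label(remainder, structure=np.ones((3, 3)))
            if n <= 1:
                warnings.warn(
                    f"cut polyline does not split label {lab}; no-op",
                    stacklevel=2,
                )
                continue
            out[region] = 0
            nxt = int(out.max())
            for k in range(1, n + 1):
                nxt += 1
                out[comps == k] = nxt
            # cut pixels themselves join the nearest resulting piece
            cut_px = region & line
            if cut_px.any():
                _, (ir, ic) = ndi.distance_transform_edt(
                    ~(comps > 0), return_indices=True
                )
                out[cut_px] = out[ir[cut_px], ic[cut_px]]
        elif op == "glue":
            a, b = int(edit["a"]), int(edit["b"])
            for lab in (a, b):
                if not (out == lab).any():
                    raise MappingError(f"glue references missing label {lab}")
            out[out == b] = a
        elif op == "trash":
            lab = int(edit["label"])
            if not (out == lab).any():
                raise MappingError(f"trash references missing label {lab}")
            out[out == lab] = 0
        elif op == "paint":
            poly = np.asarray(edit["polygon"], dtype=float)
            rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=out.shape)
            sel = out[rr, cc] == 0
            if sel.any():
                out[rr[sel], cc[sel]] = int(out.max()) + 1
        elif op == "erase":
            poly = np.asarray(edit["polygon"], dtype=float)
            rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=out.shape)
            out[rr, cc] = 0
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    return out


def load_edit_script(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cell classification and thresholds
# ---------------------------------------------------------------------------


def _feature_vector(rec: CellRecord, feature_set: str) -> np.ndarray:
    feats = [
        rec.area,
        rec.perimeter,
        rec.solidity,
        rec.axis_major,
        rec.axis_minor,
        rec.eccentricity,
    ]
    if feature_set == "morphology_plus_intensity":
        for name in sorted(rec.raw):
            feats.append(rec.global_adj.get(name, rec.raw[name]))
        for name in sorted(rec.spot_area):
            feats.append(rec.spot_area[name])
    return np.asarray(feats, dtype=float)


def classify_cells(
    records: list[CellRecord],
    training: dict[int, str],
    feature_set: str = "morphology_plus_intensity",
    *,
    C: float = 1.0,
    max_classes: int = MAX_CELL_CLASSES,
) -> list[CellRecord]:
    """Assign a class to every record from a user-labelled subset.

    ``training`` maps cell_id to class label.  A one-vs-all linear-kernel
    SVM (C = 1) with features standardised on the training subset is fit
    and applied to all records; training cells keep their given label.
    """
    if feature_set not in ("morphology_only", "morphology_plus_intensity"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    classes = sorted(set(training.values()))
    if len(classes) < 2:
        raise ValueError("training must contain at least 2 classes")
    if len(classes) > max_classes:
        raise ValueError(f"more than {max_classes} classes: {classes}")
    by_id = {rec.cell_id: rec for rec in records}
    missing = [cid for cid in training if cid not in by_id]
    if missing:
        raise ValueError(f"training references unknown cells {missing}")
    X = np.stack(
        [_feature_vector(by_id[cid], feature_set) for cid in sorted(training)]
    )
    y = [training[cid] for cid in sorted(training)]
    model = make_pipeline(
        StandardScaler(),
        OneVsRestClassifier(SVC(kernel="linear", C=C)),
    )
    model.fit(X, y)
    for rec in records:
        if rec.cell_id in training:
            rec.cell_class = training[rec.cell_id]
        else:
            rec.cell_class = str(
                model.predict(_feature_vector(rec, feature_set)[None, :])[0]
            )
    return records


def _intensity(rec: CellRecord, stain: str, mode: str) -> float:
    source = {"raw": rec.raw, "global": rec.global_adj, "ring": rec.ring_adj}[mode]
    if stain not in source:
        raise KeyError(
            f"cell {rec.cell_id}: no {mode} intensity for stain {stain!r}"
        )
    return source[stain]


def apply_thresholds(
    records: list[CellRecord], rules: list[ThresholdRule]
) -> pd.DataFrame:
    """Marker positivity per cell for each rule (>= cutoff is positive).

    Returns one row per cell with a boolean column per stain and a
    combined category string such as ``"ER+/HER2-"``.
    """
    rows = []
    for rec in records:
        row: dict = {"cell_id": rec.cell_id}
        parts = []
        for rule in rules:
            pos = _intensity(rec, rule.stain, rule.mode) >= rule.cutoff
            row[f"{rule.stain}_positive"] = bool(pos)
            parts.append(f"{rule.stain}{'+' if pos else '-'}")
        row["category"] = "/".join(parts)
        rows.append(row)
    return pd.DataFrame(rows)


def topology_map(
    records: list[CellRecord],
    stain_a: str,
    stain_b: str,
    labels: np.ndarray,
    *,
    mode: str = "global",
    value_b: str | None = None,
    cmap: str = "coolwarm",
):
    """Relative-ratio map of two stains over the segmented footprints.

    Per cell the ratio a/(a+b) of (adjusted) intensities is computed
    (0.5 = balanced, 1 = pure a); cells are coloured by ratio at their
    label footprint and a (cell_id, centroid, ratio) table is returned.
    With ``value_b="spot_area"`` the second quantity is the cell's FISH
    spot area instead of an intensity, for protein-vs-copy-number maps.
    Cells with a + b = 0 have undefined ratio and render neutral grey.

    Returns ``(table, rgb)``.
    """
    import matplotlib

    labels = np.asarray(labels)
    rows = []
    ratio_of: dict[int, float] = {}
    for rec in records:
        a = _intensity(rec, stain_a, mode)
        if value_b == "spot_area":
            b = rec.spot_area.get(stain_b, 0.0)
        else:
            b = _intensity(rec, stain_b, mode)
        total = a + b
        ratio = a / total if total > 0 else float("nan")
        key = rec.membrane_label if rec.membrane_label else rec.nucleus_label
        ratio_of[key] = ratio
        rows.append(
            dict(
                cell_id=rec.cell_id,
                row=rec.centroid[0],
                col=rec.centroid[1],
                ratio=ratio,
            )
        )
    table = pd.DataFrame(rows, columns=["cell_id", "row", "col", "ratio"])

    colormap = matplotlib.colormaps[cmap]
    rgb = np.full(labels.shape + (3,), 0.15)  # dark background
    for lab, ratio in ratio_of.items():
        sel = labels == lab
        if np.isnan(ratio):
            rgb[sel] = 0.5  # neutral grey
        else:
            rgb[sel] = colormap(float(ratio))[:3]
    return table, rgb


# ---------------------------------------------------------------------------
# CSV serialisation
# ---------------------------------------------------------------------------


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten records into one row per cell (dict fields become columns)."""
    rows = []
    for rec in records:
        row: dict = dict(
            cell_id=rec.cell_id,
            nucleus_label=rec.nucleus_label,
            membrane_label=(
                rec.membrane_label if rec.membrane_label is not None else -1
            ),
            centroid_row=rec.centroid[0],
            centroid_col=rec.centroid[1],
            area=rec.area,
            perimeter=rec.perimeter,
            solidity=rec.solidity,
            axis_major=rec.axis_major,
            axis_minor=rec.axis_minor,
            eccentricity=rec.eccentricity,
            cell_class=rec.cell_class if rec.cell_class is not None else "",
        )
        for prefix, d in (
            ("raw", rec.raw),
            ("globaladj", rec.global_adj),
            ("ringadj", rec.ring_adj),
            ("memcov", rec.membrane_cov),
            ("spotarea", rec.spot_area),
            ("copies", rec.copies),
        ):
            for name, val in d.items():
                row[f"{prefix}_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def read_cells_csv(path) -> list[CellRecord]:
    """Read a per-cell CSV back into records, bit-exact for floats."""
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


def frame_to_records(frame: pd.DataFrame) -> list[CellRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    prefixes = ("raw", "globaladj", "ringadj", "memcov", "spotarea", "copies")
    attr_of = dict(
        raw="raw",
        globaladj="global_adj",
        ringadj="ring_adj",
        memcov="membrane_cov",
        spotarea="spot_area",
        copies="copies",
    )
    for _, row in frame.iterrows():
        mem = int(row["membrane_label"])
        cls = row["cell_class"]
        rec = CellRecord(
            cell_id=int(row["cell_id"]),
            nucleus_label=int(row["nucleus_label"]),
            membrane_label=None if mem == -1 else mem,
            centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            area=float(row["area"]),
            perimeter=float(row["perimeter"]),
            solidity=float(row["solidity"]),
            axis_major=float(row["axis_major"]),
            axis_minor=float(row["axis_minor"]),
            eccentricity=float(row["eccentricity"]),
            cell_class=None if (pd.isna(cls) or cls == "") else str(cls),
        )
        for col in frame.columns:
            for prefix in prefixes:
                if col.startswith(prefix + "_") and not pd.isna(row[col]):
                    name = col[len(prefix) + 1 :]
                    val = row[col]
                    getattr(rec, attr_of[prefix])[name] = (
                        int(val) if prefix == "copies" else float(val)
                    )
        records.append(rec)
    return records
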