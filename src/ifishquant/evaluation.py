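"""Object-level segmentation scoring against a gold standard.

Counts follow a five-way taxonomy: Nt correctly segmented objects,
Nunder under-segmented (several gold objects absorbed into one
prediction), Nover over-segmented (one gold object split across several
predictions, counted per extra prediction), NFP predictions absent from
the gold standard, and NFN gold objects with no qualifying prediction.

    P = Nt / (Nt + NFP + Nover)
    R = Nt / (Nt + NFN + Nunder)
    F = 2PR / (P + R)

A prediction correctly segments a gold object when their Jaccard overlap
reaches ``overlap_threshold`` (default 0.5; pairs above 0.5 are
necessarily one-to-one).  A prediction *covers* a gold object when it
holds the majority of that object's pixels (under-segmentation evidence);
a prediction *lies inside* a gold object when the object holds the
majority of the prediction's pixels (over-segmentation evidence).

Shape fidelity complements presence/absence scoring: per matched pair the
quotient of perimeter-area ratios (prediction over gold) is 1 for
identical morphology, below 1 for predictions that are rounder/larger
than their gold object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure


@dataclass
class MatchCounts:
    """Object-level bookkeeping for one predicted-vs-gold comparison."""

    Nt: int = 0
    Nunder: int = 0
    Nover: int = 0
    NFP: int = 0
    NFN: int = 0

    def __post_init__(self) -> None:
        for name in ("Nt", "Nunder", "Nover", "NFP", "NFN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class UndefinedMetricError(ZeroDivisionError):
    """A precision/recall denominator is zero; the metric is undefined."""


def _overlap_table(pred: np.ndarray, gold: np.ndarray):
    """Sparse contingency of (pred label, gold label) -> pixel overlap."""
    both = (pred > 0) | (gold > 0)
    p = pred[both].ravel()
    g = gold[both].ravel()
    pairs, counts = np.unique(np.stack([p, g]), axis=1, return_counts=True)
    table: dict[tuple[int, int], int] = {}
    for (pl, gl), n in zip(pairs.T, counts):
        table[(int(pl), int(gl))] = int(n)
    return table


def match_segments(
    pred: np.ndarray, gold: np.ndarray, overlap_threshold: float = 0.5
) -> MatchCounts:
    """Classify every predicted and gold object into the match taxonomy.

    Each gold object contributes to exactly one of Nt, Nunder, Nover-source
    or NFN; each predicted object to one of match, under-source,
    over-piece or NFP.
    """
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError("pred and gold label maps must share a shape")
    table = _overlap_table(pred, gold)
    p_area: dict[int, int] = {}
    g_area: dict[int, int] = {}
    for (pl, gl), n in table.items():
        if pl > 0:
            p_area[pl] = p_area.get(pl, 0) + n
        if gl > 0:
            g_area[gl] = g_area.get(gl, 0) + n

    matched_g: set[int] = set()
    matched_p: set[int] = set()
    for (pl, gl), inter in table.items():
        if pl == 0 or gl == 0:
            continue
        union = p_area[pl] + g_area[gl] - inter
        if union > 0 and inter / union >= overlap_threshold:
            if gl not in matched_g and pl not in matched_p:
                matched_g.add(gl)
                matched_p.add(pl)

    # under-segmentation: one prediction holds the majority of >= 2 golds
    covers: dict[int, list[int]] = {}
    for (pl, gl), inter in table.items():
        if pl == 0 or gl == 0 or gl in matched_g:
            continue
        if inter > 0.5 * g_area[gl]:
            covers.setdefault(pl, []).append(gl)
    under_g: set[int] = set()
    under_p: set[int] = set()
    for pl, gls in covers.items():
        if pl in matched_p:
            gls = [g for g in gls]
            # a matched prediction additionally absorbing other golds still
            # under-segments those golds
        if len(gls) + (1 if pl in matched_p else 0) >= 2:
            under_g.update(gls)
            if pl not in matched_p:
                under_p.add(pl)

    # over-segmentation: >= 2 predictions lie (majority) inside one gold
    inside: dict[int, list[int]] = {}
    for (pl, gl), inter in table.items():
        if pl == 0 or gl == 0 or pl in matched_p or pl in under_p:
            continue
        if inter > 0.5 * p_area[pl]:
            inside.setdefault(gl, []).append(pl)
    n_over = 0
    over_g: set[int] = set()
    over_p: set[int] = set()
    for gl, pls in inside.items():
        base = 1 if gl in matched_g else 0
        if len(pls) + base >= 2:
            over_p.update(pls)
            n_over += len(pls) - (0 if base else 1)
            if not base and gl not in under_g:
                over_g.add(gl)

    all_g = set(g_area)
    all_p = set(p_area)
    n_fn = len(all_g - matched_g - under_g - over_g)
    n_fp = len(all_p - matched_p - under_p - over_p)
    return MatchCounts(
        Nt=len(matched_g),
        Nunder=len(under_g),
        Nover=n_over,
        NFP=n_fp,
        NFN=n_fn,
    )


def precision_recall_f(c: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and F-score from the match counts."""
    pden = c.Nt + c.NFP + c.Nover
    rden = c.Nt + c.NFN + c.Nunder
    if pden == 0 or rden == 0:
        raise UndefinedMetricError(
            f"undefined metric: precision denominator {pden}, recall denominator {rden}"
        )
    p = c.Nt / pden
    r = c.Nt / rden
    f = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return p, r, f


def matched_pairs(
    pred: np.ndarray, gold: np.ndarray, overlap_threshold: float = 0.5
) -> list[tuple[int, int]]:
    """(pred label, gold label) pairs with Jaccard >= threshold."""
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    table = _overlap_table(pred, gold)
    p_area: dict[int, int] = {}
    g_area: dict[int, int] = {}
    for (pl, gl), n in table.items():
        if pl > 0:
            p_area[pl] = p_area.get(pl, 0) + n
        if gl > 0:
            g_area[gl] = g_area.get(gl, 0) + n
    pairs = []
    used_p: set[int] = set()
    used_g: set[int] = set()
    for (pl, gl), inter in sorted(
        table.items(), key=lambda kv: -kv[1]
    ):
        if pl == 0 or gl == 0 or pl in used_p or gl in used_g:
            continue
        union = p_area[pl] + g_area[gl] - inter
        if union > 0 and inter / union >= overlap_threshold:
            pairs.append((pl, gl))
            used_p.add(pl)
            used_g.add(gl)
    return sorted(pairs)


def shape_fidelity(
    pred: np.ndarray,
    gold: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    overlap_threshold: float = 0.5,
) -> pd.DataFrame:
    """Perimeter-area ratio quotient per matched object pair.

    Returns a frame with columns pred, gold, quotient; the image-level
    summary is the mean quotient (1 = shapes faithfully reproduced).
    Perimeters use the contour-length approximation of ``skimage``.
    """
    if pairs is None:
        pairs = matched_pairs(pred, gold, overlap_threshold)
    if not pairs:
        return pd.DataFrame(columns=["pred", "gold", "quotient"])

    def ratios(labels: np.ndarray) -> dict[int, float]:
        out = {}
        for region in measure.regionprops(np.asarray(labels)):
            per = float(region.perimeter)
            out[int(region.label)] = per / float(region.area)
        return out

    rp = ratios(pred)
    rg = ratios(gold)
    rows = [
        dict(pred=pl, gold=gl, quotient=rp[pl] / rg[gl])
        for pl, gl in pairs
        if pl in rp and gl in rg and rg[gl] > 0
    ]
    return pd.DataFrame(rows, columns=["pred", "gold", "quotient"])


def evaluate(
    pred: np.ndarray, gold: np.ndarray, overlap_threshold: float = 0.5
) -> dict:
    """Full report: counts, P/R/F and mean shape-fidelity quotient."""
    counts = match_segments(pred, gold, overlap_threshold)
    try:
        p, r, f = precision_recall_f(counts)
    except UndefinedMetricError:
        p = r = f = float("nan")
    fid = shape_fidelity(pred, gold, overlap_threshold=overlap_threshold)
    return dict(
        Nt=counts.Nt,
        Nunder=counts.Nunder,
        Nover=counts.Nover,
        NFP=counts.NFP,
        NFN=counts.NFN,
        precision=p,
        recall=r,
        f_score=f,
        mean_shape_quotient=(
            float(fid["quotient"].mean()) if len(fid) else float("nan")
        ),
    )
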