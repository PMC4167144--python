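"""Image loading, contrast adjustment and background correction.

An IFISH acquisition is a set of co-registered 2-D fluorescence channels:
a DAPI nuclear counterstain (mandatory), protein stains located in the
nucleus (e.g. ER) or the membrane (e.g. HER2), and FISH spot channels
(e.g. the HER2 locus and the centromere-17 reference probe).

Two background corrections are supported: a single global value (the mean
intensity over a user-supplied background region), and a per-nucleus local
value measured in an annulus 2-6 px outside each segmented nucleus.  The
local form absorbs spatial variation in tissue autofluorescence, which is
what makes nuclear intensities comparable across cells and samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

log = logging.getLogger(__name__)

#: Recognised stain kinds.  Exactly one channel per stack must be DAPI.
STAIN_KINDS = ("DAPI", "nuclear", "membrane", "spot", "other")

#: Channel limit mirroring the interactive tool; batch mode is unbounded.
MAX_CHANNELS_GUI = 5


class ConfigurationError(ValueError):
    """Raised for inconsistent stain/channel metadata."""


@dataclass
class ImageStack:
    """Ordered set of co-registered 2-D channels with stain annotations.

    Parameters
    ----------
    channels
        2-D non-negative intensity arrays, all the same height/width.
    stains
        One stain kind per channel, drawn from :data:`STAIN_KINDS`.
    magnification
        Objective magnification, one of 20, 40, 60.
    names
        Optional human-readable channel names (e.g. ``"HER2"``); default to
        the stain kinds, disambiguated by index.
    """

    channels: list[np.ndarray]
    stains: list[str]
    magnification: int
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.stains):
            raise ConfigurationError(
                f"{len(self.stains)} stain labels for {len(self.channels)} channels"
            )
        for s in self.stains:
            if s not in STAIN_KINDS:
                raise ConfigurationError(
                    f"unknown stain kind {s!r}; expected one of {STAIN_KINDS}"
                )
        if self.stains.count("DAPI") != 1:
            raise ConfigurationError("exactly one channel must be labelled DAPI")
        shapes = {c.shape for c in self.channels}
        if len(shapes) > 1:
            raise ConfigurationError(f"channels differ in shape: {sorted(shapes)}")
        for c in self.channels:
            if c.ndim != 2:
                raise ConfigurationError("channels must be 2-D arrays")
        if self.magnification not in (20, 40, 60):
            raise ConfigurationError("magnification must be one of 20, 40, 60")
        if not self.names:
            counts: dict[str, int] = {}
            names = []
            for s in self.stains:
                counts[s] = counts.get(s, 0) + 1
                names.append(s if self.stains.count(s) == 1 else f"{s}{counts[s]}")
            self.names = names
        elif len(self.names) != len(self.channels):
            raise ConfigurationError("names must match channel count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def dapi(self) -> np.ndarray:
        return self.channels[self.stains.index("DAPI")]

    def channel(self, name: str) -> np.ndarray:
        """Return a channel by name or, failing that, by stain kind."""
        if name in self.names:
            return self.channels[self.names.index(name)]
        if name in self.stains:
            return self.channels[self.stains.index(name)]
        raise KeyError(f"no channel named {name!r}; have {self.names}")


@dataclass
class BackgroundEstimate:
    """Global and per-nucleus background intensities for one channel."""

    global_mean: float
    per_label: dict[int, float] = field(default_factory=dict)
    mode: str = "from_raw"

    def __post_init__(self) -> None:
        if self.global_mean < 0:
            raise ValueError("global_mean must be non-negative")
        if any(v < 0 for v in self.per_label.values()):
            raise ValueError("per-label background values must be non-negative")


def load_stack(
    path: str | Path,
    stains: Sequence[str],
    magnification: int,
    *,
    names: Sequence[str] | None = None,
    gui_parity: bool = False,
) -> ImageStack:
    """Load a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages (or the leading axis of a 3-D page) are taken as channels in file
    order; intensities are preserved bit-exact.  With ``gui_parity`` the
    channel count is limited to 5 as in the interactive tool.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        channels = [data]
    elif data.ndim == 3:
        # channel axis is the smallest axis of a 3-D stack
        axis = int(np.argmin(data.shape))
        channels = [np.asarray(c) for c in np.moveaxis(data, axis, 0)]
    else:
        raise IOError(f"unsupported TIFF dimensionality {data.ndim} in {path}")
    if gui_parity and len(channels) > MAX_CHANNELS_GUI:
        raise ConfigurationError(
            f"more than {MAX_CHANNELS_GUI} stains ({len(channels)}) in GUI-parity mode"
        )
    return ImageStack(
        channels=channels,
        stains=list(stains),
        magnification=int(magnification),
        names=list(names) if names is not None else [],
    )


def save_stack(path: str | Path, stack: ImageStack) -> None:
    """Write the channels of a stack as a multi-page TIFF (lossless)."""
    tifffile.imwrite(
        str(path), np.stack(stack.channels, axis=0), photometric="minisblack"
    )


def autoadjust(channel: np.ndarray, saturation_fraction: float = 0.01) -> np.ndarray:
    """Contrast-stretch a channel, saturating a fraction of extreme pixels.

    The lowest and highest ``saturation_fraction`` quantiles are clipped and
    the remainder rescaled linearly to the full range of the input dtype
    (float inputs rescale to [0, 1]).  The mapping is monotone
    non-decreasing.  This is a *display* transform: quantification always
    reads raw intensities, never the adjusted copy.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    if not 0 <= saturation_fraction < 0.5:
        raise ValueError("saturation_fraction must be in [0, 0.5)")
    lo = float(np.quantile(channel, saturation_fraction))
    hi = float(np.quantile(channel, 1.0 - saturation_fraction))
    if hi <= lo:
        warnings.warn("constant channel: no contrast stretch applied", stacklevel=2)
        return channel.copy()
    if np.issubdtype(channel.dtype, np.integer):
        out_lo = float(np.iinfo(channel.dtype).min)
        out_hi = float(np.iinfo(channel.dtype).max)
    else:
        out_lo, out_hi = 0.0, 1.0
    stretched = (channel.astype(np.float64) - lo) / (hi - lo)
    stretched = np.clip(stretched, 0.0, 1.0) * (out_hi - out_lo) + out_lo
    if np.issubdtype(channel.dtype, np.integer):
        stretched = np.round(stretched)
    return stretched.astype(channel.dtype)


def global_background(channel: np.ndarray, region_mask: np.ndarray) -> float:
    """Mean intensity of ``channel`` over a user-supplied background region."""
    channel = np.asarray(channel)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != channel.shape:
        raise ValueError("region_mask shape does not match channel")
    if not region_mask.any():
        raise ValueError("background region mask is empty")
    return float(channel[region_mask].mean())


def subtract_background(
    channel: np.ndarray, value: float, clamp: bool = True
) -> np.ndarray:
    """Subtract a scalar background; negatives clamp to 0 unless disabled."""
    if value < 0:
        raise ValueError("background value must be non-negative")
    out = np.asarray(channel, dtype=np.float64) - float(value)
    if clamp:
        np.maximum(out, 0.0, out=out)
    return out


def ring_background(
    channel: np.ndarray,
    nuclei: np.ndarray,
    inner_margin: int = 2,
    outer_margin: int = 6,
    *,
    global_mask: np.ndarray | None = None,
) -> BackgroundEstimate:
    """Per-nucleus local background in an annulus outside each nucleus.

    For each nucleus label the mean channel intensity is taken over the
    annulus between dilations of that nucleus by ``inner_margin`` and
    ``outer_margin`` pixels (disk structuring element), excluding pixels
    belonging to *any* nucleus.  A nucleus whose annulus is fully occluded
    by neighbours falls back to the global mean.

    ``global_mask`` optionally restricts the global-mean fallback region;
    by default the complement of all nuclei is used.
    """
    channel = np.asarray(channel, dtype=np.float64)
    nuclei = np.asarray(nuclei)
    if nuclei.shape != channel.shape:
        raise ValueError("nuclei label map shape does not match channel")
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("empty nucleus label map")
    if not 0 <= inner_margin < outer_margin:
        raise ValueError("need 0 <= inner_margin < outer_margin")

    any_nucleus = nuclei > 0
    if global_mask is None:
        global_mask = ~any_nucleus
    gmean = float(channel[global_mask].mean()) if global_mask.any() else float(
        channel.mean()
    )

    # Annulus membership via the Euclidean distance to each nucleus; for
    # disjoint regions this equals disk dilation but costs one EDT per call.
    dist, (ir, ic) = ndi.distance_transform_edt(~any_nucleus, return_indices=True)
    nearest = nuclei[ir, ic]  # label of the nearest nucleus pixel
    annulus_band = (~any_nucleus) & (dist > inner_margin) & (dist <= outer_margin)

    per_label: dict[int, float] = {}
    for lab in labels:
        sel = annulus_band & (nearest == lab)
        if sel.any():
            per_label[int(lab)] = float(channel[sel].mean())
        else:
            log.warning(
                "nucleus %d: annulus fully occluded, using global background", lab
            )
            per_label[int(lab)] = gmean
    return BackgroundEstimate(global_mean=gmean, per_label=per_label)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask from a TIFF/PNG file (non-zero = selected)."""
    from imageio.v3 import imread

    arr = imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0
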