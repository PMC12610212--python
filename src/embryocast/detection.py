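"""Active-nucleus calling from two-channel frames and label masks.

A nucleus is called active when the prevalence of bright green (nascent
transcription) pixels inside its mask exceeds a fraction threshold. The rule
is two-staged: a per-pixel intensity cutoff (Otsu-derived by default) decides
which pixels count as "green", and a per-nucleus prevalence threshold (default
0.05) on the fraction of such pixels decides the active call. Both thresholds
are exposed.

Segmentation itself is external: :func:`segment_adapter` wraps an optional
deep-learning segmenter behind a capability check, and everything downstream
consumes integer label masks regardless of their origin.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .types import FrameTable, NUCLEUS_COLUMNS, empty_nuclei

#: Default per-nucleus green-pixel prevalence required for an active call.
DEFAULT_PREVALENCE = 0.05


class SegmenterUnavailableError(RuntimeError):
    """The external segmenter is not installed in this environment."""


def _split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError(
            f"expected a channels-first (2, H, W) image, got shape {image.shape}"
        )
    return image[0], image[1]


def otsu_cutoff(green: np.ndarray) -> float:
    """Otsu threshold of the green channel; for a constant channel returns a
    cutoff above the maximum so that no pixel counts as green."""
    from skimage.filters import threshold_otsu

    if green.size == 0 or np.ptp(green) == 0:
        return float(green.max() if green.size else 0) + 1.0
    return float(threshold_otsu(green))


def extract_nuclei(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    intensity_cutoff: float | None = None,
    prevalence_threshold: float = DEFAULT_PREVALENCE,
    video_id: str = "v0",
    frame_id: int = 0,
    stage: str = "NC13",
    genotype: str = "sogD",
) -> FrameTable:
    """Tabulate nuclei from a two-channel frame plus integer label mask.

    One record per distinct positive label: unweighted pixel centroid
    (``x_ap``, ``y_dv``), area in pixels², the fraction of member pixels whose
    green intensity exceeds ``intensity_cutoff`` (Otsu-derived when None), and
    the active flag (``green_fraction >= prevalence_threshold``). A mask with
    no positive labels yields an empty table.
    """
    red, green = _split_channels(image)
    mask = np.asarray(mask)
    if mask.shape != green.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image plane {green.shape}"
        )
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must have an integer dtype")
    if not 0.0 <= prevalence_threshold <= 1.0:
        raise ValueError("prevalence_threshold must lie in [0, 1]")
    h, w = mask.shape
    if mask.max(initial=0) <= 0:
        return FrameTable(video_id, frame_id, stage, genotype, w, h, empty_nuclei())

    if intensity_cutoff is None:
        intensity_cutoff = otsu_cutoff(green)

    rows = []
    for region in regionprops(mask.astype(np.int64)):
        cy, cx = region.centroid  # (row, col) = (DV, AP)
        member = green[region.coords[:, 0], region.coords[:, 1]]
        frac = float(np.mean(member > intensity_cutoff))
        rows.append(
            {
                "nucleus_id": int(region.label),
                "x_ap": float(cx),
                "y_dv": float(cy),
                "area_px": float(region.area),
                "green_fraction": frac,
                "active": frac >= prevalence_threshold,
            }
        )
    nuclei = pd.DataFrame(rows, columns=list(NUCLEUS_COLUMNS))
    return FrameTable(video_id, frame_id, stage, genotype, w, h, nuclei)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a precomputed label mask (TIFF or PNG) as an integer array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        mask = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        mask = iio.imread(path)
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError(f"{path} is not an integer label mask (dtype {mask.dtype})")
    return mask


def segment_adapter(
    image: np.ndarray | None = None,
    *,
    mask_path: str | Path | None = None,
    diameter: float | None = None,
) -> np.ndarray:
    """Produce an integer label mask, via a precomputed file or an external
    deep-learning segmenter.

    When ``mask_path`` is given the adapter is bypassed and the mask loaded
    verbatim. Otherwise the image is sent through Cellpose if it is importable;
    if not, a :class:`SegmenterUnavailableError` explains how to supply
    precomputed masks instead. Downstream code treats the returned mask as
    opaque — its origin never matters.
    """
    if mask_path is not None:
        return load_mask(mask_path)
    if image is None:
        raise ValueError("provide either an image or a mask_path")
    try:
        from cellpose import models  # type: ignore[import-not-found]
    except ImportError as exc:
        raise SegmenterUnavailableError(
            "cellpose is not installed; pass mask_path= to use a precomputed "
            "label mask, or install cellpose to segment images directly"
        ) from exc
    red, _ = _split_channels(image)
    if red.max(initial=0) == 0:
        return np.zeros_like(red, dtype=np.uint16)
    model = models.Cellpose(model_type="nuclei")
    masks, *_ = model.eval(red, diameter=diameter, channels=[0, 0])
    return masks.astype(np.uint16)
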