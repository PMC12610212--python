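"""Shared domain containers for staged embryo movies.

A movie is an ordered collection of frames; each frame carries the nuclei
segmented in it, with centroid positions in image coordinates (origin at the
top-left, ``x_ap`` along the anterior–posterior axis pointing right, ``y_dv``
along the dorsal–ventral axis pointing down, pixel units, 0-based) and an
active/inactive transcription call per nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Developmental stages in chronological order: nuclear cycle 13 followed by
#: the four sub-stages of nuclear cycle 14.
STAGE_ORDER: tuple[str, ...] = ("NC13", "NC14A", "NC14B", "NC14C", "NC14D")

#: Genotype labels: the wild-type sog distal enhancer reporter and the variant
#: with Su(H) binding sites mutated.
GENOTYPES: tuple[str, str] = ("sogD", "sogD_dSuH")

#: Column order of the per-nucleus table inside a :class:`FrameTable`.
NUCLEUS_COLUMNS: tuple[str, ...] = (
    "nucleus_id",
    "x_ap",
    "y_dv",
    "area_px",
    "green_fraction",
    "active",
)


def stage_index(stage: str) -> int:
    """Position of *stage* in the chronological stage ordering."""
    try:
        return STAGE_ORDER.index(stage)
    except ValueError:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {STAGE_ORDER}"
        ) from None


@dataclass
class FrameTable:
    """All nuclei of one movie frame plus its stage/genotype context.

    ``nuclei`` is a DataFrame with columns :data:`NUCLEUS_COLUMNS`: integer
    ``nucleus_id`` (unique within the frame), centroid coordinates ``x_ap`` /
    ``y_dv`` in pixels, ``area_px`` in pixels², ``green_fraction`` in [0, 1]
    (fraction of in-mask pixels above the green intensity cutoff) and the
    boolean ``active`` call.
    """

    video_id: str
    frame_id: int
    stage: str
    genotype: str
    image_width: int
    image_height: int
    nuclei: pd.DataFrame = field(default_factory=lambda: empty_nuclei())

    def __post_init__(self) -> None:
        stage_index(self.stage)  # validates the label
        missing = set(NUCLEUS_COLUMNS) - set(self.nuclei.columns)
        if missing:
            raise ValueError(f"nuclei table missing columns {sorted(missing)}")
        ids = self.nuclei["nucleus_id"]
        if ids.duplicated().any():
            raise ValueError("nucleus_ids must be unique within a frame")
        if len(self.nuclei):
            x = self.nuclei["x_ap"].to_numpy()
            y = self.nuclei["y_dv"].to_numpy()
            if (
                (x < 0).any()
                or (y < 0).any()
                or (x >= self.image_width).any()
                or (y >= self.image_height).any()
            ):
                raise ValueError("nucleus centroid outside image bounds")

    @property
    def n_active(self) -> int:
        return int(self.nuclei["active"].sum())

    def active_positions(self) -> pd.DataFrame:
        """``x_ap``/``y_dv`` of the active nuclei only."""
        return self.nuclei.loc[self.nuclei["active"], ["x_ap", "y_dv"]]


def empty_nuclei() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": pd.Series(dtype=int),
            "x_ap": pd.Series(dtype=float),
            "y_dv": pd.Series(dtype=float),
            "area_px": pd.Series(dtype=float),
            "green_fraction": pd.Series(dtype=float),
            "active": pd.Series(dtype=bool),
        }
    )


def frames_to_dataframe(frames: Iterable[FrameTable]) -> pd.DataFrame:
    """Flatten frame tables into one long per-nucleus DataFrame."""
    parts = []
    for f in frames:
        part = f.nuclei.copy()
        part.insert(0, "video_id", f.video_id)
        part.insert(1, "frame_id", f.frame_id)
        part.insert(2, "stage", f.stage)
        part.insert(3, "genotype", f.genotype)
        part.insert(4, "image_width", f.image_width)
        part.insert(5, "image_height", f.image_height)
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=[
                "video_id",
                "frame_id",
                "stage",
                "genotype",
                "image_width",
                "image_height",
                *NUCLEUS_COLUMNS,
            ]
        )
    return pd.concat(parts, ignore_index=True)


def write_frames_csv(frames: Iterable[FrameTable], path: str | Path) -> None:
    frames_to_dataframe(frames).to_csv(path, index=False)


def read_frames_csv(path: str | Path) -> list[FrameTable]:
    """Inverse of :func:`write_frames_csv` (frame order = file order)."""
    df = pd.read_csv(path)
    frames: list[FrameTable] = []
    keys = ["video_id", "frame_id", "stage", "genotype"]
    for (vid, fid, stage, geno), grp in df.groupby(keys, sort=False):
        frames.append(
            FrameTable(
                video_id=str(vid),
                frame_id=int(fid),
                stage=str(stage),
                genotype=str(geno),
                image_width=int(grp["image_width"].iloc[0]),
                image_height=int(grp["image_height"].iloc[0]),
                nuclei=grp[list(NUCLEUS_COLUMNS)]
                .astype({"nucleus_id": int, "active": bool})
                .reset_index(drop=True),
            )
        )
    return frames


def sort_frames(frames: Sequence[FrameTable]) -> list[FrameTable]:
    """Order frames by (video, stage chronology, frame index)."""
    return sorted(
        frames, key=lambda f: (f.video_id, stage_index(f.stage), f.frame_id)
    )
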