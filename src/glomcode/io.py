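"""Reading, writing and validating the pipeline's standard file formats.

Movies are multi-frame TIFF stacks (frame-major), glomerular masks are
integer label-image TIFFs (0 = background) with a JSON sidecar mapping
labels to glomerulus names, all tables are long-format CSV checked
against explicit schemas, and configurations travel as JSON or YAML.

Frame indices are 0-based and windows are half-open, ``[start, end)``.
Glomerulus names are opaque strings; no atlas validation is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "StimulusProtocol",
    "GlomerulusMask",
    "TableSchema",
    "TRACE_SCHEMA",
    "AMPLITUDE_SCHEMA",
    "VOLUME_SCHEMA",
    "TRAP_SCHEMA",
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus timing in frame units.

    ``stim_onset``/``stim_offset`` delimit the half-open stimulus window
    ``[onset, offset)``; ``n_frames`` is the trial length.  With the
    default acquisition (10 Hz, 3 s stimulus after 2 s of baseline) the
    stimulus window covers exactly 30 frames.
    """

    frame_rate: float
    stim_onset: int
    stim_offset: int
    n_frames: int

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0 <= self.stim_onset < self.stim_offset <= self.n_frames):
            raise ValueError(
                f"need 0 <= onset < offset <= n_frames, got "
                f"({self.stim_onset}, {self.stim_offset}, {self.n_frames})"
            )

    @property
    def stim_slice(self) -> slice:
        return slice(self.stim_onset, self.stim_offset)

    @property
    def baseline_slice(self) -> slice:
        """Default pre-stimulus baseline: everything before stimulus onset."""
        return slice(0, self.stim_onset)

    def to_dict(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "stim_onset": self.stim_onset,
            "stim_offset": self.stim_offset,
            "n_frames": self.n_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            frame_rate=float(d["frame_rate"]),
            stim_onset=int(d["stim_onset"]),
            stim_offset=int(d["stim_offset"]),
            n_frames=int(d["n_frames"]),
        )


@dataclass
class GlomerulusMask:
    """Integer label image plus a label -> glomerulus-name map.

    Label 0 is background.  Every positive label occurring in the image
    must be named and non-empty; this is validated on construction.
    """

    labels: np.ndarray
    names: dict[int, str]
    plane: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        present = set(np.unique(self.labels)) - {0}
        unnamed = sorted(present - set(self.names))
        if unnamed:
            raise ValueError(f"labels without a name: {unnamed}")
        empty = sorted(set(self.names) - present)
        if empty:
            raise ValueError(f"named labels with empty regions: {empty}")

    @classmethod
    def from_regions(
        cls,
        regions: list[np.ndarray],
        names: list[str],
        plane: int | None = None,
    ) -> "GlomerulusMask":
        """Build a label image from boolean region masks; rejects overlaps."""
        if len(regions) != len(names):
            raise ValueError("regions and names differ in length")
        if not regions:
            raise ValueError("no regions given")
        shape = regions[0].shape
        cover = np.zeros(shape, dtype=np.int32)
        labels = np.zeros(shape, dtype=np.int32)
        for i, reg in enumerate(regions, start=1):
            reg = np.asarray(reg, dtype=bool)
            if reg.shape != shape:
                raise ValueError("region shapes differ")
            cover += reg
            labels[reg] = i
        if cover.max() > 1:
            raise ValueError("overlapping regions")
        return cls(labels, {i + 1: n for i, n in enumerate(names)}, plane)

    def region_pixels(self, label: int) -> np.ndarray:
        if label not in self.names:
            raise KeyError(f"unknown mask label {label}")
        return self.labels == label

    @property
    def sorted_labels(self) -> list[int]:
        return sorted(self.names)


# ---------------------------------------------------------------------------
# Movies


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    """Write a frame-major image stack as a multi-frame TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("movie stack must be (frames, height, width)")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    """Read a multi-frame TIFF; frames must be uniform in shape."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tf:
        shapes = {page.shape for page in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"non-uniform frame shapes in {path}: {sorted(shapes)}")
        stack = tf.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    return stack


# ---------------------------------------------------------------------------
# Masks


def write_mask(mask: GlomerulusMask, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), mask.labels.astype(np.int32), photometric="minisblack")
    sidecar = {"names": {str(k): v for k, v in mask.names.items()}, "plane": mask.plane}
    path.with_suffix(path.suffix + ".names.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def read_mask(path: str | Path) -> GlomerulusMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    labels = tifffile.imread(str(path))
    sidecar_path = path.with_suffix(path.suffix + ".names.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"mask name sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    names = {int(k): v for k, v in sidecar["names"].items()}
    return GlomerulusMask(labels, names, sidecar.get("plane"))


# ---------------------------------------------------------------------------
# Tables


@dataclass(frozen=True)
class TableSchema:
    """Declared CSV layout: required columns, dtypes and unique-key set."""

    name: str
    columns: dict = field(default_factory=dict)  # column -> numpy dtype kind
    key: tuple = ()

    def validate(self, df: pd.DataFrame, where: str = "<table>") -> pd.DataFrame:
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise ValueError(f"{where}: missing columns {missing} (schema {self.name})")
        out = df.copy()
        for col, kind in self.columns.items():
            if kind == "i":
                coerced = pd.to_numeric(out[col], errors="coerce")
                bad = coerced.isna() & out[col].notna()
                if bad.any():
                    rows = list(out.index[bad][:5])
                    raise ValueError(
                        f"{where}: non-integer values in column {col!r}, rows {rows}"
                    )
                out[col] = coerced.astype("int64")
            elif kind == "f":
                out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
            else:
                out[col] = out[col].astype(str)
        if self.key:
            dup = out.duplicated(subset=list(self.key))
            if dup.any():
                rows = list(out.index[dup][:5])
                raise ValueError(
                    f"{where}: duplicate keys {self.key} at rows {rows} "
                    f"({int(dup.sum())} duplicates total)"
                )
        return out


TRACE_SCHEMA = TableSchema(
    name="traces",
    columns={
        "species": "s", "fly": "s", "side": "s", "plane": "i",
        "glomerulus": "s", "odour": "s", "trial": "i", "frame": "i",
        "value": "f",
    },
    key=("species", "fly", "side", "glomerulus", "odour", "trial", "frame"),
)

AMPLITUDE_SCHEMA = TableSchema(
    name="amplitudes",
    columns={
        "species": "s", "fly": "s", "side": "s", "glomerulus": "s",
        "odour": "s", "amplitude": "f", "n_trials": "i", "provenance": "s",
    },
    key=("species", "fly", "side", "glomerulus", "odour"),
)

VOLUME_SCHEMA = TableSchema(
    name="volumes",
    columns={
        "species": "s", "fly": "s", "side": "s", "glomerulus": "s",
        "volume_um3": "f",
    },
    key=("species", "fly", "side", "glomerulus"),
)

TRAP_SCHEMA = TableSchema(
    name="trap_counts",
    columns={
        "species": "s", "condition": "s", "replicate": "i",
        "bait1": "i", "bait2": "i", "oil": "i", "empty": "i", "platform": "i",
    },
    key=("species", "condition", "replicate"),
)


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> None:
    if schema is not None:
        df = schema.validate(df, where=str(path))
    df.to_csv(path, index=False)


def read_table(path: str | Path, schema: TableSchema | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if schema is not None:
        df = schema.validate(df, where=str(path))
    return df


# ---------------------------------------------------------------------------
# Configs


def save_config(obj: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(obj, sort_keys=True))
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
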