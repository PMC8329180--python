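"""Stack I/O: multi-page TIFF and uncompressed AVI with JSON sidecars.

Every artefact written by the pipeline carries its acquisition metadata
(frame rate, timestamps, geometry, seed) in a JSON sidecar next to the
image container, plus a provenance record (tool version, parameter and
input hashes) so outputs are self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from . import __version__ as _version
from .avi import read_avi, write_avi
from .errors import UnsupportedFormatError
from .geometry import FieldGeometry
from .synth.dye import AngioSequence

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used when an RGB video must be collapsed
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class ProvenanceRecord:
    """What produced an artefact: version, parameters, input hashes."""

    tool_version: str = _version
    stage: str = ""
    parameters: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "stage": self.stage,
            "parameters": self.parameters,
            "input_hashes": self.input_hashes,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def hash_array(a: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(str(a.shape).encode())
    h.update(str(a.dtype).encode())
    h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(path, frames: np.ndarray, metadata: Optional[dict] = None) -> None:
    """Write a (t, y, x) stack as multi-page TIFF or uncompressed AVI.

    Format follows the extension (.tif/.tiff/.avi). Metadata goes into a
    JSON sidecar (and, for TIFF, into the image description as well).
    """
    path = Path(path)
    frames = np.asarray(frames)
    metadata = dict(metadata or {})
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames, description=json.dumps(metadata))
    elif path.suffix.lower() == ".avi":
        fps = float(metadata.get("fps", 15.0))
        write_avi(path, frames.astype(np.uint8), fps=fps)
    else:
        raise UnsupportedFormatError(f"unsupported output container: {path.suffix}")
    if metadata:
        sidecar_path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_stack(path, expected_kind: str = "video"):
    """Read a frame stack plus merged metadata.

    Supports multi-page TIFF and uncompressed 8-bit AVI. RGB frames are
    collapsed to grayscale with BT.601 luma weights (logged). A missing
    sidecar falls back to declared defaults with a warning.

    Returns ``(frames, metadata)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    meta: dict = {}
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        try:
            with tifffile.TiffFile(path) as tf:
                desc = tf.pages[0].description
            if desc:
                meta.update(json.loads(desc))
        except (json.JSONDecodeError, AttributeError):
            pass
    elif suffix == ".avi":
        frames, fps = read_avi(path)
        meta["fps"] = fps
    else:
        raise UnsupportedFormatError(f"unsupported container: {path.suffix}")

    sp = sidecar_path(path)
    if sp.exists():
        meta.update(json.loads(sp.read_text()))
    else:
        logger.warning("no sidecar for %s; using declared defaults", path.name)
        meta.setdefault("fps", 15.0)
        meta.setdefault("pixel_pitch_um", 11.71875)

    frames = np.asarray(frames)
    if frames.ndim == 2 and expected_kind == "video":
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        logger.info("RGB input collapsed to grayscale with luma weights %s", LUMA_WEIGHTS)
        frames = rgb_to_gray(frames)
    elif frames.ndim == 3 and expected_kind == "image" and frames.shape[-1] in (3, 4):
        frames = rgb_to_gray(frames)
    return frames, meta


def rgb_to_gray(frames: np.ndarray) -> np.ndarray:
    """Collapse an (..., 3|4)-channel image to grayscale (BT.601 luma)."""
    rgb = np.asarray(frames, dtype=np.float64)[..., :3]
    gray = rgb @ np.asarray(LUMA_WEIGHTS)
    if np.issubdtype(np.asarray(frames).dtype, np.integer):
        return np.floor(gray + 0.5).astype(np.asarray(frames).dtype)
    return gray


def write_angio_sequence(path, seq: AngioSequence, include_ground_truth: bool = True):
    """Write a simulated acquisition: frames + sidecar (+ ground truth).

    The ground truth goes to ``<stem>_ground_truth.tiff`` with the arrival
    map as 32-bit float, the ownership map as 16-bit integer labels and
    the slow-zone mask as 8-bit, one page each.
    """
    path = Path(path)
    g = seq.geometry
    meta = {
        "fps": seq.fps,
        "timestamps_s": [float(t) for t in seq.timestamps_s],
        "geometry": {
            "width_mm": g.width_mm,
            "height_mm": g.height_mm,
            "grid_nx": g.grid_nx,
            "grid_ny": g.grid_ny,
            "disc_center_mm": list(g.disc_center_mm),
        },
        "pixel_pitch_um": g.pixel_pitch_um,
    }
    write_stack(path, seq.frames, meta)
    gt_path = None
    if include_ground_truth and seq.ground_truth is not None:
        gt = seq.ground_truth
        gt_path = path.with_name(path.stem + "_ground_truth.tiff")
        arrival = np.where(
            np.isfinite(gt["arrival_s"]), gt["arrival_s"], -1.0
        ).astype(np.float32)
        with tifffile.TiffWriter(gt_path) as tw:
            tw.write(arrival, description="arrival_s (-1 = never)")
            tw.write(gt["ownership"].astype(np.int16), description="ownership")
            tw.write(
                gt["zone_mask"].astype(np.uint8) * 255, description="zone_mask"
            )
    return path, gt_path


def read_angio_sequence(path) -> AngioSequence:
    """Read a sequence written by :func:`write_angio_sequence`."""
    frames, meta = read_stack(path, expected_kind="video")
    g = meta.get("geometry", {})
    geometry = FieldGeometry(
        width_mm=g.get("width_mm", 3.0),
        height_mm=g.get("height_mm", 3.0),
        grid_nx=g.get("grid_nx", frames.shape[2]),
        grid_ny=g.get("grid_ny", frames.shape[1]),
        disc_center_mm=tuple(g.get("disc_center_mm", (-1.0, 1.5))),
    )
    ts = meta.get("timestamps_s")
    fps = float(meta.get("fps", 15.0))
    timestamps = np.asarray(ts) if ts else np.arange(len(frames)) / fps
    return AngioSequence(
        frames=frames, fps=fps, timestamps_s=timestamps, geometry=geometry
    )
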