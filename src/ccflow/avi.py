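"""Minimal uncompressed AVI reader/writer for 8-bit grayscale video.

Dynamic angiography exports are plain RIFF/AVI containers holding
uncompressed device-independent bitmaps (biCompression = 0, 8 bits per
pixel with a grayscale palette, bottom-up rows padded to 4 bytes). This
module writes exactly that layout and reads it back; anything compressed
or deeper than 8 bits is rejected explicitly rather than misread.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import UnsupportedFormatError

_AVIF_HASINDEX = 0x10
_AVIIF_KEYFRAME = 0x10


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write a (t, y, x) uint8 stack as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be a (t, y, x) uint8 array")
    n, h, w = frames.shape
    row_bytes = (w + 3) & ~3
    frame_bytes = row_bytes * h

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    rate = max(int(round(fps * 1000)), 1)
    scale = 1000
    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # microseconds per frame
        frame_bytes * int(round(fps)),
        0,
        _AVIF_HASINDEX,
        n,
        0,
        1,
        frame_bytes,
        w,
        h,
        0,
        0,
        0,
        0,
    )
    strh = (
        b"vids"
        + b"DIB "
        + struct.pack("<IHHIIIIIIIi", 0, 0, 0, 0, scale, rate, 0, n, frame_bytes, 0, 0)
        + struct.pack("<4h", 0, 0, w, h)
    )
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 0)
    palette = b"".join(struct.pack("<4B", g, g, g, 0) for g in range(256))
    strf = bmih + palette

    hdrl = lst(
        b"hdrl",
        chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)),
    )

    movi_payload = b""
    index_entries = []
    offset = 4  # relative to the 'movi' fourcc
    for f in frames:
        dib = np.zeros((h, row_bytes), dtype=np.uint8)
        dib[:, :w] = f[::-1]  # bottom-up rows
        data = dib.tobytes()
        movi_payload += chunk(b"00db", data)
        index_entries.append((offset, len(data)))
        offset += 8 + len(data) + (len(data) % 2)
    movi = lst(b"movi", movi_payload)

    idx1 = b"".join(
        b"00db" + struct.pack("<3I", _AVIIF_KEYFRAME, off, size)
        for off, size in index_entries
    )
    body = b"AVI " + hdrl + movi + chunk(b"idx1", idx1)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 8-bit AVI; returns ``(frames, fps)``.

    Raises
    ------
    UnsupportedFormatError
        For compressed streams or bit depths other than 8.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise UnsupportedFormatError(f"{path} is not an AVI file")

    width = height = None
    fps = None
    frames_raw: list[bytes] = []

    def walk(buf: bytes):
        nonlocal width, height, fps
        pos = 0
        while pos + 8 <= len(buf):
            fourcc = buf[pos : pos + 4]
            (size,) = struct.unpack("<I", buf[pos + 4 : pos + 8])
            payload = buf[pos + 8 : pos + 8 + size]
            if fourcc == b"LIST":
                walk(payload[4:])
            elif fourcc == b"strh" and payload[:4] == b"vids":
                scale, rate = struct.unpack("<II", payload[20:28])
                if scale:
                    fps = rate / scale
            elif fourcc == b"strf":
                (
                    _bisize,
                    w,
                    h,
                    _planes,
                    bitcount,
                    compression,
                ) = struct.unpack("<IiiHHI", payload[:20])
                if compression != 0:
                    raise UnsupportedFormatError(
                        f"compressed AVI stream (biCompression={compression}); "
                        "only uncompressed grayscale is supported"
                    )
                if bitcount != 8:
                    raise UnsupportedFormatError(
                        f"{bitcount}-bit AVI stream; only 8-bit is supported"
                    )
                width, height = w, abs(h)
            elif fourcc in (b"00db", b"00dc"):
                frames_raw.append(payload)
            pos += 8 + size + (size % 2)

    walk(data[12:])
    if width is None or not frames_raw:
        raise UnsupportedFormatError(f"no uncompressed video stream found in {path}")

    row_bytes = (width + 3) & ~3
    frames = np.empty((len(frames_raw), height, width), dtype=np.uint8)
    for i, raw in enumerate(frames_raw):
        dib = np.frombuffer(raw[: row_bytes * height], dtype=np.uint8)
        dib = dib.reshape(height, row_bytes)
        frames[i] = dib[::-1, :width]
    return frames, float(fps if fps else 15.0)
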