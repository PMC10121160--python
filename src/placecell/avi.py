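"""Minimal uncompressed 8-bit grayscale AVI ("GREY"/"Y800") read/write.

Behavior and scope videos are saved as RIFF/AVI containers with raw 8-bit
frames ('00db' chunks) and no compression.  This module implements exactly
that subset: one video stream, fourcc GREY or Y800 (or biCompression 0 with
8-bit depth), frames stored top-down in acquisition order.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_GRAY_FOURCC = {b"GREY", b"Y800", b"Y8  ", b"\x00\x00\x00\x00"}


def write_gray_avi(path: str | Path, frames: np.ndarray, fps: float = 30.0) -> None:
    """Write (n, h, w) uint8 frames as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be (n, h, w) uint8")
    n, h, w = frames.shape
    frame_bytes = h * w

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(list_type: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", list_type + payload)

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # dwMicroSecPerFrame
        int(frame_bytes * fps),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIiI4H",
        b"vids", b"GREY", 0, 0, 0, 0,
        1000, int(round(fps * 1000)),  # dwScale, dwRate
        0, n, frame_bytes, -1, 0,  # start, length, bufsize, quality, samplesize
        0, 0, w, h,
    )
    strf = struct.pack(
        "<IiiHHIIiiII",
        40, w, h, 1, 8, int.from_bytes(b"GREY", "little"),
        frame_bytes, 0, 0, 0, 0,
    )
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))
    movi_payload = b"".join(chunk(b"00db", frames[i].tobytes()) for i in range(n))
    movi = lst(b"movi", movi_payload)
    # idx1: one entry per frame
    idx_entries = []
    offset = 4  # from start of movi list data ('movi' fourcc counts as offset 0..4)
    padded = frame_bytes + (frame_bytes % 2)
    for _ in range(n):
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, offset, frame_bytes))
        offset += 8 + padded
    idx1 = chunk(b"idx1", b"".join(idx_entries))
    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as f:
        f.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def read_gray_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed grayscale AVI; returns (frames, fps)."""
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError("not a RIFF/AVI file")

    width = height = None
    fps = 30.0
    frames: list[np.ndarray] = []

    def walk(buf: bytes, start: int, end: int):
        nonlocal width, height, fps
        pos = start
        while pos + 8 <= end:
            fourcc = buf[pos : pos + 4]
            (size,) = struct.unpack("<I", buf[pos + 4 : pos + 8])
            body = pos + 8
            if fourcc == b"LIST":
                walk(buf, body + 4, body + size)
            elif fourcc == b"strh":
                fcc_type, _handler = buf[body : body + 4], buf[body + 4 : body + 8]
                if fcc_type == b"vids":
                    scale, rate = struct.unpack("<II", buf[body + 20 : body + 28])
                    if scale:
                        fps = rate / scale
            elif fourcc == b"strf" and width is None:
                (_bisize, w, h, _planes, bits, comp) = struct.unpack(
                    "<IiiHHI", buf[body : body + 20]
                )
                if bits != 8 or comp.to_bytes(4, "little") not in _GRAY_FOURCC:
                    raise ValueError("AVI is not uncompressed 8-bit grayscale")
                width, height = w, abs(h)
            elif fourcc in (b"00db", b"00dc"):
                if width is None:
                    raise ValueError("frame chunk before stream format header")
                raw = buf[body : body + size]
                if len(raw) != width * height:
                    raise ValueError("frame chunk size does not match dimensions")
                frames.append(
                    np.frombuffer(raw, dtype=np.uint8).reshape(height, width)
                )
            pos = body + size + (size % 2)

    walk(data, 12, len(data))
    if not frames:
        raise ValueError("AVI contains no frames")
    return np.stack(frames), fps
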