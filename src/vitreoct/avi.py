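"""Minimal uncompressed RIFF-AVI reader and writer.

Only the plain 'DIB ' (biCompression == 0) video stream variant is handled:
24-bit BGR frames stored bottom-up with 4-byte-aligned rows, exactly what a
lossless grayscale OCT export needs for a pixel-identical round trip.  No
audio, no compressed codecs, no OpenDML extensions.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .exceptions import FormatError

__all__ = ["read_avi", "write_avi"]

_AVIH = struct.Struct("<14I")
_STRH = struct.Struct("<4s4sI2H8I4h")
_BMIH = struct.Struct("<I2i2H2I2i2I")


def _pad_width(width: int) -> int:
    # DIB rows are padded to 32-bit boundaries
    return (width * 3 + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, fps: int = 25) -> None:
    """Write grayscale or RGB frames as an uncompressed 24-bit AVI.

    ``frames`` is (n, h, w) grayscale or (n, h, w, 3) RGB, uint8.  Grayscale
    frames are stored with the value replicated on all three channels, so a
    read-back plus BT.601 grayscale conversion is the identity.
    """
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise FormatError("AVI frames must be uint8")
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise FormatError(f"expected (n,h,w) or (n,h,w,3) frames, got {frames.shape}")
    n, h, w, _ = frames.shape
    row_bytes = _pad_width(w)
    frame_bytes = row_bytes * h

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        out = fourcc + struct.pack("<I", len(payload)) + payload
        if len(payload) % 2:
            out += b"\x00"
        return out

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    avih = _AVIH.pack(
        int(1e6 / fps), frame_bytes * fps, 0, 0x10, n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0
    )
    strh = _STRH.pack(
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, n, frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h
    )
    strf = _BMIH.pack(40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))

    movi_payload = bytearray(b"movi")
    index = bytearray()
    for frame in frames:
        # BGR, bottom-up, padded rows
        bgr = frame[::-1, :, ::-1]
        data = np.zeros((h, row_bytes), dtype=np.uint8)
        data[:, : w * 3] = bgr.reshape(h, w * 3)
        offset = len(movi_payload)
        movi_payload += chunk(b"00db", data.tobytes())
        index += b"00db" + struct.pack("<3I", 0x10, offset, frame_bytes)
    movi = chunk(b"LIST", bytes(movi_payload))
    idx1 = chunk(b"idx1", bytes(index))

    riff_payload = b"AVI " + hdrl + movi + idx1
    Path(path).write_bytes(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> np.ndarray:
    """Read an uncompressed 24-bit AVI into an (n, h, w, 3) RGB uint8 array."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise FormatError(f"{path}: not a RIFF/AVI file")

    width = height = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"strf" and size >= 40:
                fields = _BMIH.unpack_from(buf, data_pos)
                if fields[4] != 24 or fields[5] != 0:
                    raise FormatError(
                        f"{path}: only uncompressed 24-bit AVI is supported "
                        f"(bit count {fields[4]}, compression {fields[5]})"
                    )
                width, height = fields[1], abs(fields[2])
            elif fourcc[2:] in (b"db", b"dc") and size > 0:
                if width is None:
                    raise FormatError(f"{path}: video frame before stream format header")
                row_bytes = _pad_width(width)
                if size < row_bytes * height:
                    raise FormatError(f"{path}: truncated frame chunk")
                raw = np.frombuffer(buf, np.uint8, row_bytes * height, data_pos)
                rows = raw.reshape(height, row_bytes)[:, : width * 3]
                # bottom-up BGR -> top-down RGB
                frames.append(rows.reshape(height, width, 3)[::-1, :, ::-1].copy())

    walk(12, len(buf))
    if not frames:
        raise FormatError(f"{path}: no video frames found")
    return np.stack(frames)
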