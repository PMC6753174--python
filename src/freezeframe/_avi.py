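"""Minimal lossless AVI (RIFF) reader and writer for grayscale video.

Frames are stored as uncompressed device-independent bitmaps (``DIB``,
``biCompression = BI_RGB``), 8 bits per pixel with an identity grayscale
palette. Uncompressed storage keeps the pixel values bit-exact through a
write/read round trip, which the analysis pipeline relies on: a lossy codec
would inject frame-to-frame differences that masquerade as animal motion.

Only the subset of the AVI container needed for single-stream grayscale
video is implemented: one ``vids`` stream, ``00db`` frame chunks and an
``idx1`` index. 24-bit BGR frames are accepted on read (converted to
luma) so externally produced uncompressed files remain usable.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from pathlib import Path

import numpy as np

from .errors import VideoIOError

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010

# ITU-R BT.601 luma weights, used wherever color input must become one channel
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def _fps_to_rational(fps: float) -> tuple[int, int]:
    """fps -> (rate, scale) with fps = rate / scale."""
    frac = Fraction(fps).limit_denominator(100_000)
    return frac.numerator, frac.denominator


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write a (n_frames, height, width) uint8 stack as an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise VideoIOError(f"expected (n, h, w) grayscale stack, got shape {frames.shape}")
    if frames.dtype != np.uint8:
        raise VideoIOError(f"expected uint8 frames, got {frames.dtype}")
    n, height, width = frames.shape
    if fps <= 0:
        raise VideoIOError(f"fps must be positive, got {fps}")

    rate, scale = _fps_to_rational(fps)
    row_bytes = _pad4(width)
    frame_bytes = row_bytes * height

    avih = struct.pack(
        "<14I",
        round(1e6 * scale / rate),  # dwMicroSecPerFrame
        frame_bytes * max(1, round(fps)),  # dwMaxBytesPerSec (advisory)
        0,  # dwPaddingGranularity
        _AVIF_HASINDEX,
        n,  # dwTotalFrames
        0,  # dwInitialFrames
        1,  # dwStreams
        frame_bytes,  # dwSuggestedBufferSize
        width,
        height,
        0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2H8I4h",
        b"vids", b"DIB ",
        0, 0, 0,  # flags, priority, language
        0,  # initial frames
        scale, rate,
        0,  # start
        n,  # length in frames
        frame_bytes,  # suggested buffer size
        0xFFFFFFFF,  # quality: default
        0,  # sample size (0: varies)
        0, 0, width, height,  # rcFrame
    )
    bmih = struct.pack(
        "<IiiHHIIiiII",
        40, width, height, 1, 8,
        0,  # BI_RGB: uncompressed
        frame_bytes, 0, 0, 256, 0,
    )
    palette = bytes(
        b for v in range(256) for b in (v, v, v, 0)  # identity gray RGBQUADs
    )
    strf = bmih + palette

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        return fourcc + struct.pack("<I", len(payload)) + payload + (b"\0" * (len(payload) & 1))

    def list_chunk(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    # DIB frames are stored bottom-up with rows padded to 4 bytes
    if row_bytes == width:
        raster = frames[:, ::-1, :]
    else:
        raster = np.zeros((n, height, row_bytes), dtype=np.uint8)
        raster[:, :, :width] = frames[:, ::-1, :]

    movi_items = []
    index_entries = []
    offset = 4  # offsets in idx1 count from the 'movi' fourcc
    for i in range(n):
        data = raster[i].tobytes()
        movi_items.append(chunk(b"00db", data))
        index_entries.append(struct.pack("<4s3I", b"00db", _AVIIF_KEYFRAME, offset, len(data)))
        offset += 8 + _pad4(len(data))
    movi = list_chunk(b"movi", b"".join(movi_items))
    idx1 = chunk(b"idx1", b"".join(index_entries))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(Path(path), "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    """Yield (fourcc, payload_start, payload_size) over a chunk sequence."""
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + _pad4(size)


def is_avi(path: str | Path) -> bool:
    try:
        with open(path, "rb") as fh:
            head = fh.read(12)
    except OSError:
        return False
    return len(head) == 12 and head[:4] == b"RIFF" and head[8:12] == b"AVI "


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns (frames (n, h, w) uint8, fps)."""
    path = Path(path)
    try:
        buf = path.read_bytes()
    except OSError as exc:
        raise VideoIOError(f"cannot read video file {path}: {exc}") from exc
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise VideoIOError(f"{path} is not an AVI (RIFF) file")

    width = height = bitcount = None
    compression = None
    rate = scale = None
    micro_per_frame = None
    palette_luma = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, rate, scale
        nonlocal micro_per_frame, palette_luma
        for fourcc, pstart, psize in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(pstart + 4, pstart + psize)
            elif fourcc == b"avih" and psize >= 56:
                fields = struct.unpack_from("<14I", buf, pstart)
                micro_per_frame = fields[0]
            elif fourcc == b"strh" and psize >= 56:
                ftype, _, _, _, _, _, s, r = struct.unpack_from("<4s4sI2H3I", buf, pstart)
                if ftype == b"vids":
                    scale, rate = s, r
            elif fourcc == b"strf" and psize >= 40 and width is None:
                (_, w, h, _, bc, comp, *_rest) = struct.unpack_from("<IiiHHI", buf, pstart)
                width, height, bitcount, compression = w, h, bc, comp
                if bc == 8 and psize >= 40 + 4 * 256:
                    quads = np.frombuffer(buf, np.uint8, 4 * 256, pstart + 40).reshape(256, 4)
                    # RGBQUAD order is (b, g, r, reserved)
                    luma = (
                        quads[:, 2] * LUMA_WEIGHTS[0]
                        + quads[:, 1] * LUMA_WEIGHTS[1]
                        + quads[:, 0] * LUMA_WEIGHTS[2]
                    )
                    palette_luma = np.clip(luma.round(), 0, 255).astype(np.uint8)
            elif fourcc in (b"00db", b"00dc") and psize > 0:
                frame_chunks.append((pstart, psize))

    walk(12, len(buf))

    if width is None or not frame_chunks:
        raise VideoIOError(f"{path}: no decodable video stream found")
    if compression != 0:
        raise VideoIOError(
            f"{path}: compressed AVI stream (biCompression={compression:#x}) is not supported; "
            "re-encode as uncompressed DIB"
        )
    if bitcount not in (8, 24):
        raise VideoIOError(f"{path}: unsupported bit depth {bitcount}")

    if rate and scale:
        fps = rate / scale
    elif micro_per_frame:
        fps = 1e6 / micro_per_frame
    else:
        raise VideoIOError(f"{path}: no frame-rate information in headers")

    bottom_up = height > 0
    height = abs(height)
    bpp = bitcount // 8
    row_bytes = _pad4(width * bpp)
    frames = np.empty((len(frame_chunks), height, width), dtype=np.uint8)
    for i, (pstart, psize) in enumerate(frame_chunks):
        if psize < row_bytes * height:
            raise VideoIOError(f"{path}: truncated frame chunk {i}")
        raster = np.frombuffer(buf, np.uint8, row_bytes * height, pstart)
        raster = raster.reshape(height, row_bytes)
        if bitcount == 8:
            img = raster[:, :width]
            if palette_luma is not None:
                img = palette_luma[img]
        else:
            bgr = raster[:, : width * 3].reshape(height, width, 3)
            img = (bgr[:, :, ::-1].astype(np.float64) @ LUMA_WEIGHTS).round()
            img = np.clip(img, 0, 255).astype(np.uint8)
        frames[i] = img[::-1] if bottom_up else img
    return frames, float(fps)
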