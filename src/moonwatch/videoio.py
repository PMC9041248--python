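"""Video I/O: numbered PNG sequences and MJPEG-encoded AVI.

Both dialects yield/accept 8-bit grayscale frames and carry no trustworthy
timing — per-frame times always come from the timestamp log
(:mod:`moonwatch.timing`).

The AVI support is a deliberately minimal RIFF container implementation
(``hdrl``/``movi``/``idx1``) around Pillow's JPEG codec: no ffmpeg-backed
writer exists in the supported environment, and MJPEG-in-AVI is just a
sequence of JPEG chunks.  Files it writes play in common players and it
reads back its own output as well as other simple MJPEG AVIs.
"""

from __future__ import annotations

import io
import re
import struct
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
from PIL import Image

__all__ = [
    "write_png_sequence",
    "read_png_sequence",
    "AviWriter",
    "write_avi",
    "read_avi",
    "open_video",
]


# ---------------------------------------------------------------- PNG dialect

def write_png_sequence(
    frames: Iterable[np.ndarray], out_dir: str | Path, prefix: str = "frame", digits: int = 6
) -> list[Path]:
    """Write frames as ``<prefix>_000000.png`` ... under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out_dir / f"{prefix}_{i:0{digits}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_png_sequence(src: str | Path) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (frame_index, gray frame) from a directory of numbered PNGs.

    Indices are parsed from the trailing integer in each filename, so gaps
    in numbering are preserved.
    """
    src = Path(src)
    files = sorted(src.glob("*.png")) if src.is_dir() else sorted(src.parent.glob(src.name))
    if not files:
        raise FileNotFoundError(f"no PNG frames under {src}")
    for p in files:
        m = re.search(r"(\d+)\D*$", p.stem)
        idx = int(m.group(1)) if m else 0
        yield idx, _as_gray(iio.imread(p))


# ---------------------------------------------------------------- AVI dialect

class AviWriter:
    """Streaming MJPEG-in-AVI writer for 8-bit grayscale frames."""

    def __init__(self, path: str | Path, fps: float = 30.0, quality: int = 92) -> None:
        self.path = Path(path)
        self.fps = float(fps)
        self.quality = int(quality)
        self._fh = open(self.path, "wb")
        self._shape: tuple[int, int] | None = None
        self._index: list[tuple[int, int]] = []  # (offset within movi, size)
        self._movi_start: int | None = None
        self._closed = False
        self._fh.write(b"\x00" * 224)  # placeholder for RIFF + hdrl, rewritten on close

    def append(self, frame: np.ndarray) -> None:
        frame = np.asarray(frame, dtype=np.uint8)
        if frame.ndim != 2:
            raise ValueError("AviWriter takes single-channel 8-bit frames")
        if self._shape is None:
            self._shape = frame.shape
            self._fh.seek(224)
            self._fh.write(b"LIST\x00\x00\x00\x00movi")
            self._movi_start = 224 + 8
        elif frame.shape != self._shape:
            raise ValueError("frame size changed mid-stream")
        buf = io.BytesIO()
        Image.fromarray(frame, mode="L").save(buf, format="JPEG", quality=self.quality)
        data = buf.getvalue()
        if len(data) % 2:
            data += b"\x00"
        offset = self._fh.tell() - self._movi_start
        self._fh.write(b"00dc" + struct.pack("<I", len(data)) + data)
        self._index.append((offset, len(data)))

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        if self._shape is None:
            self._fh.close()
            raise ValueError("no frames written")
        height, width = self._shape
        movi_end = self._fh.tell()
        # idx1
        self._fh.write(b"idx1" + struct.pack("<I", 16 * len(self._index)))
        for offset, size in self._index:
            self._fh.write(b"00dc" + struct.pack("<III", 0x10, offset + 4, size))
        file_end = self._fh.tell()

        n = len(self._index)
        usec = int(round(1e6 / self.fps))
        max_size = max(size for _, size in self._index)
        avih = struct.pack(
            "<14I", usec, int(max_size * self.fps), 0, 0x10, n, 0, 1, max_size,
            width, height, 0, 0, 0, 0,
        )
        strh = struct.pack(
            "<4s4sIHHIIIIIIiI4h",
            b"vids", b"MJPG", 0, 0, 0, 0,
            1000, int(round(self.fps * 1000)),  # scale, rate
            0, n, max_size, -1, 0,  # start, length, bufsize, quality, samplesize
            0, 0, width, height,
        )
        strf = struct.pack(
            "<IiiHH4sIiiII", 40, width, height, 1, 24, b"MJPG", width * height * 3,
            0, 0, 0, 0,
        )
        strl = b"LIST" + struct.pack("<I", 4 + 8 + len(strh) + 8 + len(strf)) + b"strl" \
            + b"strh" + struct.pack("<I", len(strh)) + strh \
            + b"strf" + struct.pack("<I", len(strf)) + strf
        hdrl_body = b"avih" + struct.pack("<I", len(avih)) + avih + strl
        hdrl = b"LIST" + struct.pack("<I", 4 + len(hdrl_body)) + b"hdrl" + hdrl_body
        header = b"RIFF" + struct.pack("<I", file_end - 8) + b"AVI " + hdrl
        if len(header) > 224:  # header budget: fixed-size hdrl always fits
            raise RuntimeError("AVI header overflow")
        header += b"JUNK" + struct.pack("<I", 224 - len(header) - 8)
        self._fh.seek(0)
        self._fh.write(header)
        # patch movi LIST size
        self._fh.seek(224 + 4)
        self._fh.write(struct.pack("<I", movi_end - 224 - 8))
        self._fh.close()

    def __enter__(self) -> "AviWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_avi(path: str | Path, frames: Iterable[np.ndarray], fps: float = 30.0, **kw) -> Path:
    with AviWriter(path, fps=fps, **kw) as w:
        for frame in frames:
            w.append(frame)
    return Path(path)


def read_avi(path: str | Path) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (frame_index, gray frame) from an MJPEG AVI."""
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"{path}: not an AVI file")
    idx = 0
    for chunk_id, payload in _riff_chunks(data[12:]):
        if chunk_id in (b"00dc", b"00db") and payload:
            yield idx, _as_gray(np.asarray(Image.open(io.BytesIO(payload)).convert("L")))
            idx += 1


def _riff_chunks(buf: bytes) -> Iterator[tuple[bytes, bytes]]:
    pos = 0
    while pos + 8 <= len(buf):
        cid = buf[pos:pos + 4]
        size = struct.unpack("<I", buf[pos + 4:pos + 8])[0]
        body = buf[pos + 8:pos + 8 + size]
        if cid == b"LIST":
            yield from _riff_chunks(body[4:])
        else:
            yield cid, body
        pos += 8 + size + (size % 2)


def open_video(src: str | Path) -> Iterator[tuple[int, np.ndarray]]:
    """Dispatch on dialect: a ``.avi`` file or a PNG-sequence directory."""
    src = Path(src)
    if src.is_file() and src.suffix.lower() == ".avi":
        return read_avi(src)
    return read_png_sequence(src)


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return img.astype(np.uint8)
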