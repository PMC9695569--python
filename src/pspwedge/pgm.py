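"""Binary PGM (P5, maxval 255) reader/writer.

The simulator exports radiographs as 8-bit binary PGM — a lossless,
universally parseable stand-in for the scanners' proprietary RAW
export.  The parser is deliberately strict: only P5 with maxval 255 is
accepted, and truncated files are rejected, so a round trip is always
bit-exact.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError

__all__ = ["read_pgm", "write_pgm"]


def write_pgm(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D uint8 array as binary PGM (P5, maxval 255)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise FormatError("write_pgm expects a 2-D uint8 array")
    rows, cols = arr.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{cols} {rows}\n255\n".encode("ascii"))
        fh.write(arr.tobytes())


def _read_token(fh) -> bytes:
    """Next whitespace-delimited header token, skipping '#' comments."""
    token = b""
    while True:
        ch = fh.read(1)
        if ch == b"":
            raise FormatError("truncated PGM header")
        if ch == b"#":
            while ch not in (b"\n", b""):
                ch = fh.read(1)
            continue
        if ch.isspace():
            if token:
                return token
            continue
        token += ch


def read_pgm(path: str | os.PathLike) -> np.ndarray:
    """Read a binary PGM file written by :func:`write_pgm`.

    Raises :class:`FormatError` on a non-P5 magic number, a maxval
    other than 255, or truncated pixel data.
    """
    with open(path, "rb") as fh:
        magic = fh.read(2)
        if magic != b"P5":
            raise FormatError(f"not a binary PGM (P5) file: magic {magic!r}")
        try:
            cols = int(_read_token(fh))
            rows = int(_read_token(fh))
            maxval = int(_read_token(fh))
        except ValueError as exc:
            raise FormatError(f"malformed PGM header: {exc}") from exc
        if maxval != 255:
            raise FormatError(f"unsupported maxval {maxval}; expected 255")
        if rows < 1 or cols < 1:
            raise FormatError(f"invalid PGM dimensions {cols} x {rows}")
        data = fh.read(rows * cols)
        if len(data) != rows * cols:
            raise FormatError("truncated PGM pixel data")
    return np.frombuffer(data, dtype=np.uint8).reshape(rows, cols)
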