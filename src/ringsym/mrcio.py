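"""Minimal MRC2014 image/stack I/O.

Reads modes 0 (int8), 1 (int16) and 2 (float32); writes mode 2 with the
pixel size recorded in the cell dimensions.  Data are stored as (nz, ny, nx)
with x fastest, per the MRC2014 convention; a stack is nz single images.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ringsym.polarize import RingImage

HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}
_MAP_MAGIC = int.from_bytes(b"MAP ", "little")
_MACHST_LE = int.from_bytes(b"\x44\x41\x00\x00", "little")


def write_stack(path: str | Path, images: list[RingImage] | np.ndarray,
                pixel_size_A: float | None = None) -> None:
    """Write images as a mode-2 (float32) MRC2014 stack."""
    if isinstance(images, np.ndarray):
        data = np.asarray(images, dtype=np.float32)
        if data.ndim == 2:
            data = data[None]
        psize = float(pixel_size_A or 1.0)
    else:
        if not images:
            raise ValueError("nothing to write: empty image list")
        data = np.stack([im.pixels for im in images]).astype(np.float32)
        psize = float(pixel_size_A or images[0].pixel_size_A)
    nz, ny, nx = data.shape
    h = np.zeros(256, dtype="<i4")
    hf = h.view("<f4")
    h[0:3] = (nx, ny, nz)
    h[3] = 2  # mode 2: float32
    h[7:10] = (nx, ny, nz)  # mx, my, mz
    hf[10:13] = (nx * psize, ny * psize, nz * psize)  # cella (Angstrom)
    hf[13:16] = 90.0
    h[16:19] = (1, 2, 3)  # mapc, mapr, maps
    hf[19] = float(data.min())
    hf[20] = float(data.max())
    hf[21] = float(data.mean())
    h[22] = 0  # ispg 0: image stack
    h[23] = 0  # nsymbt
    h[27] = 20140  # nversion
    h[52] = _MAP_MAGIC
    h[53] = _MACHST_LE
    hf[54] = float(data.std())
    h[55] = 0  # nlabl
    with open(path, "wb") as fh:
        fh.write(h.tobytes())
        fh.write(data.astype("<f4").tobytes())


def read_stack(path: str | Path) -> list[RingImage]:
    """Read an MRC2014 single image or stack into a list of RingImage."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < HEADER_BYTES:
        raise ValueError(
            f"corrupt header in {path.name}: need {HEADER_BYTES} header bytes, "
            f"file has {len(raw)}"
        )
    h = np.frombuffer(raw[:HEADER_BYTES], dtype="<i4")
    hf = h.view("<f4")
    nx, ny, nz, mode = int(h[0]), int(h[1]), int(h[2]), int(h[3])
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise ValueError(f"corrupt header in {path.name}: dimensions {(nx, ny, nz)}")
    if mode not in _MODE_DTYPES:
        raise ValueError(
            f"unsupported MRC mode {mode} in {path.name}: only modes "
            f"{sorted(_MODE_DTYPES)} (int8/int16/float32) are supported"
        )
    nsymbt = int(h[23])
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    expected = HEADER_BYTES + nsymbt + nx * ny * nz * dtype.itemsize
    if len(raw) < expected:
        raise ValueError(
            f"truncated file {path.name}: expected {expected} bytes "
            f"({nx}x{ny}x{nz} mode {mode}), found {len(raw)}"
        )
    mx = int(h[7])
    psize = float(hf[10]) / mx if mx > 0 and hf[10] > 0 else 1.0
    data = np.frombuffer(
        raw[HEADER_BYTES + nsymbt : expected], dtype=dtype
    ).reshape(nz, ny, nx)
    stem = path.stem
    return [
        RingImage(pixels=data[i].astype(np.float64), pixel_size_A=psize,
                  id=f"{stem}@{i:05d}")
        for i in range(nz)
    ]
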