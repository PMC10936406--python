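"""Minimal MRC2014 volume reader/writer.

Supports single-volume files in modes 0 (int8), 1 (int16), 2 (float32) and
6 (uint16), little- or big-endian, with an optional extended header that is
skipped on read.  Voxel size is stored in the CELLA fields so that
``cella / (mx, my, mz)`` yields the pixel size in angstroms, per the MRC2014
convention.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.int8,
    1: np.int16,
    2: np.float32,
    6: np.uint16,
}
_DTYPE_MODES = {np.dtype(v): k for k, v in _MODE_DTYPES.items()}

# MAP + machine stamp for little-endian files
_MAP_ID = b"MAP "
_MACHST_LE = b"\x44\x44\x00\x00"


def read_mrc(path) -> tuple[np.ndarray, float | None]:
    """Read an MRC volume.

    Returns
    -------
    data : ndarray, shape (nz, ny, nx)
    pixel_size_nm : float or None
        In-plane pixel size in nanometres, if the header carries a
        positive cell size; otherwise None.
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise ValueError(f"truncated MRC header in {path}")
        byte_order = "<"
        nx, ny, nz, mode = struct.unpack(byte_order + "4i", header[:16])
        if mode not in _MODE_DTYPES or not (0 < nx and 0 < ny and 0 < nz):
            # retry big-endian
            byte_order = ">"
            nx, ny, nz, mode = struct.unpack(byte_order + "4i", header[:16])
        if mode not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {mode} in {path}")
        mx, my, mz = struct.unpack(byte_order + "3i", header[28:40])
        cella = struct.unpack(byte_order + "3f", header[40:52])
        (nsymbt,) = struct.unpack(byte_order + "i", header[92:96])
        if nsymbt:
            fh.seek(HEADER_BYTES + nsymbt)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder(byte_order)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"truncated MRC data in {path}")
        data = data.reshape(nz, ny, nx)
    pixel_size_nm = None
    if mx > 0 and cella[0] > 0:
        pixel_size_nm = float(cella[0]) / mx / 10.0  # angstrom -> nm
    return data, pixel_size_nm


def write_mrc(path, data: np.ndarray, pixel_size_nm: float | None = None) -> None:
    """Write a 3D array as a little-endian MRC2014 volume."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D (nz, ny, nx) array")
    if data.dtype not in _DTYPE_MODES:
        data = data.astype(np.float32)
    mode = _DTYPE_MODES[np.dtype(data.dtype)]
    nz, ny, nx = data.shape
    px_angstrom = (pixel_size_nm or 0.0) * 10.0
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into(
        "<3f", header, 40, nx * px_angstrom, ny * px_angstrom, nz * px_angstrom
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    finite = data[np.isfinite(data)]
    dmin, dmax, dmean = (
        (float(finite.min()), float(finite.max()), float(finite.mean()))
        if finite.size
        else (0.0, 0.0, 0.0)
    )
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg, nsymbt
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    rms = float(finite.std()) if finite.size else 0.0
    struct.pack_into("<f", header, 216, rms)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        data.astype(data.dtype.newbyteorder("<"), copy=False).tofile(fh)
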