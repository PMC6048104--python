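"""Minimal MetaImage (.mhd/.mha) reader and writer.

Supports 3D, uncompressed, local-data files: either a .mhd text header with a
companion raw file, or a .mha file with the raw block appended to the header.
Data on disk follows the MetaImage convention (x fastest, z slowest); arrays
are exposed in (x, y, z) index order.
"""

from __future__ import annotations

import os

import numpy as np

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_LONG": np.int64,
    "MET_ULONG": np.uint64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


def _parse_header(text: str) -> dict:
    header: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, value = line.split("=", 1)
        header[key.strip()] = value.strip()
    return header


def read(path: str) -> tuple[np.ndarray, tuple[float, ...], tuple[float, ...]]:
    """Read a MetaImage file; returns (data_xyz, spacing, origin)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    # header is ASCII up to and including the ElementDataFile line
    end = raw.find(b"ElementDataFile")
    if end < 0:
        raise OSError(f"not a MetaImage file (no ElementDataFile): {path}")
    newline = raw.find(b"\n", end)
    if newline < 0:
        newline = len(raw) - 1
    header = _parse_header(raw[: newline + 1].decode("ascii", errors="replace"))

    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise ValueError(f"expected a 3D MetaImage, got NDims={ndims}: {path}")
    if header.get("CompressedData", "False").lower() == "true":
        raise ValueError(f"compressed MetaImage not supported: {path}")
    if header.get("BinaryData", "True").lower() != "true":
        raise ValueError(f"ASCII MetaImage not supported: {path}")
    byte_order_msb = header.get(
        "BinaryDataByteOrderMSB", header.get("ElementByteOrderMSB", "False")
    )
    elem_type = header.get("ElementType", "MET_FLOAT")
    if elem_type not in _MET_TO_DTYPE:
        raise ValueError(f"unsupported ElementType {elem_type}: {path}")
    dtype = np.dtype(_MET_TO_DTYPE[elem_type])
    if byte_order_msb.lower() == "true":
        dtype = dtype.newbyteorder(">")

    shape_xyz = tuple(int(s) for s in header["DimSize"].split())
    spacing = tuple(float(s) for s in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(
        float(s) for s in header.get("Offset", header.get("Position", "0 0 0")).split()
    )

    datafile = header["ElementDataFile"]
    count = int(np.prod(shape_xyz))
    if datafile == "LOCAL":
        buf = raw[newline + 1 :]
        data = np.frombuffer(buf, dtype=dtype, count=count)
    else:
        datapath = os.path.join(os.path.dirname(os.path.abspath(path)), datafile)
        data = np.fromfile(datapath, dtype=dtype, count=count)
    if data.size != count:
        raise OSError(f"truncated MetaImage data ({data.size} of {count} values): {path}")
    # disk layout: x fastest -> C-order array is (z, y, x); transpose to (x, y, z)
    data = data.reshape(shape_xyz[::-1]).transpose(2, 1, 0)
    return data, spacing, origin


def write(
    path: str,
    data_xyz: np.ndarray,
    spacing: tuple[float, ...],
    origin: tuple[float, ...],
) -> None:
    """Write a 3D array in (x, y, z) order as .mhd (+ .raw) or .mha."""
    data_xyz = np.ascontiguousarray(data_xyz.transpose(2, 1, 0))  # -> x fastest on disk
    dtype = np.dtype(data_xyz.dtype).newbyteorder("=")
    if dtype not in _DTYPE_TO_MET:
        raise ValueError(f"cannot store dtype {data_xyz.dtype} in MetaImage")
    shape_xyz = data_xyz.shape[::-1]
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        f"DimSize = {' '.join(str(s) for s in shape_xyz)}",
        f"ElementSpacing = {' '.join(repr(float(s)) for s in spacing)}",
        f"Offset = {' '.join(repr(float(o)) for o in origin)}",
        f"ElementType = {_DTYPE_TO_MET[dtype]}",
    ]
    payload = data_xyz.astype(dtype, copy=False).tobytes()
    if path.endswith(".mha"):
        lines.append("ElementDataFile = LOCAL")
        with open(path, "wb") as fh:
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
            fh.write(payload)
    elif path.endswith(".mhd"):
        rawname = os.path.basename(path)[:-4] + ".raw"
        lines.append(f"ElementDataFile = {rawname}")
        with open(path, "w", encoding="ascii") as fh:
            fh.write("\n".join(lines) + "\n")
        with open(os.path.join(os.path.dirname(os.path.abspath(path)), rawname), "wb") as fh:
            fh.write(payload)
    else:
        raise ValueError(f"MetaImage path must end in .mhd or .mha: {path}")
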