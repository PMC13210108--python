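"""Lightweight NRRD volume I/O (attached header, raw/gzip/ascii encodings).

Covers the subset of the NRRD1 format needed for phase-resolved binary or
grey-valued volumes with spacing metadata: 3-D arrays, little-endian,
``space directions`` as an axis-aligned diagonal, ``space origin``.
"""

from __future__ import annotations

import gzip
import re
from pathlib import Path

import numpy as np

_TYPE_MAP = {
    "uint8": np.uint8, "uchar": np.uint8, "unsigned char": np.uint8,
    "int16": np.int16, "short": np.int16,
    "uint16": np.uint16,
    "int32": np.int32, "int": np.int32,
    "float": np.float32, "float32": np.float32,
    "double": np.float64, "float64": np.float64,
}
_INV_TYPE = {np.dtype(np.uint8): "uint8", np.dtype(np.int16): "int16",
             np.dtype(np.uint16): "uint16", np.dtype(np.int32): "int32",
             np.dtype(np.float32): "float", np.dtype(np.float64): "double"}


def write_nrrd(path, array: np.ndarray, spacing, origin=(0.0, 0.0, 0.0),
               encoding: str = "gzip") -> None:
    """Write a 3-D array as NRRD with isotropic-or-not voxel spacing (mm)."""
    array = np.ascontiguousarray(array)
    if array.ndim != 3:
        raise ValueError("only 3-D volumes are supported")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    dtype = array.dtype
    if dtype == np.bool_:
        array = array.astype(np.uint8)
        dtype = array.dtype
    if dtype not in _INV_TYPE:
        raise ValueError(f"unsupported dtype {dtype}")
    dirs = " ".join(f"({s:.17g},0,0)" if i == 0 else
                    f"(0,{s:.17g},0)" if i == 1 else
                    f"(0,0,{s:.17g})" for i, s in enumerate(spacing))
    header = [
        "NRRD0004",
        "# aneupulse volume",
        f"type: {_INV_TYPE[dtype]}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"space directions: {dirs}",
        "kinds: domain domain domain",
        "endian: little",
        f"encoding: {encoding}",
        f"space origin: ({origin[0]:.17g},{origin[1]:.17g},{origin[2]:.17g})",
        "",
    ]
    raw = array.astype(array.dtype.newbyteorder("<")).tobytes(order="C")
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(b"\n")
        if encoding == "raw":
            fh.write(raw)
        elif encoding == "gzip":
            fh.write(gzip.compress(raw))
        elif encoding in ("ascii", "text", "txt"):
            np.savetxt(fh, array.reshape(-1, array.shape[-1]), fmt="%g")
        else:
            raise ValueError(f"unsupported encoding {encoding!r}")


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read a NRRD volume; returns (array, header-dict with spacing/origin)."""
    data = Path(path).read_bytes()
    sep = data.find(b"\n\n")
    if sep < 0:
        raise ValueError("malformed NRRD: no blank line after header")
    header_text = data[:sep].decode("ascii", errors="replace")
    body = data[sep + 2:]
    fields: dict[str, str] = {}
    for line in header_text.splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip()
    dtype = np.dtype(_TYPE_MAP[fields["type"]]).newbyteorder("<")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    encoding = fields.get("encoding", "raw")
    if encoding == "raw":
        arr = np.frombuffer(body, dtype=dtype, count=int(np.prod(sizes)))
    elif encoding in ("gzip", "gz"):
        arr = np.frombuffer(gzip.decompress(body), dtype=dtype,
                            count=int(np.prod(sizes)))
    elif encoding in ("ascii", "text", "txt"):
        arr = np.array(body.decode("ascii").split(), dtype=float).astype(dtype)
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
    arr = arr.reshape(sizes)
    spacing = np.ones(3)
    if "space directions" in fields:
        vecs = re.findall(r"\(([^)]*)\)", fields["space directions"])
        mat = np.array([[float(x) for x in v.split(",")] for v in vecs])
        spacing = np.linalg.norm(mat, axis=1)
    elif "spacings" in fields:
        spacing = np.array([float(s) for s in fields["spacings"].split()])
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = np.array(
            [float(x) for x in fields["space origin"].strip("()").split(",")]
        )
    meta = {"spacing": spacing, "origin": origin, "raw_header": fields}
    return np.array(arr), meta
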