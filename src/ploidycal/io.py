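"""File I/O: flow-cytometry event lists, rasters, tables, configuration.

Flow-cytometry events are accepted either as CSV (single column or a
named column, default ``fsc_area``) or as FCS 3.x list-mode files. The
FCS reader is deliberately minimal — uncompensated list-mode data with
float or integer storage — which covers exported ploidy list files; a
matching writer exists for building test fixtures only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import LabeledImage

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL = "fsc_area"


# ---------------------------------------------------------------------------
# FCS 3.x list mode
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)[1:]
    # trailing delimiter leaves an empty tail element
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise ValueError("malformed FCS TEXT segment (odd key/value count)")
    return {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path, channel: str | None = None) -> np.ndarray:
    """Read one channel from an FCS 3.0/3.1 list-mode file.

    ``channel`` matches the $PnN short name (case-insensitive); ``None``
    selects the FSC-area channel if present (a name containing both
    "fsc" and "a"), else the sole channel, else raises listing the
    available names.
    """
    path = Path(path)
    blob = path.read_bytes()
    version = blob[:6].decode("latin-1", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(blob[lo:hi].decode("latin-1").strip() or 0)

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_beg : text_end + 1])
    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))

    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    bits = [int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)]

    if dtype_code == "F":
        base = "f4"
    elif dtype_code == "D":
        base = "f8"
    elif dtype_code == "I":
        widths = set(bits)
        if len(widths) != 1 or widths.pop() not in (16, 32):
            raise ValueError(f"{path}: unsupported integer bit widths {bits}")
        base = "u2" if bits[0] == 16 else "u4"
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code!r}")
    dt = np.dtype(("<" if little else ">") + base)

    payload = blob[data_beg : data_end + 1]
    need = n_tot * n_par * dt.itemsize
    if len(payload) < need:
        raise ValueError(f"{path}: DATA segment truncated ({len(payload)} < {need})")
    mat = np.frombuffer(payload[:need], dtype=dt).reshape(n_tot, n_par)

    lowered = [n.lower() for n in names]
    if channel is not None:
        if channel.lower() not in lowered:
            raise KeyError(
                f"channel {channel!r} not in {path}; available: {names}"
            )
        idx = lowered.index(channel.lower())
    else:
        fsc = [i for i, n in enumerate(lowered) if "fsc" in n and "a" in n]
        if fsc:
            idx = fsc[0]
        elif n_par == 1:
            idx = 0
        else:
            raise KeyError(f"no FSC-area channel found in {path}; available: {names}")
    return mat[:, idx].astype(np.float64)


def write_fcs(path: str | Path, values: np.ndarray, channel: str = "FSC-A") -> None:
    """Write a single-channel FCS 3.0 list-mode file (fixtures only)."""
    values = np.asarray(values, dtype="<f4")
    data = values.tobytes()
    keys = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": "1",
        "$TOT": str(values.size),
        "$P1N": channel,
        "$P1B": "32",
        "$P1E": "0,0",
        "$P1R": str(int(max(values.max(initial=1.0), 1.0)) + 1),
        "$NEXTDATA": "0",
    }
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in keys.items()) + delim
    text_bytes = text.encode("ascii")
    header_len = 58
    text_beg = header_len
    text_end = text_beg + len(text_bytes) - 1
    data_beg = text_end + 1
    data_end = data_beg + len(data) - 1
    header = (
        b"FCS3.0    "
        + f"{text_beg:>8d}{text_end:>8d}{data_beg:>8d}{data_end:>8d}".encode()
        + f"{0:>8d}{0:>8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + data)


# ---------------------------------------------------------------------------
# events (CSV or FCS)
# ---------------------------------------------------------------------------

def read_events(path: str | Path, channel_name: str | None = None) -> np.ndarray:
    """Event values from a CSV or FCS 3.x file.

    CSV: the named column (default ``fsc_area``); a headerless or
    single-column file yields its only numeric column. FCS: dispatched to
    :func:`read_fcs`.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        return read_fcs(path, channel_name)
    df = pd.read_csv(path)
    name = channel_name or DEFAULT_CHANNEL
    if name in df.columns:
        return df[name].to_numpy(dtype=float)
    numeric = df.select_dtypes("number")
    if channel_name is None and numeric.shape[1] == 1:
        return numeric.iloc[:, 0].to_numpy(dtype=float)
    raise KeyError(
        f"channel {name!r} not found in {path}; available: {list(df.columns)}"
    )


# ---------------------------------------------------------------------------
# rasters and tables
# ---------------------------------------------------------------------------

def write_labeled_image(
    image: LabeledImage, intensity_path: str | Path, labels_path: str | Path
) -> None:
    """Persist a scene as a 16-bit intensity TIFF plus 16-bit label TIFF."""
    tifffile.imwrite(
        str(intensity_path), np.clip(np.rint(image.intensity), 0, 65535).astype(np.uint16)
    )
    if image.labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(str(labels_path), image.labels.astype(np.uint16))


def read_labeled_image(
    intensity_path: str | Path, labels_path: str | Path
) -> LabeledImage:
    """Load intensity and label rasters (TIFF or PNG) as a LabeledImage."""

    def _load(p):
        p = Path(p)
        if p.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(str(p))
        from imageio.v3 import imread  # PNG path

        return imread(str(p))

    return LabeledImage(
        _load(intensity_path).astype(np.float64),
        _load(labels_path).astype(np.int32),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (plain nested mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
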