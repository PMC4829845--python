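"""Event loading (CSV / FCS) and artifact serialization.

Flow-cytometry exports arrive either as 3-column CSV (header ``r,g,b``,
any case, extra columns allowed) or as FCS list-mode files.  A minimal
FCS 2.0/3.0/3.1 reader is included: it parses the header offsets and TEXT
segment, selects channels by ``$PnN`` (short name) or ``$PnS`` (stain
name), and reads list-mode DATA of type F (float32), D (float64) or I
(unsigned integer), either byte order.  A matching FCS 3.1 float writer is
provided for exporting synthetic events.

Grid, landscape and spillover artifacts serialise to plain-text formats:
dense CSV for grids, JSON with a run-length-encoded assignment map for
landscapes, CSV for spillover matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .colorspace import (
    SCALE_MAX_CYTOMETER,
    ChromaticityGrid,
    ColorEvents,
    solid_angle_column,
    OCTANT_SOLID_ANGLE_SR,
)
from .landscape import ChromaticLandscape, SpilloverMatrix, UNASSIGNED
from .metrics import ModeResult

__all__ = [
    "load_events",
    "read_events_csv",
    "write_events_csv",
    "read_fcs",
    "write_fcs",
    "grid_to_csv",
    "grid_from_csv",
    "landscape_to_json",
    "landscape_from_json",
    "spillover_to_csv",
    "spillover_from_csv",
]

DEFAULT_CHANNEL_MAP = {"R": "r", "G": "g", "B": "b"}


# ---------------------------------------------------------------------------
# Event loading
# ---------------------------------------------------------------------------


def load_events(
    path,
    format: str | None = None,
    channel_map: Mapping[str, str] | None = None,
    scale_max: float = SCALE_MAX_CYTOMETER,
    negative_policy: str = "clamp",
) -> ColorEvents:
    """Load per-cell RGB events from a CSV or FCS file.

    ``channel_map`` maps the logical channels ``R``/``G``/``B`` to column
    names (CSV) or FCS channel names; defaults to ``r``/``g``/``b``.
    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        return read_events_csv(path, channel_map, scale_max, negative_policy)
    if format == "fcs":
        return read_fcs(path, channel_map, scale_max, negative_policy)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'fcs')")


def read_events_csv(
    path,
    channel_map: Mapping[str, str] | None = None,
    scale_max: float = SCALE_MAX_CYTOMETER,
    negative_policy: str = "clamp",
) -> ColorEvents:
    cmap = dict(channel_map or DEFAULT_CHANNEL_MAP)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no events")
    cols = {c.lower(): c for c in df.columns}
    picked = {}
    for logical in ("R", "G", "B"):
        want = cmap.get(logical, logical.lower())
        if want in df.columns:
            picked[logical] = want
        elif want.lower() in cols:
            picked[logical] = cols[want.lower()]
        else:
            raise ValueError(
                f"{path}: channel {want!r} for {logical} not found; "
                f"available columns: {list(df.columns)}"
            )
    return ColorEvents.from_rgb(
        df[picked["R"]].to_numpy(float),
        df[picked["G"]].to_numpy(float),
        df[picked["B"]].to_numpy(float),
        scale_max=scale_max,
        negative_policy=negative_policy,
        meta={"path": str(path), "format": "csv"},
    )


def write_events_csv(events: ColorEvents, path) -> None:
    pd.DataFrame({"r": events.r, "g": events.g, "b": events.b}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Minimal FCS support
# ---------------------------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty FCS TEXT segment")
    delim = raw[0:1]
    parts = raw[1:].split(delim)
    # trailing delimiter produces an empty last token
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        kv[key] = parts[i + 1].decode("utf-8", "replace").strip()
    return kv


def read_fcs(
    path,
    channel_map: Mapping[str, str] | None = None,
    scale_max: float | None = None,
    negative_policy: str = "clamp",
) -> ColorEvents:
    """Read an FCS 2.0/3.0/3.1 list-mode file and map R/G/B channels."""
    cmap = dict(channel_map or DEFAULT_CHANNEL_MAP)
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise ValueError(f"{path}: not an FCS file (too short)")
    version = blob[:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path}: not an FCS file (bad magic {version!r})")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    text = _parse_text_segment(blob[text_start : text_end + 1])

    def kw(key, default=None):
        v = text.get(key, default)
        if v is None:
            raise ValueError(f"{path}: missing required FCS keyword {key}")
        return v

    data_start = int(text.get("$BEGINDATA") or blob[26:34] or 0)
    data_end = int(text.get("$ENDDATA") or blob[34:42] or 0)
    n_par = int(kw("$PAR"))
    n_tot = int(kw("$TOT"))
    dtype_code = kw("$DATATYPE").upper()
    mode = kw("$MODE", "L").upper()
    if mode != "L":
        raise ValueError(f"{path}: only list mode ($MODE/L) is supported")
    byteord = kw("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")

    names = [text.get(f"$P{k}N", f"P{k}") for k in range(1, n_par + 1)]
    stains = [text.get(f"$P{k}S", "") for k in range(1, n_par + 1)]
    bits = [int(text.get(f"$P{k}B", "32")) for k in range(1, n_par + 1)]

    if dtype_code == "F":
        base = "f4"
        widths = [32] * n_par
    elif dtype_code == "D":
        base = "f8"
        widths = [64] * n_par
    elif dtype_code == "I":
        widths = bits
        if len(set(widths)) != 1 or widths[0] not in (8, 16, 32):
            raise ValueError(
                f"{path}: only uniform 8/16/32-bit integer data supported"
            )
        base = f"u{widths[0] // 8}"
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code}")
    endian = "<" if little else ">"
    dt = np.dtype(endian + base)
    n_values = n_par * n_tot
    raw = blob[data_start : data_start + n_values * dt.itemsize]
    if len(raw) < n_values * dt.itemsize:
        raise ValueError(f"{path}: truncated DATA segment")
    data = np.frombuffer(raw, dtype=dt, count=n_values).reshape(n_tot, n_par)

    def channel_index(want: str) -> int:
        for k, (nm, st) in enumerate(zip(names, stains)):
            if want in (nm, st):
                return k
        raise ValueError(
            f"{path}: channel {want!r} not found; available $PnN={names}, "
            f"$PnS={stains}"
        )

    idx = {logical: channel_index(cmap.get(logical, logical.lower()))
           for logical in ("R", "G", "B")}
    if scale_max is None:
        scale_max = float(text.get(f"$P{idx['R'] + 1}R", SCALE_MAX_CYTOMETER))
    meta = {
        "path": str(path),
        "format": "fcs",
        "fcs_version": version.strip(),
        "n_par": n_par,
        "acquisition_date": text.get("$DATE"),
    }
    return ColorEvents.from_rgb(
        data[:, idx["R"]].astype(float),
        data[:, idx["G"]].astype(float),
        data[:, idx["B"]].astype(float),
        scale_max=scale_max,
        negative_policy=negative_policy,
        meta=meta,
    )


def write_fcs(
    events: ColorEvents,
    path,
    channel_names: tuple[str, str, str] = ("tdTomato", "Venus", "Cerulean"),
) -> None:
    """Write events as a minimal FCS 3.1 file (float32, little-endian)."""
    data = np.column_stack([events.r, events.g, events.b]).astype("<f4")
    payload = data.tobytes()
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": "3",
        "$TOT": str(events.n),
        "$NEXTDATA": "0",
    }
    for k, name in enumerate(channel_names, start=1):
        kv[f"$P{k}N"] = name
        kv[f"$P{k}S"] = name
        kv[f"$P{k}B"] = "32"
        kv[f"$P{k}E"] = "0,0"
        kv[f"$P{k}R"] = f"{events.scale_max:g}"

    # iterate because BEGINDATA/ENDDATA lengths depend on the TEXT length
    header_len = 58
    delim = "/"
    for _ in range(3):
        text = delim + delim.join(
            f"{k}{delim}{v}" for k, v in sorted(kv.items())
        ) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(payload) - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
    header = (
        f"FCS3.1    "
        f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == header_len
    Path(path).write_bytes(header + text.encode("ascii") + payload)


# ---------------------------------------------------------------------------
# Grid / landscape / spillover serialization
# ---------------------------------------------------------------------------


def grid_to_csv(grid: ChromaticityGrid, path) -> None:
    """Dense long-format CSV with a commented metadata header."""
    with open(path, "w") as fh:
        fh.write(
            f"# resolution_deg={grid.resolution_deg!r} "
            f"n_events={grid.n_events} n_zero_value={grid.n_zero_value} "
            f"n_saturated={grid.n_saturated} scale_max={grid.scale_max!r}\n"
        )
        grid.to_dataframe().to_csv(fh, index=False, float_format="%.9g")


def grid_from_csv(path) -> ChromaticityGrid:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(
        tok.split("=", 1) for tok in header.lstrip("# ").strip().split()
    )
    res = float(meta["resolution_deg"])
    n = int(round(90.0 / res))
    raw = np.zeros((n, n), dtype=np.int64)
    i = np.round(df["theta_lo"].to_numpy() / res).astype(int)
    j = np.round(df["phi_lo"].to_numpy() / res).astype(int)
    raw[i, j] = df["raw_count"].to_numpy()
    omega = solid_angle_column(res)
    counts = raw / omega[np.newaxis, :] * (OCTANT_SOLID_ANGLE_SR / (n * n))
    return ChromaticityGrid(
        resolution_deg=res,
        raw_counts=raw,
        counts=counts,
        n_events=int(meta["n_events"]),
        n_zero_value=int(meta["n_zero_value"]),
        n_saturated=int(meta["n_saturated"]),
        scale_max=float(meta["scale_max"]),
    )


def _rle_encode(flat: np.ndarray) -> list[list[int]]:
    runs = []
    start = 0
    for k in range(1, len(flat) + 1):
        if k == len(flat) or flat[k] != flat[start]:
            runs.append([int(flat[start]), k - start])
            start = k
    return runs


def _rle_decode(runs, n) -> np.ndarray:
    out = np.empty(n, dtype=np.int32)
    pos = 0
    for value, length in runs:
        out[pos : pos + length] = value
        pos += length
    if pos != n:
        raise ValueError("run-length data does not match grid size")
    return out


def landscape_to_json(landscape: ChromaticLandscape, path) -> None:
    """Compact JSON: per-clone contour element lists and an RLE assignment map."""
    obj = {
        "resolution_deg": landscape.resolution_deg,
        "landscape_fraction": landscape.landscape_fraction,
        "policy": landscape.policy,
        "majority_threshold": landscape.majority_threshold,
        "clone_ids": landscape.clone_ids,
        "modes": {
            c: {
                "element": list(m.element),
                "n_max": m.n_max,
                "theta": m.theta,
                "phi": m.phi,
                "tied": m.tied,
            }
            for c, m in landscape.modes.items()
        },
        "spreads": {
            c: {
                "elements": np.argwhere(mask).tolist(),
                "counts": [
                    round(float(landscape.count_grids[c][i, j]), 9)
                    for i, j in np.argwhere(mask)
                ],
            }
            for c, mask in landscape.spread_masks.items()
        },
        "assignment_rle": _rle_encode(landscape.assignment.ravel()),
    }
    Path(path).write_text(json.dumps(obj))


def landscape_from_json(path) -> ChromaticLandscape:
    obj = json.loads(Path(path).read_text())
    res = float(obj["resolution_deg"])
    n = int(round(90.0 / res))
    clone_ids = list(obj["clone_ids"])
    assignment = _rle_decode(obj["assignment_rle"], n * n).reshape(n, n)
    spread_masks, count_grids, modes = {}, {}, {}
    for c in clone_ids:
        sp = obj["spreads"][c]
        mask = np.zeros((n, n), dtype=bool)
        counts = np.zeros((n, n))
        for (i, j), v in zip(sp["elements"], sp["counts"]):
            mask[i, j] = True
            counts[i, j] = v
        spread_masks[c] = mask
        count_grids[c] = counts
        m = obj["modes"][c]
        modes[c] = ModeResult(
            element=tuple(m["element"]),
            n_max=m["n_max"],
            theta=m["theta"],
            phi=m["phi"],
            tied=m["tied"],
        )
    return ChromaticLandscape(
        resolution_deg=res,
        clone_ids=clone_ids,
        count_grids=count_grids,
        spread_masks=spread_masks,
        modes=modes,
        assignment=assignment,
        landscape_fraction=float(obj["landscape_fraction"]),
        policy=obj["policy"],
        majority_threshold=float(obj["majority_threshold"]),
    )


def spillover_to_csv(ms: SpilloverMatrix, path) -> None:
    ms.to_dataframe().to_csv(path, index_label="true_clone", float_format="%.9g")


def spillover_from_csv(path) -> SpilloverMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.columns[-1] != UNASSIGNED:
        raise ValueError(f"{path}: last column must be {UNASSIGNED!r}")
    return SpilloverMatrix(clone_ids=list(df.index), matrix=df.to_numpy(float))
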