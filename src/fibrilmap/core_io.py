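"""Localization tables: data model, CSV I/O, merging, filtering, rendering.

A *localization* is one fitted fluorophore detection from a single-molecule
localization microscopy (SMLM) experiment: lateral position ``x, y`` (and
optionally ``z``) in nanometres, the camera frame it was detected in, the
fitted photon count, the lateral localization precision sigma (nm) and an
integer channel label.  Tables of localizations are carried as pandas
DataFrames wrapped in :class:`LocalizationTable` so metadata (pixel size,
channel names) travels with the records.

The module also implements the standard post-processing applied to such
tables before any quantitative analysis:

* :func:`merge_relocalizations` — blinking fluorophores yield chains of
  detections in consecutive frames; detections within a radius and a frame
  gap are combined into one localization.
* :func:`filter_localizations` — reject poorly localized or out-of-focus
  records (axial window, precision cut-off).
* :func:`gaussian_render` — render each localization as an isotropic 2D
  Gaussian of width equal to its own precision, the field's canonical
  visualisation and the substrate for line-profile extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "COLUMNS",
    "Localization",
    "LocalizationTable",
    "FibrilPolyline",
    "RenderedImage",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "merge_relocalizations",
    "filter_localizations",
    "gaussian_render",
    "read_polylines",
    "write_rendered_image",
]

#: Canonical column order of a localization table (all positions in nm).
COLUMNS = ("x", "y", "z", "frame", "photons", "precision", "channel")

#: Default lateral precision (nm) filled in when a CSV lacks the column.
DEFAULT_PRECISION_NM = 6.0

#: Header synonyms accepted by :func:`read_localizations` (lower-cased,
#: whitespace/bracket content stripped).  Covers ThunderSTORM-style
#: ``x [nm]`` headers and a few common exporter variants.
DIALECT_SYNONYMS: Mapping[str, str] = {
    "x": "x",
    "xnm": "x",
    "xpos": "x",
    "position_x": "x",
    "y": "y",
    "ynm": "y",
    "ypos": "y",
    "position_y": "y",
    "z": "z",
    "znm": "z",
    "frame": "frame",
    "frameidx": "frame",
    "t": "frame",
    "photons": "photons",
    "intensity": "photons",
    "intensityphoton": "photons",
    "precision": "precision",
    "uncertainty": "precision",
    "uncertaintyxy": "precision",
    "uncertainty_xy": "precision",
    "locprec": "precision",
    "sigma_loc": "precision",
    "channel": "channel",
    "ch": "channel",
}


class FormatError(ValueError):
    """Raised for malformed localization CSV input."""


@dataclass(frozen=True)
class Localization:
    """A single fluorophore detection (positions and precision in nm)."""

    x: float
    y: float
    z: float = 0.0
    frame: int = 0
    photons: float = 1.0
    precision: float = DEFAULT_PRECISION_NM
    channel: int = 0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"precision must be > 0, got {self.precision}")
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if self.photons < 0:
            raise ValueError(f"photons must be >= 0, got {self.photons}")


@dataclass
class LocalizationTable:
    """An ordered collection of localizations sharing one coordinate origin.

    Parameters
    ----------
    records:
        DataFrame with columns :data:`COLUMNS`; positions in nm.
    pixel_size_nm:
        Camera pixel size of the originating acquisition (nm); metadata only.
    channel_names:
        Optional mapping of channel index to a human-readable label.
    """

    records: pd.DataFrame
    pixel_size_nm: float = 94.0
    channel_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be > 0")
        df = pd.DataFrame(self.records)
        for col in COLUMNS:
            if col not in df.columns:
                raise FormatError(f"localization table missing column {col!r}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["frame"] = df["frame"].astype(np.int64)
        df["channel"] = df["channel"].astype(np.int64)
        for col in ("x", "y", "z", "photons", "precision"):
            df[col] = df[col].astype(float)
        if len(df) and not (df["precision"] > 0).all():
            raise ValueError("all localization precisions must be > 0")
        if len(df) and ((df["frame"] < 0).any() or (df["photons"] < 0).any()):
            raise ValueError("frames and photon counts must be non-negative")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(
        cls, records: Sequence[Localization], **kwargs
    ) -> "LocalizationTable":
        df = pd.DataFrame(
            [(r.x, r.y, r.z, r.frame, r.photons, r.precision, r.channel) for r in records],
            columns=list(COLUMNS),
        )
        return cls(df, **kwargs)

    @classmethod
    def from_arrays(cls, x, y, **cols) -> "LocalizationTable":
        """Build a table from coordinate arrays, defaulting missing columns."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        n = len(x)
        meta = {k: cols.pop(k) for k in ("pixel_size_nm", "channel_names") if k in cols}
        data = {
            "x": x,
            "y": np.broadcast_to(np.asarray(y, dtype=float), (n,)),
            "z": np.broadcast_to(np.asarray(cols.get("z", 0.0), dtype=float), (n,)),
            "frame": np.broadcast_to(np.asarray(cols.get("frame", 0)), (n,)),
            "photons": np.broadcast_to(np.asarray(cols.get("photons", 1.0), dtype=float), (n,)),
            "precision": np.broadcast_to(
                np.asarray(cols.get("precision", DEFAULT_PRECISION_NM), dtype=float), (n,)
            ),
            "channel": np.broadcast_to(np.asarray(cols.get("channel", 0)), (n,)),
        }
        return cls(pd.DataFrame(data), **meta)

    def select_channel(self, channel: int) -> "LocalizationTable":
        sub = self.records[self.records["channel"] == channel]
        return LocalizationTable(
            sub, pixel_size_nm=self.pixel_size_nm, channel_names=dict(self.channel_names)
        )


@dataclass
class FibrilPolyline:
    """A user-drawn line along a fibril, with the band half-width used to
    collect localizations around it (both in nm)."""

    vertices: np.ndarray  # (n, 2) in nm
    band_halfwidth: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("polyline needs at least two 2D vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive polyline vertices must be distinct")
        if self.band_halfwidth <= 0:
            raise ValueError("band halfwidth must be > 0")
        self.vertices = v

    @property
    def length(self) -> float:
        """Total arc length (nm)."""
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


@dataclass
class RenderedImage:
    """Pixel values on a regular grid; ``pixel_size`` in nm and ``origin``
    the nm coordinates of the low corner of pixel (0, 0).  Pixel (i, j)
    spans the half-open square [origin + i*px, origin + (i+1)*px)."""

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        self.pixels = np.asarray(self.pixels, dtype=float)
        if np.any(self.pixels < 0):
            raise ValueError("rendered intensities must be non-negative")


# ---------------------------------------------------------------------------
# CSV I/O


def _normalize_header(name: str) -> str:
    base = name.strip().lower()
    if "[" in base:
        base = base.split("[", 1)[0]
    return "".join(ch for ch in base if ch.isalnum() or ch == "_").strip("_")


def read_localizations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    default_precision_nm: float = DEFAULT_PRECISION_NM,
) -> LocalizationTable:
    """Read a localization CSV (header row, positions in nm).

    ``x``, ``y`` and ``frame`` are mandatory; ``z`` defaults to 0,
    ``photons`` to 1, ``precision`` to *default_precision_nm* and
    ``channel`` to 0 when absent.  Header synonyms (e.g. ``x [nm]``,
    ``uncertainty_xy [nm]``) are resolved through the documented dialect
    map; pass ``dialect`` to extend or override it.
    """
    synonyms = dict(DIALECT_SYNONYMS)
    if dialect:
        synonyms.update({_normalize_header(k): v for k, v in dialect.items()})
    raw = pd.read_csv(path)
    rename = {}
    for col in raw.columns:
        key = _normalize_header(str(col))
        if key in synonyms and synonyms[key] not in rename.values():
            rename[col] = synonyms[key]
    raw = raw.rename(columns=rename)
    for required in ("x", "y", "frame"):
        if required not in raw.columns:
            raise FormatError(f"missing mandatory column {required!r} in {path}")
    for col, default in (
        ("z", 0.0),
        ("photons", 1.0),
        ("precision", default_precision_nm),
        ("channel", 0),
    ):
        if col not in raw.columns:
            raw[col] = default
    for col in ("x", "y", "z", "photons", "precision"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        raw[col] = coerced
    raw = raw.dropna(subset=["x", "y"])
    return LocalizationTable(raw[list(COLUMNS)])


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table in the package's canonical CSV dialect."""
    table.records.to_csv(path, index=False, float_format="%.6f")


def read_polylines(path: str | Path) -> list[FibrilPolyline]:
    """Read fibril polyline annotations from JSON.

    Expected layout: ``[{"label": "fib1", "vertices": [[x, y], ...],
    "band_halfwidth": 100.0}, ...]`` with coordinates in nm.
    """
    with open(path) as fh:
        payload = json.load(fh)
    lines = []
    for entry in payload:
        lines.append(
            FibrilPolyline(
                vertices=np.asarray(entry["vertices"], dtype=float),
                band_halfwidth=float(entry.get("band_halfwidth", 100.0)),
                label=str(entry.get("label", "")),
            )
        )
    return lines


def write_rendered_image(image: RenderedImage, path: str | Path) -> None:
    """Write a rendered image as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, image.pixels.astype(np.float32))


# ---------------------------------------------------------------------------
# Merging, filtering, rendering


def merge_relocalizations(
    table: LocalizationTable,
    radius_nm: float = 100.0,
    max_frame_gap: int = 1,
) -> LocalizationTable:
    """Combine chains of re-detections of one fluorophore.

    Blinking emitters are localized repeatedly in consecutive frames.
    Records are scanned in frame order (ties by record index); a record
    joins an open chain of the same channel when it lies within
    ``radius_nm`` of the chain's running photon-weighted mean position and
    within ``max_frame_gap`` frames of the chain's last member.  Each chain
    is replaced by one localization: photon-weighted mean position, photons
    summed, precision the photon-weighted mean of the members' precisions.

    The pass is single-sweep sequential chaining (the usual behaviour of
    localization post-processors): it is idempotent whenever distinct
    emitters are separated by more than the merge radius; for overlapping
    emitter clouds a repeated merge may combine further records because
    centroids move.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    if max_frame_gap < 1:
        raise ValueError("max_frame_gap must be >= 1")
    df = table.records
    if df.empty:
        return LocalizationTable(
            df.copy(), pixel_size_nm=table.pixel_size_nm,
            channel_names=dict(table.channel_names),
        )

    order = np.lexsort((np.arange(len(df)), df["frame"].to_numpy()))
    cols = {c: df[c].to_numpy() for c in COLUMNS}

    # open chains: per chain the running weighted sums
    chains: list[dict] = []
    open_idx: list[int] = []  # indices into `chains` still eligible
    for i in order:
        x, y, z = cols["x"][i], cols["y"][i], cols["z"][i]
        fr, ph = cols["frame"][i], cols["photons"][i]
        pr, ch = cols["precision"][i], cols["channel"][i]
        w = ph if ph > 0 else 1.0  # zero-photon records carry unit weight
        # retire chains whose last frame fell out of the gap window
        open_idx = [k for k in open_idx if fr - chains[k]["last_frame"] <= max_frame_gap]
        target = None
        for k in open_idx:
            c = chains[k]
            if c["channel"] != ch or fr == c["last_frame"]:
                continue  # same-frame records are distinct emitters
            mx, my = c["wx"] / c["w"], c["wy"] / c["w"]
            if (x - mx) ** 2 + (y - my) ** 2 <= radius_nm**2:
                target = c
                break
        if target is None:
            chains.append(
                dict(wx=w * x, wy=w * y, wz=w * z, w=w, photons=ph,
                     wprec=w * pr, last_frame=fr, first=i, channel=ch)
            )
            open_idx.append(len(chains) - 1)
        else:
            target["wx"] += w * x
            target["wy"] += w * y
            target["wz"] += w * z
            target["w"] += w
            target["photons"] += ph
            target["wprec"] += w * pr
            target["last_frame"] = fr

    chains.sort(key=lambda c: c["first"])
    out = pd.DataFrame(
        {
            "x": [c["wx"] / c["w"] for c in chains],
            "y": [c["wy"] / c["w"] for c in chains],
            "z": [c["wz"] / c["w"] for c in chains],
            "frame": [int(cols["frame"][c["first"]]) for c in chains],
            "photons": [c["photons"] for c in chains],
            "precision": [c["wprec"] / c["w"] for c in chains],
            "channel": [int(c["channel"]) for c in chains],
        }
    )
    return LocalizationTable(
        out, pixel_size_nm=table.pixel_size_nm, channel_names=dict(table.channel_names)
    )


def filter_localizations(
    table: LocalizationTable,
    z_min_nm: float = -1000.0,
    z_max_nm: float = 1000.0,
    precision_max_nm: float = 12.0,
) -> LocalizationTable:
    """Keep records with z in [z_min, z_max] and precision strictly below
    ``precision_max_nm`` (defaults: −1…+1 µm axial window, 12 nm cut)."""
    if not z_min_nm < z_max_nm:
        raise ValueError("z_min must be < z_max")
    if precision_max_nm <= 0:
        raise ValueError("precision_max must be > 0")
    df = table.records
    keep = (
        (df["z"] >= z_min_nm)
        & (df["z"] <= z_max_nm)
        & (df["precision"] < precision_max_nm)
    )
    return LocalizationTable(
        df[keep], pixel_size_nm=table.pixel_size_nm,
        channel_names=dict(table.channel_names),
    )


def gaussian_render(
    table: LocalizationTable,
    pixel_size_nm: float,
    region: tuple[float, float, float, float],
    min_sigma_nm: float = 1.0,
) -> RenderedImage:
    """Render localizations as pixel-integrated 2D Gaussians.

    Each localization contributes an isotropic Gaussian with standard
    deviation equal to its own precision (floored at ``min_sigma_nm``),
    integrated analytically over each pixel so that every kernel carries
    unit total weight over the plane; z is neglected.

    ``region`` is ``(x_min, y_min, x_max, y_max)`` in nm; the image covers
    it with half-open pixels of ``pixel_size_nm``.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be > 0")
    x0, y0, x1, y1 = region
    nx = int(np.ceil((x1 - x0) / pixel_size_nm))
    ny = int(np.ceil((y1 - y0) / pixel_size_nm))
    if nx < 1 or ny < 1:
        raise ValueError("region must cover at least one pixel")
    img = np.zeros((ny, nx))
    df = table.records
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    sig = np.maximum(df["precision"].to_numpy(), min_sigma_nm)
    xedges = x0 + pixel_size_nm * np.arange(nx + 1)
    yedges = y0 + pixel_size_nm * np.arange(ny + 1)
    for xc, yc, s in zip(xs, ys, sig):
        # clip to a ±6 sigma window for speed
        ix0 = max(0, int((xc - 6 * s - x0) / pixel_size_nm))
        ix1 = min(nx, int((xc + 6 * s - x0) / pixel_size_nm) + 1)
        iy0 = max(0, int((yc - 6 * s - y0) / pixel_size_nm))
        iy1 = min(ny, int((yc + 6 * s - y0) / pixel_size_nm) + 1)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        cx = 0.5 * (erf((xedges[ix0 : ix1 + 1] - xc) / (np.sqrt(2) * s)))
        cy = 0.5 * (erf((yedges[iy0 : iy1 + 1] - yc) / (np.sqrt(2) * s)))
        img[iy0:iy1, ix0:ix1] += np.outer(np.diff(cy), np.diff(cx))
    return RenderedImage(img, pixel_size_nm, origin=(x0, y0))
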