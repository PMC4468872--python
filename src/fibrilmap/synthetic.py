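"""Ground-truth simulators for the staggered-overlap protofibril model.

The model: fibronectin dimers of end-to-end length ``E`` lie extended and
aligned along the fibril axis in a staggered, linear arrangement.  Dimer
``k`` occupies the axial interval ``[k*L, k*L + E]`` where ``L`` is the
repeat length (the periodicity of the assembly), so adjacent molecules
overlap antiparallel over ``O = E - L`` at their N-termini.  Site-specific
antibodies see two epitopes per dimer (one per monomer): an N-terminal site
labels both dimer ends, a C-terminal site labels the dimer centre (the two
monomers' C-termini are bridged by disulfides), and an internal site at
axial distance ``d`` from the centre labels ``centre ± d``.

On top of the geometry, the labeling model reproduces the stochastic
features of real dSTORM data: incomplete labeling (Bernoulli per epitope),
antibody linkage error (isotropic Gaussian scatter of the fluorophore
around its epitope), per-localization precision noise, and multiple
localizations per fluorophore from blinking (geometric count).

Simulators return a :class:`~fibrilmap.core_io.LocalizationTable` plus a
:class:`GroundTruth` recording every epitope and each localization's parent,
so all downstream estimators can be validated against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import COLUMNS, LocalizationTable

__all__ = [
    "FibrilArchitecture",
    "LabelingModel",
    "AntibodySite",
    "N_TERMINAL",
    "C_TERMINAL",
    "internal",
    "GroundTruth",
    "SectionBox",
    "JunctionAnnotation",
    "epitope_positions",
    "simulate_protofibril",
    "simulate_random_fibril",
    "simulate_junction",
    "simulate_dimer_pair_spots",
    "simulate_bleach_movie",
]


@dataclass(frozen=True)
class FibrilArchitecture:
    """Geometry of the staggered protofibril: dimer length ``E``, repeat
    ``L`` and number of repeats, all in nm.  The N-terminal overlap is
    ``O = E - L`` by construction."""

    E: float = 133.0
    L: float = 95.0
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.L <= self.E:
            raise ValueError(f"need 0 < L <= E, got L={self.L}, E={self.E}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def O(self) -> float:  # noqa: E743 - domain symbol
        """N-terminal overlap between adjacent dimers (nm)."""
        return self.E - self.L

    @property
    def length(self) -> float:
        """Axial extent of the assembly (nm)."""
        return (self.n_repeats - 1) * self.L + self.E


@dataclass(frozen=True)
class LabelingModel:
    """Stochastic labeling and localization model.

    efficiency:
        Probability that an epitope carries a fluorophore.
    linkage_error_sd:
        Isotropic 2D Gaussian scatter of the fluorophore around the epitope
        (nm); ~8 nm for a primary+secondary antibody stack, 0 for a dye
        conjugated directly to the protein.
    precision_mean, precision_sd:
        Per-localization lateral precision drawn from a truncated normal
        (nm); the localization is displaced by that precision.
    relocalizations_mean:
        Mean of the geometric (support >= 1) number of localizations each
        fluorophore produces through blinking.
    photons_mean:
        Mean fitted photon count per localization (exponential draw).
    """

    efficiency: float = 0.7
    linkage_error_sd: float = 8.0
    precision_mean: float = 6.0
    precision_sd: float = 1.0
    relocalizations_mean: float = 2.0
    photons_mean: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1:
            raise ValueError("efficiency must be in [0, 1]")
        for name in ("linkage_error_sd", "precision_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.precision_mean <= 0:
            raise ValueError("precision_mean must be > 0")
        if self.relocalizations_mean < 1:
            raise ValueError("relocalizations_mean must be >= 1")


@dataclass(frozen=True)
class AntibodySite:
    """Epitope site on the dimer: ``kind`` in {'N', 'C', 'internal'};
    ``offset`` is the axial distance from the dimer centre for internal
    sites (nm)."""

    kind: str
    offset: float = 0.0


N_TERMINAL = AntibodySite("N")
C_TERMINAL = AntibodySite("C")


def internal(offset_nm: float) -> AntibodySite:
    """Internal epitope at axial distance ``offset_nm`` from dimer centre."""
    return AntibodySite("internal", float(offset_nm))


@dataclass
class GroundTruth:
    """True epitope positions and the provenance of every localization."""

    epitope_x: np.ndarray  # axial epitope positions, nm
    epitope_y: np.ndarray  # transverse axis offsets, nm
    epitope_channel: np.ndarray
    parent_epitope: np.ndarray  # per-localization index into epitope arrays
    architecture: FibrilArchitecture | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.parent_epitope) and len(self.epitope_x):
            if self.parent_epitope.max() >= len(self.epitope_x):
                raise ValueError("localization parent epitope does not exist")


@dataclass(frozen=True)
class SectionBox:
    """A rectangular measurement box on a fibril: centre (nm), unit axis
    direction, length along the axis and width across it (nm)."""

    center: tuple[float, float]
    axis: tuple[float, float] = (1.0, 0.0)
    length: float = 200.0
    width: float = 50.0

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.axis))
        if norm == 0:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))
        if self.length <= 0 or self.width <= 0:
            raise ValueError("box length and width must be > 0")


@dataclass
class JunctionAnnotation:
    """Three section boxes per branch of a fibril junction: the bundled
    segment ``B`` before the branch point and the branches ``A1``, ``A2``."""

    B: list[SectionBox]
    A1: list[SectionBox]
    A2: list[SectionBox]
    label: str = ""


# ---------------------------------------------------------------------------
# Epitope geometry


def epitope_positions(arch: FibrilArchitecture, site: AntibodySite) -> np.ndarray:
    """Axial positions (nm) of all epitopes of one antibody site.

    Dimer ``k`` spans ``[k*L, k*L + E]``.  N-terminal sites label both dimer
    ends, so per period the labels form pairs split by the overlap
    ``O = E - L``; C-terminal sites give two coincident labels at the dimer
    centre; an internal site at distance ``d`` gives ``centre ± d``.
    """
    k = np.arange(arch.n_repeats, dtype=float)
    starts = k * arch.L
    centers = starts + arch.E / 2.0
    if site.kind == "N":
        pos = np.concatenate([starts, starts + arch.E])
    elif site.kind == "C":
        pos = np.concatenate([centers, centers])
    elif site.kind == "internal":
        d = site.offset
        if d > arch.E / 2.0:
            raise ValueError(
                f"internal offset {d} nm exceeds half the dimer length {arch.E / 2} nm"
            )
        pos = np.concatenate([centers - d, centers + d])
    else:
        raise ValueError(f"unknown antibody site kind {site.kind!r}")
    return np.sort(pos)


# ---------------------------------------------------------------------------
# Labeling engine


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                      lower: float = 0.5) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    lower = min(lower, mean)  # never floor above the requested mean
    draws = rng.normal(mean, sd, size)
    while np.any(draws < lower):  # redraw the rare tail below the floor
        bad = draws < lower
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
    return draws


def _label_epitopes(
    epitope_x: np.ndarray,
    epitope_y: np.ndarray,
    channel: int,
    labeling: LabelingModel,
    rng: np.random.Generator,
    max_frame: int = 20000,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Apply the labeling model to epitopes; returns records and the parent
    epitope index of each localization."""
    n = len(epitope_x)
    labeled = rng.random(n) < labeling.efficiency
    idx = np.flatnonzero(labeled)
    rows = {c: [] for c in COLUMNS}
    parents = []
    if len(idx):
        fx = epitope_x[idx] + rng.normal(0, labeling.linkage_error_sd, len(idx))
        fy = epitope_y[idx] + rng.normal(0, labeling.linkage_error_sd, len(idx))
        counts = rng.geometric(1.0 / labeling.relocalizations_mean, len(idx))
        for j, (cx, cy, m) in enumerate(zip(fx, fy, counts)):
            prec = _truncated_normal(rng, labeling.precision_mean,
                                     labeling.precision_sd, int(m))
            rows["x"].extend(cx + rng.normal(0, prec))
            rows["y"].extend(cy + rng.normal(0, prec))
            rows["z"].extend(np.zeros(int(m)))
            rows["frame"].extend(np.sort(rng.integers(0, max_frame, int(m))))
            rows["photons"].extend(rng.exponential(labeling.photons_mean, int(m)))
            rows["precision"].extend(prec)
            rows["channel"].extend(np.full(int(m), channel, dtype=int))
            parents.extend([idx[j]] * int(m))
    df = pd.DataFrame(rows) if rows["x"] else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in COLUMNS}
    )
    return df, np.asarray(parents, dtype=int)


# ---------------------------------------------------------------------------
# Simulators


def simulate_protofibril(
    arch: FibrilArchitecture = FibrilArchitecture(),
    labeling: LabelingModel = LabelingModel(),
    antibody_sites: Sequence[AntibodySite] = (C_TERMINAL,),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate a labeled protofibril lying along the x axis from 0 nm.

    One channel per antibody site, in the order given.  Deterministic for a
    fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    all_df, parents = [], []
    ex, ey, ech = [], [], []
    offset = 0
    for channel, site in enumerate(antibody_sites):
        pos = epitope_positions(arch, site)
        y = np.zeros_like(pos)
        df, par = _label_epitopes(pos, y, channel, labeling, rng)
        all_df.append(df)
        parents.append(par + offset)
        ex.append(pos)
        ey.append(y)
        ech.append(np.full(len(pos), channel, dtype=int))
        offset += len(pos)
    records = pd.concat(all_df, ignore_index=True) if all_df else pd.DataFrame()
    truth = GroundTruth(
        epitope_x=np.concatenate(ex),
        epitope_y=np.concatenate(ey),
        epitope_channel=np.concatenate(ech),
        parent_epitope=np.concatenate(parents) if parents else np.array([], dtype=int),
        architecture=arch,
    )
    return LocalizationTable(records), truth


def simulate_random_fibril(
    length_nm: float,
    label_density: float,
    labeling: LabelingModel = LabelingModel(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Negative control: epitopes from a homogeneous Poisson process of the
    given density (per nm) along the axis, labeled like a real fibril."""
    if label_density < 0:
        raise ValueError("label density must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = rng.poisson(label_density * length_nm)
    pos = np.sort(rng.uniform(0, length_nm, n))
    df, _ = _label_epitopes(pos, np.zeros(n), 0, labeling, rng)
    return LocalizationTable(df if len(df) else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in COLUMNS}))


#: Junction analyses use dense stains (lysine-conjugated protein or a
#: polyclonal antibody hitting many epitopes), not a single site: higher
#: labeling probability and more blinks per fluorophore than the
#: single-epitope default.
JUNCTION_LABELING = LabelingModel(
    efficiency=0.9, linkage_error_sd=8.0, precision_mean=6.0, precision_sd=1.0,
    relocalizations_mean=3.0,
)

#: Epitope sites of a dense polyclonal/lysine-conjugate stain: termini plus
#: internal sites spread quasi-uniformly along the dimer (lysines and
#: polyclonal epitopes are distributed over the whole molecule, unlike a
#: single site-specific antibody).
JUNCTION_SITES = (
    N_TERMINAL, C_TERMINAL,
    internal(10.0), internal(20.0), internal(30.0),
    internal(40.0), internal(50.0), internal(60.0),
)


def simulate_junction(
    arch: FibrilArchitecture = FibrilArchitecture(),
    n_before: int = 2,
    shifts: Sequence[float] | None = None,
    labeling: LabelingModel = JUNCTION_LABELING,
    seed: int | None = None,
    antibody_sites: Sequence[AntibodySite] = JUNCTION_SITES,
    bundle_length_nm: float = 700.0,
    branch_length_nm: float = 700.0,
    axis_spacing_nm: float = 10.0,
    branch_separation_nm: float = 300.0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate a fibril junction under pure bundling.

    ``n_before`` protofibrils run bundled (parallel axes ``axis_spacing_nm``
    apart) along x < 0 and split into separate branches for x > 0: branch 1
    keeps the protofibrils with even index, branch 2 the odd ones.  Pure
    bundling means the bundled segment carries exactly the union of the
    branch protofibrils' molecules — nothing is gained or lost at the
    junction, so the expected junction metric is Δ = 0.

    ``shifts`` are per-protofibril axial offsets (nm) of the repeat pattern;
    default all zero.  The returned ground truth carries a
    :class:`JunctionAnnotation` (three 200x50 nm boxes per branch) in
    ``extras['annotation']``.
    """
    if n_before < 2:
        raise ValueError("a junction needs at least 2 bundled protofibrils")
    if shifts is None:
        shifts = np.zeros(n_before)
    shifts = np.asarray(shifts, dtype=float)
    if len(shifts) != n_before:
        raise ValueError("need one axial shift per protofibril")
    rng = np.random.default_rng(seed)

    total_len = bundle_length_nm + branch_length_nm
    # enough repeats to cover [-bundle, +branch] for any shift
    n_rep = int(np.ceil((total_len + arch.E + np.ptp(shifts)) / arch.L)) + 2
    cover = FibrilArchitecture(E=arch.E, L=arch.L, n_repeats=n_rep)

    all_df, parents = [], []
    ex, ey, ech = [], [], []
    offset = 0
    for p in range(n_before):
        branch = p % 2  # 0 -> A1, 1 -> A2
        y_before = (p - (n_before - 1) / 2.0) * axis_spacing_nm
        y_after = (branch_separation_nm / 2.0) * (1 if branch == 0 else -1) \
            + (p // 2) * axis_spacing_nm
        for channel, site in enumerate(antibody_sites):
            pos = epitope_positions(cover, site) - bundle_length_nm - arch.E + shifts[p]
            keep = (pos >= -bundle_length_nm) & (pos <= branch_length_nm)
            pos = pos[keep]
            y = np.where(pos < 0, y_before, y_after)
            df, par = _label_epitopes(pos, y, channel, labeling, rng)
            all_df.append(df)
            parents.append(par + offset)
            ex.append(pos)
            ey.append(y)
            ech.append(np.full(len(pos), channel, dtype=int))
            offset += len(pos)

    records = pd.concat([d for d in all_df if len(d)], ignore_index=True) \
        if any(len(d) for d in all_df) else pd.DataFrame(
            {c: pd.Series(dtype=float) for c in COLUMNS})

    # section boxes wide enough that their edge bins see only background:
    # the transverse label spread is ~sqrt(linkage^2 + precision^2) around
    # each axis, so cover the bundle plus ~5 sigma on both sides
    sigma_t = float(np.hypot(labeling.linkage_error_sd, labeling.precision_mean))
    box_w = axis_spacing_nm * (n_before - 1) + 10.0 * sigma_t

    def boxes(xs: float, y: float) -> list[SectionBox]:
        step = 220.0 if xs >= 0 else -220.0
        return [SectionBox(center=(xs + step * i, y), axis=(1.0, 0.0),
                           width=box_w) for i in range(3)]

    annotation = JunctionAnnotation(
        B=boxes(-150.0, 0.0),
        A1=boxes(150.0, branch_separation_nm / 2.0),
        A2=boxes(150.0, -branch_separation_nm / 2.0),
    )
    truth = GroundTruth(
        epitope_x=np.concatenate(ex),
        epitope_y=np.concatenate(ey),
        epitope_channel=np.concatenate(ech),
        parent_epitope=np.concatenate(parents) if parents else np.array([], dtype=int),
        architecture=arch,
        extras={"annotation": annotation, "shifts": shifts},
    )
    return LocalizationTable(records), truth


#: Direct dye conjugation on the purified protein: no antibody stack, hence
#: no linkage error, and a dSTORM spot of a stably blinking dye accumulates
#: many localizations.
DIMER_SPOT_LABELING = LabelingModel(
    efficiency=1.0, linkage_error_sd=0.0, precision_mean=6.0, precision_sd=1.0,
    relocalizations_mean=10.0,
)


def simulate_dimer_pair_spots(
    separation_nm: float,
    labeling: LabelingModel = DIMER_SPOT_LABELING,
    seed: int | None = None,
    context_density: float = 0.02,
    context_length_nm: float = 600.0,
    min_localizations_per_end: int = 5,
) -> LocalizationTable:
    """Simulate a single end-labelled dimer inside a co-stained fibril.

    Channel 0 holds the two dye-labelled dimer ends at the given axial
    separation (centred on the fibril axis); channel 1 holds a co-staining
    context along the same axis used to identify the fibril.

    Measured spot pairs are *selected* as two distinct visible spots, so
    the blink count of each end is conditioned on a minimum
    (``min_localizations_per_end``); an end with fewer localizations would
    not appear as a selectable spot in the rendered image.
    """
    if separation_nm < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    ends = np.array([-separation_nm / 2.0, separation_nm / 2.0])
    rows = {c: [] for c in COLUMNS}
    for end in ends:
        cx = end + rng.normal(0, labeling.linkage_error_sd)
        cy = rng.normal(0, labeling.linkage_error_sd)
        m = int(rng.geometric(1.0 / labeling.relocalizations_mean))
        while m < min_localizations_per_end:  # selection: both spots visible
            m = int(rng.geometric(1.0 / labeling.relocalizations_mean))
        prec = _truncated_normal(rng, labeling.precision_mean,
                                 labeling.precision_sd, m)
        rows["x"].extend(cx + rng.normal(0, prec))
        rows["y"].extend(cy + rng.normal(0, prec))
        rows["z"].extend(np.zeros(m))
        rows["frame"].extend(np.sort(rng.integers(0, 20000, m)))
        rows["photons"].extend(rng.exponential(labeling.photons_mean, m))
        rows["precision"].extend(prec)
        rows["channel"].extend(np.zeros(m, dtype=int))
    df0 = pd.DataFrame(rows)
    n_ctx = rng.poisson(context_density * context_length_nm)
    ctx = rng.uniform(-context_length_nm / 2, context_length_nm / 2, n_ctx)
    df1, _ = _label_epitopes(np.sort(ctx), np.zeros(n_ctx), 1,
                             LabelingModel(efficiency=1.0, linkage_error_sd=0.0,
                                           precision_mean=8.0, precision_sd=1.0,
                                           relocalizations_mean=2.0), rng)
    frames = [d for d in (df0, df1) if len(d)]
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in COLUMNS})
    return LocalizationTable(records)


# ---------------------------------------------------------------------------
# Photobleaching movies


def _psf_spot(shape: tuple[int, int], x_px: float, y_px: float,
              sigma_px: float) -> np.ndarray:
    """Pixel-integrated 2D Gaussian PSF with unit total intensity."""
    from scipy.special import erf

    ny, nx = shape
    xe = np.arange(nx + 1) - 0.5
    ye = np.arange(ny + 1) - 0.5
    cx = 0.5 * erf((xe - x_px) / (np.sqrt(2) * sigma_px))
    cy = 0.5 * erf((ye - y_px) / (np.sqrt(2) * sigma_px))
    return np.outer(np.diff(cy), np.diff(cx))


def simulate_bleach_movie(
    n_fluors: int,
    positions_px: Sequence[tuple[float, float]],
    photons_per_fluor: float | Sequence[float],
    bleach_frames: Sequence[int],
    noise_model: str = "poisson",
    seed: int | None = None,
    n_frames: int = 1000,
    shape: tuple[int, int] = (21, 21),
    background: float = 10.0,
    psf_sigma_px: float = 1.4,
    pixel_size_nm: float = 94.0,
    exclusion_radius_px: float = 4.0,
) -> tuple[np.ndarray, dict]:
    """Simulate a stepwise-photobleaching movie of one or more spots.

    Each fluorophore emits a diffraction-limited spot (pixel-integrated 2D
    Gaussian PSF, ``photons_per_fluor`` photons per frame) until its bleach
    frame; afterwards it is dark.  Per-pixel Poisson shot noise on signal
    plus a constant ``background`` photon level (``noise_model='none'``
    disables the noise for exact geometry checks).

    Returns the (n_frames, ny, nx) float movie in photon counts and a ground
    truth dict: positions (px and nm), bleach frames, per-fluor photon
    rates, pixel size and any close-spot warnings.
    """
    if n_fluors < 1:
        raise ValueError("need at least one fluorophore")
    positions = np.asarray(positions_px, dtype=float).reshape(n_fluors, 2)
    bleach = np.asarray(bleach_frames, dtype=int)
    if len(bleach) != n_fluors or np.any(np.diff(bleach) <= 0):
        raise ValueError("bleach_frames must be strictly increasing, one per fluorophore")
    if n_frames < 10:
        raise ValueError("movie needs at least 10 frames")
    if np.any(bleach >= n_frames):
        raise ValueError("bleach frames must fall inside the movie")
    rates = np.broadcast_to(np.asarray(photons_per_fluor, dtype=float), (n_fluors,))
    rng = np.random.default_rng(seed)

    # fluorophores within one ROI are expected (that is the measurement);
    # warn when the spot cloud is too spread out for a single isolated ROI
    warnings_list = []
    centers = positions.mean(axis=0, keepdims=True)
    spread = np.hypot(*(positions - centers).T)
    if np.any(spread > exclusion_radius_px):
        warnings_list.append(
            f"spot spread {spread.max():.1f} px exceeds the exclusion radius "
            f"{exclusion_radius_px} px; ROIs may overlap"
        )
        warnings.warn(warnings_list[-1], stacklevel=2)

    ny, nx = shape
    spots = np.stack([_psf_spot(shape, x, y, psf_sigma_px) for x, y in positions])
    movie = np.empty((n_frames, ny, nx), dtype=float)
    frame_idx = np.arange(n_frames)
    alive = frame_idx[:, None] < bleach[None, :]  # (T, n_fluors)
    clean = np.tensordot(alive * rates[None, :], spots, axes=(1, 0)) + background
    if noise_model == "poisson":
        movie = rng.poisson(clean).astype(float)
    elif noise_model == "none":
        movie = clean
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")

    truth = {
        "positions_px": positions.tolist(),
        "positions_nm": (positions * pixel_size_nm).tolist(),
        "bleach_frames": bleach.tolist(),
        "photons_per_frame": rates.tolist(),
        "background": background,
        "psf_sigma_px": psf_sigma_px,
        "pixel_size_nm": pixel_size_nm,
        "warnings": warnings_list,
    }
    return movie, truth
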