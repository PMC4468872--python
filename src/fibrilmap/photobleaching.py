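"""Stepwise-photobleaching analysis: step counting and sub-diffraction
localization from difference images.

A diffraction-limited spot containing a few fluorophores bleaches in
discrete downward intensity steps, one per fluorophore.  The pipeline:

1. :func:`detect_spots` — isolated intensity maxima in an early movie frame
   become 9x9-pixel regions of interest (ROIs); overlapping or saturated
   ROIs are excluded.
2. :func:`extract_trace` / :func:`find_steps` — the per-frame summed ROI
   intensity is segmented into plateaus (minimum five frames) by a greedy
   change-point search with the number of steps chosen by the Bayesian
   information criterion.
3. :func:`filter_traces` — traces with upward steps, step heights varying
   by more than a factor of two, incomplete bleaching, or a poor
   piecewise-constant fit are rejected.
4. :func:`difference_roi_localize` — for each step, the summed ROI after
   the step is rescaled to the length of the plateau before it and
   subtracted; the difference image isolates the single bleached
   fluorophore and is fitted by a 2D Gaussian, localizing it far below the
   diffraction limit.
5. :func:`step_distances` — Euclidean distances between the two step
   localizations of two-step spots measure inter-fluorophore separations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import curve_fit

__all__ = [
    "Plateau",
    "StepFit",
    "BleachTrace",
    "StepLocalization",
    "detect_spots",
    "extract_trace",
    "find_steps",
    "find_steps_exhaustive",
    "filter_traces",
    "difference_roi_localize",
    "step_distances",
    "analyze_movie",
]

#: First movie frame used for spot detection (0-based; the fifth image).
DEFAULT_START_FRAME = 4
#: ROI edge length in pixels (odd).
DEFAULT_ROI_SIZE = 9
#: Minimum plateau length in frames.
DEFAULT_MIN_PLATEAU = 5
#: Camera saturation level (photon-converted counts).
DEFAULT_SATURATION = 65535.0


@dataclass(frozen=True)
class Plateau:
    """A constant-intensity segment of a bleach trace: frames
    [start, end) at the given mean level."""

    start: int
    end: int
    level: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StepFit:
    """Piecewise-constant segmentation of a bleach trace."""

    plateaus: list[Plateau]
    rss: float
    bic: float

    @property
    def n_steps(self) -> int:
        return len(self.plateaus) - 1

    @property
    def step_frames(self) -> list[int]:
        """Frame index of each step (first frame of the following plateau)."""
        return [p.start for p in self.plateaus[1:]]

    @property
    def step_heights(self) -> list[float]:
        """Downward steps are positive."""
        return [
            self.plateaus[i].level - self.plateaus[i + 1].level
            for i in range(self.n_steps)
        ]


@dataclass
class BleachTrace:
    """Per-ROI intensity time series with its segmentation and QC status."""

    center: tuple[int, int]  # (row, col) pixel of the ROI centre
    intensity: np.ndarray  # summed ROI photons per frame
    fit: StepFit | None = None
    accepted: bool = False
    reject_reason: str = ""


@dataclass
class StepLocalization:
    """A single bleached fluorophore localized from a difference image."""

    x_nm: float
    y_nm: float
    sigma_nm: float
    intensity: float  # integrated photons in the difference image
    background: float  # fitted constant offset (photons / pixel)
    precision_nm: float
    step_index: int

    def __post_init__(self) -> None:
        if self.precision_nm <= 0:
            raise ValueError("precision must be > 0")


# ---------------------------------------------------------------------------
# Spot detection and trace extraction


def detect_spots(
    movie: np.ndarray,
    threshold: float,
    roi_size_px: int = DEFAULT_ROI_SIZE,
    start_frame: int = DEFAULT_START_FRAME,
    saturation: float = DEFAULT_SATURATION,
) -> list[tuple[int, int]]:
    """Find isolated spots in ``movie[start_frame]`` as ROI centres.

    Local maxima above ``threshold`` whose ROIs fit inside the image become
    candidates; any two candidates with overlapping ROIs are both dropped
    (only isolated spots are usable), as are ROIs containing a pixel at or
    above ``saturation`` in any frame.  Returns (row, col) centres.
    """
    if roi_size_px % 2 != 1:
        raise ValueError("ROI size must be odd")
    frame = np.asarray(movie[start_frame], dtype=float)
    half = roi_size_px // 2
    # candidates are plain local maxima; isolation is enforced by the
    # ROI-overlap rule below (both members of a close pair are dropped)
    is_max = (frame == maximum_filter(frame, size=3)) & (frame > threshold)
    rows, cols = np.nonzero(is_max)
    candidates = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if half <= r < frame.shape[0] - half and half <= c < frame.shape[1] - half
    ]
    # drop every member of an overlapping pair
    keep = []
    for i, (r, c) in enumerate(candidates):
        isolated = all(
            not (abs(r - r2) < roi_size_px and abs(c - c2) < roi_size_px)
            for j, (r2, c2) in enumerate(candidates)
            if j != i
        )
        if isolated:
            keep.append((r, c))
    # saturation check over the whole movie
    out = []
    mov = np.asarray(movie)
    for r, c in keep:
        roi = mov[:, r - half : r + half + 1, c - half : c + half + 1]
        if np.max(roi) >= saturation:
            continue
        out.append((r, c))
    return out


def extract_trace(
    movie: np.ndarray, center: tuple[int, int], roi_size_px: int = DEFAULT_ROI_SIZE
) -> BleachTrace:
    """Summed ROI intensity per frame for one spot."""
    half = roi_size_px // 2
    r, c = center
    roi = np.asarray(movie, dtype=float)[
        :, r - half : r + half + 1, c - half : c + half + 1
    ]
    return BleachTrace(center=center, intensity=roi.sum(axis=(1, 2)))


# ---------------------------------------------------------------------------
# Step finding


def _segment_cost(cum: np.ndarray, cum2: np.ndarray, i: int, j: int) -> float:
    """RSS of trace[i:j] around its mean, from prefix sums."""
    n = j - i
    s = cum[j] - cum[i]
    ss = cum2[j] - cum2[i]
    return float(ss - s * s / n)


def _bic(n: int, rss: float, n_steps: int) -> float:
    # parameters: n_steps+1 plateau levels and n_steps change points
    p = 2 * n_steps + 1
    return n * np.log(max(rss, 1e-12) / n) + p * np.log(n)


def _plateaus_from_bounds(
    y: np.ndarray, bounds: list[int]
) -> list[Plateau]:
    return [
        Plateau(bounds[i], bounds[i + 1], float(y[bounds[i] : bounds[i + 1]].mean()))
        for i in range(len(bounds) - 1)
    ]


def find_steps(
    trace: np.ndarray | BleachTrace,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
    max_steps: int = 10,
) -> StepFit:
    """Segment a bleach trace into intensity plateaus.

    Greedy change-point placement: starting from a single plateau, the split
    that most reduces the residual sum of squares is added one at a time
    (each resulting plateau at least ``min_plateau_frames`` long); the
    number of steps is then chosen as the model with minimal Bayesian
    information criterion along that greedy path.
    """
    y = trace.intensity if isinstance(trace, BleachTrace) else np.asarray(trace, dtype=float)
    n = len(y)
    m = int(min_plateau_frames)
    if n < 2 * m:
        raise ValueError(
            f"trace of {n} frames is shorter than two minimum plateaus ({2 * m})"
        )
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y.astype(float) ** 2)])

    def _refine(bnds: list[int]) -> list[int]:
        # re-optimize each interior change point between its neighbours
        # until stable (one or two passes in practice)
        bnds = list(bnds)
        for _ in range(5):
            moved = False
            for k in range(1, len(bnds) - 1):
                i, j = bnds[k - 1], bnds[k + 1]
                ts = np.arange(i + m, j - m + 1)
                if len(ts) == 0:
                    continue
                s1 = cum[ts] - cum[i]
                s2 = cum[j] - cum[ts]
                costs = -s1 * s1 / (ts - i) - s2 * s2 / (j - ts)
                t_best = int(ts[np.argmin(costs)])
                if t_best != bnds[k]:
                    bnds[k] = t_best
                    moved = True
            if not moved:
                break
        return bnds

    def _rss_of(bnds: list[int]) -> float:
        return sum(
            _segment_cost(cum, cum2, bnds[i], bnds[i + 1])
            for i in range(len(bnds) - 1)
        )

    bounds = [0, n]
    rss = _segment_cost(cum, cum2, 0, n)
    path = [(list(bounds), rss)]
    while len(bounds) - 2 < max_steps:
        best = None  # (new_rss, insert_pos, t)
        for k in range(len(bounds) - 1):
            i, j = bounds[k], bounds[k + 1]
            if j - i < 2 * m:
                continue
            ts = np.arange(i + m, j - m + 1)
            n1 = ts - i
            n2 = j - ts
            s1 = cum[ts] - cum[i]
            s2 = cum[j] - cum[ts]
            ss = cum2[j] - cum2[i]
            costs = ss - s1 * s1 / n1 - s2 * s2 / n2
            t_best = int(ts[np.argmin(costs)])
            new_rss = rss - _segment_cost(cum, cum2, i, j) + float(np.min(costs))
            if best is None or new_rss < best[0]:
                best = (new_rss, k + 1, t_best)
        if best is None:
            break
        bounds.insert(best[1], best[2])
        bounds.sort()
        bounds = _refine(bounds)
        rss = _rss_of(bounds)
        path.append((list(bounds), rss))

    best_fit = None
    for bnds, r in path:
        bic = _bic(n, r, len(bnds) - 2)
        if best_fit is None or bic < best_fit.bic:
            best_fit = StepFit(_plateaus_from_bounds(y, bnds), r, bic)
    return best_fit


def find_steps_exhaustive(
    trace: np.ndarray,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
    max_steps: int = 3,
) -> StepFit:
    """Exhaustive change-point search for short traces.

    Enumerates every admissible set of up to ``max_steps`` change points and
    selects the global BIC optimum.  Exponential in ``max_steps``; intended
    as an independent reference for :func:`find_steps` on traces of a few
    tens of frames.
    """
    from itertools import combinations

    y = np.asarray(trace, dtype=float)
    n = len(y)
    m = int(min_plateau_frames)
    if n < 2 * m:
        raise ValueError("trace shorter than two minimum plateaus")
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y**2)])

    best: StepFit | None = None
    positions = range(m, n - m + 1)
    for k in range(0, max_steps + 1):
        for cps in combinations(positions, k):
            bnds = [0, *cps, n]
            if any(bnds[i + 1] - bnds[i] < m for i in range(len(bnds) - 1)):
                continue
            r = sum(
                _segment_cost(cum, cum2, bnds[i], bnds[i + 1])
                for i in range(len(bnds) - 1)
            )
            bic = _bic(n, r, k)
            if best is None or bic < best.bic:
                best = StepFit(_plateaus_from_bounds(y, bnds), r, bic)
    return best


# ---------------------------------------------------------------------------
# Trace quality filters


def filter_traces(
    trace: BleachTrace,
    max_height_ratio: float = 2.0,
    chi2_max: float = 3.0,
    background_level: float | None = None,
    incomplete_tol: float = 0.5,
) -> BleachTrace:
    """Apply the trace quality rules; sets ``accepted`` and the reason.

    Rejects traces with no step, any upward step, step heights varying by
    more than ``max_height_ratio``, incomplete bleaching (final plateau
    above the background by more than ``incomplete_tol`` of the smallest
    step, when ``background_level`` is given), or a reduced chi-square of
    the plateau fit above ``chi2_max`` (variance taken as the Poisson
    expectation, i.e. the local plateau level).
    """
    if trace.fit is None:
        trace.fit = find_steps(trace)
    fit = trace.fit
    heights = fit.step_heights
    trace.accepted = False
    if fit.n_steps == 0:
        trace.reject_reason = "no bleaching step found"
        return trace
    if any(h <= 0 for h in heights):
        trace.reject_reason = "upward step"
        return trace
    if max(heights) / min(heights) > max_height_ratio:
        trace.reject_reason = (
            f"step heights vary by more than a factor of {max_height_ratio:g}"
        )
        return trace
    if background_level is not None:
        residual_signal = fit.plateaus[-1].level - background_level
        if residual_signal > incomplete_tol * min(heights):
            trace.reject_reason = "did not bleach completely"
            return trace
    # reduced chi-square of the piecewise-constant fit under Poisson noise
    dof = max(len(trace.intensity) - (2 * fit.n_steps + 1), 1)
    var = np.concatenate(
        [np.full(p.length, max(p.level, 1.0)) for p in fit.plateaus]
    )
    model = np.concatenate([np.full(p.length, p.level) for p in fit.plateaus])
    chi2 = float(np.sum((trace.intensity - model) ** 2 / var) / dof)
    if chi2 > chi2_max:
        trace.reject_reason = f"plateau fit does not resemble the data (chi2={chi2:.2f})"
        return trace
    trace.accepted = True
    trace.reject_reason = ""
    return trace


# ---------------------------------------------------------------------------
# Difference-ROI localization


def _gauss2d(coords, photons, x0, y0, sigma, offset):
    """Pixel-integrated 2D Gaussian: ``photons`` is the total integrated
    intensity, ``offset`` a constant per-pixel background."""
    from scipy.special import erf as _erf

    x, y = coords
    sq2 = np.sqrt(2.0) * sigma
    fx = 0.5 * (_erf((x + 0.5 - x0) / sq2) - _erf((x - 0.5 - x0) / sq2))
    fy = 0.5 * (_erf((y + 0.5 - y0) / sq2) - _erf((y - 0.5 - y0) / sq2))
    return (photons * fx * fy + offset).ravel()


def _thompson_precision(
    sigma_nm: float, pixel_nm: float, photons: float, bg_noise_sd: float
) -> float:
    """Lateral localization error of a Gaussian-PSF fit (Thompson-style):
    shot-noise and pixelation terms plus the background term."""
    s2 = sigma_nm**2 + pixel_nm**2 / 12.0
    var = s2 / photons + 8 * np.pi * sigma_nm**4 * bg_noise_sd**2 / (
        pixel_nm**2 * photons**2
    )
    return float(np.sqrt(var))


def difference_roi_localize(
    movie: np.ndarray,
    center: tuple[int, int],
    fit: StepFit,
    pixel_size_nm: float = 94.0,
    roi_size_px: int = DEFAULT_ROI_SIZE,
    residual_se_factor: float = 2.0,
) -> list[StepLocalization]:
    """Localize each bleached fluorophore from plateau difference images.

    For step ``i`` (between plateaus ``i`` and ``i+1``): the ROI frames of
    each plateau are summed; the after-sum is rescaled by the ratio of
    plateau lengths so both represent the same exposure, and subtracted
    from the before-sum.  The difference image contains only the
    fluorophore that bleached at that step and is least-squares fitted by a
    2D Gaussian (free x, y, width, amplitude, constant background).

    If any fit diverges, or its residuals show systematic structure (the
    mean residual of any ROI quadrant exceeding ``residual_se_factor``
    standard errors), the whole spot is discarded by raising
    ``RuntimeError`` — mirroring how such spots are excluded in practice.
    """
    if len(fit.plateaus) < 2:
        raise ValueError("need at least two plateaus for a difference image")
    half = roi_size_px // 2
    r, c = center
    mov = np.asarray(movie, dtype=float)
    roi = mov[:, r - half : r + half + 1, c - half : c + half + 1]
    yy, xx = np.mgrid[0:roi_size_px, 0:roi_size_px]
    out: list[StepLocalization] = []
    for i in range(len(fit.plateaus) - 1):
        before, after = fit.plateaus[i], fit.plateaus[i + 1]
        sum_before = roi[before.start : before.end].sum(axis=0)
        sum_after = roi[after.start : after.end].sum(axis=0)
        scale = before.length / after.length
        diff = sum_before - scale * sum_after

        med = float(np.median(diff))
        photons0 = float(diff.sum() - med * diff.size)
        p0 = [max(photons0, 1.0), float(np.argmax(diff.max(axis=0))),
              float(np.argmax(diff.max(axis=1))), 1.5, med]
        try:
            popt, _ = curve_fit(
                _gauss2d, (xx, yy), diff.ravel(), p0=p0,
                bounds=([0, -1, -1, 0.3, -np.inf],
                        [np.inf, roi_size_px, roi_size_px, roi_size_px, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"difference-image fit diverged at step {i}; spot discarded"
            ) from exc
        photons, x0, y0, sigma, offset = popt
        resid = diff - _gauss2d((xx, yy), *popt).reshape(diff.shape)
        # systematic-structure check per ROI quadrant; meaningless when the
        # residuals are numerically negligible against the signal
        if resid.std(ddof=1) > 1e-6 * max(photons, 1.0):
            h = roi_size_px // 2
            quads = [resid[:h, :h], resid[:h, h:], resid[h:, :h], resid[h:, h:]]
            for q in quads:
                se = q.std(ddof=1) / np.sqrt(q.size)
                if se > 0 and abs(q.mean()) > residual_se_factor * se:
                    raise RuntimeError(
                        f"systematic residual structure at step {i}; spot discarded"
                    )
        photons = float(photons)
        bg_noise = float(resid.std(ddof=1))
        precision = _thompson_precision(
            sigma * pixel_size_nm, pixel_size_nm, max(photons, 1.0), bg_noise
        )
        out.append(
            StepLocalization(
                x_nm=float((c - half + x0) * pixel_size_nm),
                y_nm=float((r - half + y0) * pixel_size_nm),
                sigma_nm=float(sigma * pixel_size_nm),
                intensity=photons,
                background=float(offset),
                precision_nm=precision,
                step_index=i,
            )
        )
    return out


def step_distances(
    step_localizations: list[StepLocalization], require_steps: int = 2
) -> float:
    """Euclidean distance (nm) between the two localizations of a two-step
    spot.  Spots with any other number of steps measure aggregates or
    overlapping molecules and are excluded."""
    if len(step_localizations) != require_steps:
        raise ValueError(
            f"spot has {len(step_localizations)} steps; exactly "
            f"{require_steps} required for a distance"
        )
    a, b = step_localizations
    return float(np.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm))


# ---------------------------------------------------------------------------
# Convenience pipeline


def analyze_movie(
    movie: np.ndarray,
    threshold: float,
    pixel_size_nm: float = 94.0,
    roi_size_px: int = DEFAULT_ROI_SIZE,
    start_frame: int = DEFAULT_START_FRAME,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
    background_level: float | None = None,
) -> list[dict]:
    """Run the full stepwise-photobleaching pipeline on one movie.

    Returns one record per detected spot: the trace, its segmentation and
    QC status, and (for accepted two-step spots) the step localizations
    and their pairwise distance.
    """
    results = []
    for center in detect_spots(
        movie, threshold, roi_size_px=roi_size_px, start_frame=start_frame
    ):
        trace = extract_trace(movie, center, roi_size_px=roi_size_px)
        trace.fit = find_steps(trace, min_plateau_frames=min_plateau_frames)
        trace = filter_traces(trace, background_level=background_level)
        record: dict = {"center": center, "trace": trace}
        if trace.accepted and trace.fit.n_steps == 2:
            try:
                locs = difference_roi_localize(
                    movie, center, trace.fit,
                    pixel_size_nm=pixel_size_nm, roi_size_px=roi_size_px,
                )
                record["localizations"] = locs
                record["distance_nm"] = step_distances(locs)
            except RuntimeError as exc:
                trace.accepted = False
                trace.reject_reason = str(exc)
        results.append(record)
    return results
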