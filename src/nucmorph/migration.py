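"""3D interstitial migration scoring and 2D scratch-closure kinetics.

Migration into a devitalized tissue substrate is scored from two-channel
confocal z-stacks: the explant-ECM interface plane is detected from the
tissue channel's per-plane occupancy profile, cells are found as local
maxima of the smoothed cell channel, and each cell's infiltration depth is
the signed distance of its centroid below the interface (positive = into
tissue).  A cell counts as migrated when fully embedded, operationalized
as depth >= an embedding margin approximating the blob radius.

Scratch closure is scored from image time series: the cell-free void is
detected as a low-local-variance region (texture, not raw brightness,
distinguishes cells from void), and the closure rate is the OLS slope of
scratch area versus time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "CellRecord",
    "MigrationStack",
    "ScratchSeries",
    "detect_interface",
    "score_cells",
    "percent_migrated",
    "cumulative_frequency",
    "scratch_area",
    "closure_rate",
]


@dataclass
class CellRecord:
    """One detected cell: centroid in um, signed depth, embedded flag."""

    x_um: float
    y_um: float
    z_um: float
    depth_um: float
    embedded: bool


@dataclass
class MigrationStack:
    """Two-channel z-stack with detected interface and per-cell depths."""

    cell_channel: np.ndarray
    tissue_channel: np.ndarray
    z_step_um: float
    px_size_um: float = 1.0
    interface_z_um: float | None = None
    cells: list[CellRecord] = field(default_factory=list)


def detect_interface(tissue_channel: np.ndarray, z_step_um: float) -> float:
    """Locate the explant-ECM interface from the tissue channel.

    The per-plane tissue occupancy fraction (Otsu-binarized over the whole
    stack) rises from ~0 above the tissue to a plateau inside it; the
    interface is the first z, linearly interpolated between planes, where
    occupancy crosses half the plateau value.

    Raises when the channel is empty/constant or occupancy never crosses
    half-plateau.
    """
    tissue_channel = np.asarray(tissue_channel, dtype=np.float64)
    if tissue_channel.ndim != 3:
        raise ValueError("tissue channel must be a 3D (z, y, x) stack")
    if tissue_channel.shape[0] < 3:
        raise ValueError("stack needs at least 3 planes")
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")
    if tissue_channel.max() == tissue_channel.min():
        raise ValueError("tissue channel is constant; no interface")
    thr = threshold_otsu(tissue_channel)
    occ = (tissue_channel > thr).mean(axis=(1, 2))
    nz = len(occ)
    # support both orientations: tissue may enter from either end of z
    rising = occ[: nz // 2].mean() <= occ[(nz + 1) // 2 :].mean()
    prof = occ if rising else occ[::-1]
    z = _first_half_plateau_crossing(prof) * z_step_um
    if not rising:
        z = (nz - 1) * z_step_um - z
    return float(z)


def _first_half_plateau_crossing(occ: np.ndarray) -> float:
    """First index (interpolated) where occupancy crosses half its plateau."""
    half = occ.max() / 2.0
    above = occ >= half
    if above.all():
        raise ValueError("occupancy never crosses half-plateau")
    idx = int(np.argmax(above))
    if idx == 0:
        return 0.0
    o0, o1 = occ[idx - 1], occ[idx]
    frac = (half - o0) / (o1 - o0) if o1 > o0 else 0.0
    return idx - 1 + frac


def _refine_z(profile: np.ndarray, k: int) -> float:
    """Parabolic sub-plane refinement of a peak along z."""
    if k <= 0 or k >= len(profile) - 1:
        return float(k)
    y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(k)
    return float(k + 0.5 * (y0 - y2) / denom)


def score_cells(
    stack: MigrationStack,
    embed_margin_um: float = 5.0,
    blob_radius_um: float = 5.0,
    threshold_rel: float = 0.3,
) -> list[CellRecord]:
    """Detect cells in the smoothed cell channel and score their depths.

    Cells are local maxima of the Gaussian-smoothed cell channel above
    ``threshold_rel`` times its maximum, separated by at least twice the
    blob radius; the z coordinate is refined to sub-plane precision by a
    parabolic fit through the peak's z profile.  ``embedded`` is
    depth >= ``embed_margin_um``.  Requires a detected interface
    (:func:`detect_interface` is run if needed).  Results are stored on
    the stack and returned.
    """
    if stack.interface_z_um is None:
        stack.interface_z_um = detect_interface(stack.tissue_channel, stack.z_step_um)
    cellch = np.asarray(stack.cell_channel, dtype=np.float64)
    sigma_vox = (
        blob_radius_um / 2.0 / stack.z_step_um,
        blob_radius_um / 2.0 / stack.px_size_um,
        blob_radius_um / 2.0 / stack.px_size_um,
    )
    smooth = ndi.gaussian_filter(cellch, sigma=sigma_vox)
    if smooth.max() <= 0:
        stack.cells = []
        return stack.cells
    min_dist = (
        max(1, int(round(2 * blob_radius_um / stack.z_step_um))),
        max(1, int(round(2 * blob_radius_um / stack.px_size_um))),
        max(1, int(round(2 * blob_radius_um / stack.px_size_um))),
    )
    peaks = peak_local_max(
        smooth,
        min_distance=max(min_dist) if len(set(min_dist)) == 1 else 1,
        threshold_abs=threshold_rel * smooth.max(),
        exclude_border=False,
    )
    # enforce anisotropic separation in um (peak_local_max is isotropic)
    scale = np.array([stack.z_step_um, stack.px_size_um, stack.px_size_um])
    peaks = peaks[np.argsort(-smooth[tuple(peaks.T)])] if len(peaks) else peaks
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(
            np.linalg.norm((p - q) * scale) >= 2 * blob_radius_um for q in kept
        ):
            kept.append(p)
    cells: list[CellRecord] = []
    for p in kept:
        k, y, x = (int(v) for v in p)
        z_ref = _refine_z(smooth[:, y, x], k)
        z_um = z_ref * stack.z_step_um
        depth = z_um - stack.interface_z_um
        cells.append(
            CellRecord(
                x_um=float(x * stack.px_size_um),
                y_um=float(y * stack.px_size_um),
                z_um=float(z_um),
                depth_um=float(depth),
                embedded=bool(depth >= embed_margin_um),
            )
        )
    stack.cells = cells
    return cells


def percent_migrated(cells: list[CellRecord]) -> float:
    """Percent of cells fully embedded: 100 x embedded / total."""
    if len(cells) == 0:
        raise ValueError("no cells to score")
    return 100.0 * sum(c.embedded for c in cells) / len(cells)


def cumulative_frequency(
    depths_um: np.ndarray, bin_edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative frequency (%) of infiltration depths at each bin edge.

    Returns ``(edges, pct)`` where ``pct[i]`` is the percentage of depths
    <= ``edges[i]``; the maximum depth is appended as a final edge when
    the given edges do not cover it, so the curve always ends at 100%.
    """
    depths = np.asarray(depths_um, dtype=np.float64)
    if depths.size == 0:
        raise ValueError("no depths supplied")
    if not np.all(np.isfinite(depths)):
        raise ValueError("depths must be finite")
    edges = np.sort(np.asarray(bin_edges, dtype=np.float64))
    if edges.size == 0 or edges[-1] < depths.max():
        edges = np.append(edges, depths.max())
    pct = np.array(
        [100.0 * np.count_nonzero(depths <= e) / depths.size for e in edges]
    )
    return edges, pct


def scratch_area(
    image: np.ndarray,
    window_px: int = 7,
    closing_radius_px: int = 5,
    separation_ratio: float = 0.2,
) -> tuple[float, bool]:
    """Scratch (cell-free void) area of one frame, in px^2.

    The void is detected from a local intensity-variance map (window
    ``window_px``): confluent cell regions are high-variance speckle while
    the void is flat.  The variance map is Otsu-thresholded on a log scale
    (robust when the void is a small fraction of the frame), the
    low-variance mask is morphologically closed, and the largest connected
    component spanning the full frame height is taken as the scratch.  Two
    safeguards make the detector honest on confluent frames: the void's
    mean variance must be below ``separation_ratio`` times the cell
    region's mean variance (otherwise there is no true void and (0, True)
    is returned), and the detected void is dilated by the window
    half-width to undo the erosion the sliding window causes at the
    void/cell boundary.

    Returns ``(area_px2, no_void_flag)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    mean = ndi.uniform_filter(image, size=window_px, mode="reflect")
    meansq = ndi.uniform_filter(image**2, size=window_px, mode="reflect")
    var = np.maximum(meansq - mean**2, 0.0)
    if var.max() == var.min():
        return 0.0, True
    logvar = np.log10(var + 1e-12)
    thr = threshold_otsu(logvar)
    low = logvar < thr
    if not low.any() or low.all():
        return 0.0, True
    if var[low].mean() > separation_ratio * max(var[~low].mean(), 1e-300):
        return 0.0, True  # no genuine void: both classes are cell texture
    # closing with border_value=1 on the erosion so the void is not
    # clipped where it meets the frame edge
    selem = disk(closing_radius_px)
    low = ndi.binary_erosion(
        ndi.binary_dilation(low, structure=selem), structure=selem, border_value=1
    )
    labels, n = ndi.label(low)
    h = image.shape[0]
    best = 0.0
    found = False
    for lab in range(1, n + 1):
        comp = labels == lab
        rows = np.nonzero(comp.any(axis=1))[0]
        if rows[0] == 0 and rows[-1] == h - 1:  # spans full frame height
            comp = ndi.binary_dilation(comp, structure=disk(window_px // 2))
            area = float(comp.sum())
            if area > best:
                best = area
                found = True
    if not found:
        return 0.0, True
    return best, False


@dataclass
class ScratchSeries:
    """Scratch areas over time with the fitted closure rate."""

    times_h: np.ndarray
    areas_px2: np.ndarray
    closure_rate: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=np.float64)
        self.areas_px2 = np.asarray(self.areas_px2, dtype=np.float64)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas_px2 < 0):
            raise ValueError("areas must be non-negative")


def closure_rate(series: ScratchSeries) -> float:
    """OLS slope of scratch area vs time (area per hour, negative = closing).

    Fitted over frames before the first zero-area frame (areas measured
    after closure carry no kinetic information).
    """
    areas = series.areas_px2
    times = series.times_h
    zero = np.nonzero(areas == 0)[0]
    end = int(zero[0]) if zero.size else len(areas)
    t, a = times[:end], areas[:end]
    if len(a) < 2:
        raise ValueError("need at least 2 pre-closure frames to fit a rate")
    slope = float(np.polyfit(t, a, 1)[0])
    series.closure_rate = slope
    return slope
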