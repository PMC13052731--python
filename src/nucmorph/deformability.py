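"""Nuclear aspect ratio (NAR) and its response to applied strain.

NAR is the major/minor axis ratio of the ellipse sharing the mask's second
central moments.  Under increasing substrate strain a softer, more
deformable nucleus elongates more, so the per-nucleus NAR-vs-strain slope
and the pooled correlation of (strain, delta-NAR) summarize nuclear
deformability.  Nuclei are tracked across strain frames by greedy
nearest-centroid matching after compensating the global affine stretch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .segment import LabeledNucleiField

__all__ = [
    "StrainSeries",
    "NarStrainResponse",
    "nar",
    "match_nuclei",
    "build_strain_series",
    "nar_strain_response",
]

logger = logging.getLogger(__name__)


def nar(mask: np.ndarray) -> float:
    """Nuclear aspect ratio of a boolean mask.

    Ratio of the major to minor axis of the ellipse with the same second
    central moments as the mask; >= 1 by construction and invariant to
    rotation and translation.

    Raises on masks below 5 px or with a degenerate (sub-pixel) minor axis.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) < 5:
        raise ValueError("mask too small for moment ellipse (area < 5 px)")
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / len(c)
    evals = np.linalg.eigvalsh(cov)
    # degeneracy judged on the raw moments: a sub-pixel minor axis means
    # the mask carries no usable width information
    if 4.0 * np.sqrt(max(evals[0], 0.0)) < 1.0:
        raise ValueError("degenerate mask: minor axis below 1 px")
    # each pixel is a unit square represented by its centre; the region's
    # continuous covariance exceeds the centre covariance by the
    # within-pixel variance 1/12 (Sheppard-style correction), which
    # matters for small nuclei
    evals = evals + 1.0 / 12.0
    # moment-equivalent ellipse axis length = 4*sqrt(eigenvalue)
    minor = 4.0 * np.sqrt(evals[0])
    major = 4.0 * np.sqrt(evals[1])
    return float(major / minor)


def _estimate_stretch(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> np.ndarray:
    """Per-axis global stretch (row, col) between two centroid clouds.

    Uses the ratio of centroid-cloud standard deviations about the cloud
    mean, which is exact for a pure diagonal affine stretch and robust to
    which nuclei are present as long as the clouds largely overlap.
    """
    if len(centroids_a) < 3 or len(centroids_b) < 3:
        return np.ones(2)
    sa = centroids_a.std(axis=0)
    sb = centroids_b.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(sa > 0, sb / sa, 1.0)
    return np.where(np.isfinite(s), s, 1.0)


def match_nuclei(
    frame_a: LabeledNucleiField,
    frame_b: LabeledNucleiField,
    max_disp_px: float = 15.0,
    stretch: tuple[float, float] | None = None,
) -> list[tuple[int, int]]:
    """Greedy nearest-centroid correspondence between two frames.

    Frame-a centroids are mapped through the global (row, col) stretch —
    estimated from the centroid clouds when not given — before matching.
    Candidate pairs within ``max_disp_px`` are accepted greedily by
    increasing distance; each object is matched at most once.  Returns
    (label_a, label_b) pairs.
    """
    ca = frame_a.centroids
    cb = frame_b.centroids
    if len(ca) == 0 or len(cb) == 0:
        return []
    s = np.asarray(stretch, dtype=float) if stretch is not None else _estimate_stretch(ca, cb)
    centre_a = ca.mean(axis=0)
    centre_b = cb.mean(axis=0)
    mapped = centre_b + (ca - centre_a) * s

    d = np.linalg.norm(mapped[:, None, :] - cb[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in order:
        if d[i, j] > max_disp_px:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        pairs.append((frame_a.regions[i].label, frame_b.regions[j].label))
    return pairs


@dataclass
class StrainSeries:
    """Per-nucleus NAR tracked across strain levels.

    ``tracks`` maps a persistent track id to a list of (strain, NAR)
    observations; every track starts at strain 0.
    """

    strains: list[float]
    frames: list[LabeledNucleiField]
    tracks: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


def build_strain_series(
    frames: list[LabeledNucleiField],
    strains: list[float],
    max_disp_px: float = 15.0,
) -> StrainSeries:
    """Track nuclei through a strain series and record NAR per observation.

    Tracks are anchored at the strain-0 frame (track id = label there) and
    extended frame-to-frame; a track that loses its nucleus at any strain
    is censored from later frames rather than interpolated.
    """
    if len(frames) != len(strains):
        raise ValueError("frames and strains length mismatch")
    if any(b <= a for a, b in zip(strains, strains[1:])):
        raise ValueError("strains must be strictly increasing")
    series = StrainSeries(strains=list(strains), frames=list(frames))
    label_by_region = {
        r.label: nar(r.mask) for r in frames[0].regions if r.area_px >= 5
    }
    current = {lbl: lbl for lbl in label_by_region}  # track id -> label in frame i
    for tid, lbl in current.items():
        series.tracks[tid] = [(strains[0], label_by_region[lbl])]
    for i in range(1, len(frames)):
        pairs = dict(match_nuclei(frames[i - 1], frames[i], max_disp_px))
        nar_b = {r.label: r for r in frames[i].regions}
        nxt: dict[int, int] = {}
        for tid, lbl in current.items():
            if lbl not in pairs:
                continue
            lbl_b = pairs[lbl]
            try:
                v = nar(nar_b[lbl_b].mask)
            except ValueError:
                continue
            series.tracks[tid].append((strains[i], v))
            nxt[tid] = lbl_b
        current = nxt
    return series


@dataclass
class NarStrainResponse:
    """Per-track NAR-vs-strain slopes plus the pooled correlation."""

    slopes: dict[int, float]
    pearson_r: float
    constant: bool  # True when delta-NAR had no variance (r reported as 0)
    n_excluded: int


def nar_strain_response(series: StrainSeries) -> NarStrainResponse:
    """OLS slope of NAR vs strain per track and pooled Pearson correlation.

    The correlation pools (strain, delta-NAR) pairs across tracks, where
    delta-NAR is relative to each track's strain-0 value.  Tracks with
    fewer than 2 observations are excluded (count logged and reported).
    """
    slopes: dict[int, float] = {}
    pooled_strain: list[float] = []
    pooled_dnar: list[float] = []
    n_excluded = 0
    for tid, obs in series.tracks.items():
        if len(obs) < 2:
            n_excluded += 1
            continue
        eps = np.array([o[0] for o in obs])
        vals = np.array([o[1] for o in obs])
        slopes[tid] = float(np.polyfit(eps, vals, 1)[0])
        base = vals[eps.argmin()]
        pooled_strain.extend(eps.tolist())
        pooled_dnar.extend((vals - base).tolist())
    if n_excluded:
        logger.info("nar_strain_response: excluded %d short tracks", n_excluded)
    pooled_strain_arr = np.array(pooled_strain)
    pooled_dnar_arr = np.array(pooled_dnar)
    if (
        len(pooled_strain_arr) < 2
        or np.ptp(pooled_dnar_arr) == 0
        or np.ptp(pooled_strain_arr) == 0
    ):
        return NarStrainResponse(slopes, 0.0, True, n_excluded)
    r = float(stats.pearsonr(pooled_strain_arr, pooled_dnar_arr)[0])
    return NarStrainResponse(slopes, r, False, n_excluded)
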