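"""Seeded synthetic fixtures with ground truth.

Generates DAPI-like nucleus fields with a tunable chromatin-condensation
knob, plane-strain deformed series of those fields, two-channel confocal
z-stacks with cells at known depths relative to a tissue interface,
shrinking scratch-wound time series, and differential-expression tables
with a known set of true effects.  Every generated object is recorded in a
:class:`GroundTruth` sidecar so downstream measurements can be validated
without any real microscopy or sequencing data.

All generators are driven by a single integer seed through
``numpy.random.default_rng`` and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "NucleusFieldSpec",
    "GroundTruth",
    "PlacementError",
    "gen_nucleus_field",
    "gen_strain_series",
    "gen_migration_stack",
    "gen_scratch_series",
    "gen_de_table",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap in the frame."""


@dataclass(frozen=True)
class NucleusFieldSpec:
    """Parameters of a synthetic DAPI nucleus field.

    ``condensation`` in [0, 1] scales the contrast of punctate
    heterochromatin foci rendered inside each nucleus: 0 gives a
    near-uniform interior, 1 gives high-contrast foci, and the expected
    within-mask intensity variance increases strictly with the knob.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 25
    radius_px: float = 20.0
    condensation: float = 1.0
    foci_per_nucleus: int = 12
    noise_sd: float = 0.0
    seed: int = 0
    # eccentricity range of the elliptical nuclei (axis ratio b/a)
    axis_ratio_range: tuple[float, float] = (0.8, 1.0)
    # fraction of each image border kept free of nucleus centres; widened
    # internally by the strain-series generator so stretched nuclei stay
    # inside the frame
    margin_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.n_nuclei > 0 and self.radius_px < 3:
            raise ValueError("radius_px must be >= 3")
        if not 0.0 <= self.condensation <= 1.0:
            raise ValueError("condensation must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Truth sidecar: one entry per rendered object.

    Only the fields relevant to the generating function are populated.
    ``label_map`` carries the per-nucleus masks losslessly (0 = background,
    k = nucleus k, matching 1-based positions in the vector fields).
    """

    label_map: np.ndarray | None = None
    centroids: list[tuple[float, float]] = field(default_factory=list)
    true_nar: list[float] = field(default_factory=list)
    orientations_rad: list[float] = field(default_factory=list)
    semi_axes_px: list[tuple[float, float]] = field(default_factory=list)
    true_depths_um: list[float] = field(default_factory=list)
    embedded: list[bool] = field(default_factory=list)
    cell_xyz_um: list[tuple[float, float, float]] = field(default_factory=list)
    interface_z_um: float | None = None
    true_scratch_area_px: list[float] = field(default_factory=list)
    true_de_genes: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def masks(self) -> list[np.ndarray]:
        """Per-object boolean masks recovered from the label map."""
        if self.label_map is None:
            return []
        n = int(self.label_map.max())
        return [self.label_map == k for k in range(1, n + 1)]

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("label_map")
        return json.dumps(d, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# nucleus fields


def _place_centres(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: float,
    margin_frac: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centres inside the frame."""
    h, w = shape
    mr = radius * 1.3 + 2  # keep whole ellipse inside
    r0, r1 = max(mr, margin_frac * h), h - max(mr, margin_frac * h)
    c0, c1 = max(mr, margin_frac * w), w - max(mr, margin_frac * w)
    if n > 0 and (r1 <= r0 or c1 <= c0):
        raise PlacementError("frame too small for the requested nuclei")
    centres: list[np.ndarray] = []
    min_sep = 2.0 * radius * 1.15 + 2
    attempts = 0
    while len(centres) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {n} non-overlapping nuclei after "
                f"{max_attempts} attempts"
            )
        cand = np.array([rng.uniform(r0, r1), rng.uniform(c0, c1)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centres):
            centres.append(cand)
    return np.array(centres).reshape(n, 2)


def _render_nucleus(
    image: np.ndarray,
    label_map: np.ndarray,
    label: int,
    centre: np.ndarray,
    a: float,
    b: float,
    theta: float,
    condensation: float,
    n_foci: int,
    rng: np.random.Generator,
) -> None:
    """Paint one elliptical nucleus with heterochromatin foci in place."""
    h, w = image.shape
    pad = int(np.ceil(max(a, b))) + 2
    r_lo = max(int(centre[0]) - pad, 0)
    r_hi = min(int(centre[0]) + pad + 1, h)
    c_lo = max(int(centre[1]) - pad, 0)
    c_hi = min(int(centre[1]) + pad + 1, w)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dr, dc = rr - centre[0], cc - centre[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0

    # nuclear background: uniform when fully decondensed, gaining a gentle
    # centre-to-rim falloff as chromatin condenses
    base = 0.55 * (1.0 - 0.25 * rho2 * condensation)
    intensity = np.where(inside, base, 0.0)

    # punctate heterochromatin foci; amplitude scales with condensation
    sigma = max(a, b) * 0.12
    amp = 0.4 * condensation
    if amp > 0 and n_foci > 0:
        for _ in range(n_foci):
            # uniform position within the ellipse (polar in unit disc)
            r_unit = np.sqrt(rng.uniform(0, 0.8))
            phi = rng.uniform(0, 2 * np.pi)
            fu = r_unit * a * np.cos(phi)
            fv = r_unit * b * np.sin(phi)
            fr = centre[0] + fu * ct - fv * st
            fc = centre[1] + fu * st + fv * ct
            blob = amp * np.exp(-((rr - fr) ** 2 + (cc - fc) ** 2) / (2 * sigma**2))
            intensity = intensity + np.where(inside, blob, 0.0)
    elif n_foci > 0:
        # burn the same number of random draws so the geometry of other
        # nuclei is identical across condensation settings at fixed seed
        rng.uniform(size=(n_foci, 2))

    image[r_lo:r_hi, c_lo:c_hi] = np.maximum(image[r_lo:r_hi, c_lo:c_hi], intensity)
    label_map[r_lo:r_hi, c_lo:c_hi][inside] = label


def gen_nucleus_field(spec: NucleusFieldSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a field of non-overlapping elliptical nuclei.

    Returns a float image in [0, ~1] and a :class:`GroundTruth` whose
    label map, centroids, orientations and true axis ratios describe every
    nucleus.  Deterministic for a fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    image = np.zeros((h, w), dtype=np.float64)
    label_map = np.zeros((h, w), dtype=np.int32)
    truth = GroundTruth(label_map=label_map)
    if spec.n_nuclei == 0:
        if spec.noise_sd > 0:
            image += rng.normal(0.0, spec.noise_sd, size=image.shape)
        return image, truth

    centres = _place_centres(
        rng, (h, w), spec.n_nuclei, spec.radius_px, spec.margin_frac
    )
    for k, centre in enumerate(centres, start=1):
        ratio = rng.uniform(*spec.axis_ratio_range)
        a = spec.radius_px / np.sqrt(ratio)  # keep area ~ pi r^2
        b = spec.radius_px * np.sqrt(ratio)
        theta = rng.uniform(0, np.pi)
        _render_nucleus(
            image, label_map, k, centre, a, b, theta,
            spec.condensation, spec.foci_per_nucleus, rng,
        )
        truth.centroids.append((float(centre[0]), float(centre[1])))
        truth.semi_axes_px.append((float(a), float(b)))
        truth.orientations_rad.append(float(theta))
        truth.true_nar.append(float(max(a, b) / min(a, b)))

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image, truth


# ---------------------------------------------------------------------------
# strain series


def _ellipse_nar_under_stretch(
    a: float, b: float, theta: float, s_axial: float, s_trans: float
) -> float:
    """Axis ratio of an ellipse after a diagonal stretch.

    Stretch is ``s_axial`` along columns and ``s_trans`` along rows.  The
    ellipse x^T A x = 1 maps to x'^T S^-1 A S^-1 x' = 1; semi-axes are the
    inverse square roots of the eigenvalues of the new form.
    """
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    A = R @ np.diag([1 / a**2, 1 / b**2]) @ R.T
    S_inv = np.diag([1 / s_trans, 1 / s_axial])  # (row, col) order
    A2 = S_inv @ A @ S_inv
    ev = np.linalg.eigvalsh(A2)
    axes = 1.0 / np.sqrt(ev)
    return float(max(axes) / min(axes))


def gen_strain_series(
    base_spec: NucleusFieldSpec,
    strains: Sequence[float],
    transverse_contraction: bool = True,
) -> tuple[list[np.ndarray], list[GroundTruth]]:
    """Deform a base nucleus field under plane strain.

    The frame at engineering strain ``eps`` is the base frame resampled
    under the affine map stretching columns by ``1 + eps`` about the image
    centre.  With ``transverse_contraction`` the rows contract by
    ``1 / (1 + eps)`` (area-preserving); otherwise rows are unchanged.

    Returns one image and one GroundTruth per strain level; truth carries
    transformed centroids and the analytic NAR of each nucleus, with the
    nucleus index serving as a persistent track id across frames.
    """
    strains = list(strains)
    if any(s < 0 for s in strains):
        raise ValueError("strains must be non-negative")
    if strains != sorted(strains):
        raise ValueError("strains must be sorted ascending")
    if not strains or strains[0] != 0:
        raise ValueError("first strain level must be 0")

    eps_max = strains[-1]
    # widen the placement margin so stretched nuclei stay inside the frame
    margin = max(base_spec.margin_frac, 0.5 * (1 - 1 / (1 + eps_max)) + 0.05)
    spec = NucleusFieldSpec(
        image_shape=base_spec.image_shape,
        n_nuclei=base_spec.n_nuclei,
        radius_px=base_spec.radius_px,
        condensation=base_spec.condensation,
        foci_per_nucleus=base_spec.foci_per_nucleus,
        noise_sd=base_spec.noise_sd,
        seed=base_spec.seed,
        axis_ratio_range=base_spec.axis_ratio_range,
        margin_frac=margin,
    )
    base_image, base_truth = gen_nucleus_field(spec)
    h, w = base_image.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])

    images: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    for eps in strains:
        s_axial = 1.0 + eps
        s_trans = 1.0 / s_axial if transverse_contraction else 1.0
        if eps == 0:
            images.append(base_image.copy())
            t = GroundTruth(
                label_map=base_truth.label_map.copy(),
                centroids=list(base_truth.centroids),
                true_nar=list(base_truth.true_nar),
                semi_axes_px=list(base_truth.semi_axes_px),
                orientations_rad=list(base_truth.orientations_rad),
            )
            truths.append(t)
            continue
        # affine_transform maps output coords through the matrix to input
        # coords, so we pass the inverse stretch
        inv = np.diag([1 / s_trans, 1 / s_axial])
        offset = centre - inv @ centre
        img = ndi.affine_transform(base_image, inv, offset=offset, order=1, mode="constant")
        lbl = ndi.affine_transform(
            base_truth.label_map, inv, offset=offset, order=0, mode="constant"
        )
        images.append(img)
        t = GroundTruth(label_map=lbl)
        for (r, c), (a, b), theta in zip(
            base_truth.centroids, base_truth.semi_axes_px, base_truth.orientations_rad
        ):
            t.centroids.append(
                (
                    float(centre[0] + s_trans * (r - centre[0])),
                    float(centre[1] + s_axial * (c - centre[1])),
                )
            )
            t.true_nar.append(_ellipse_nar_under_stretch(a, b, theta, s_axial, s_trans))
            t.semi_axes_px.append((a, b))
            t.orientations_rad.append(theta)
        truths.append(t)
    return images, truths


# ---------------------------------------------------------------------------
# migration z-stacks


def gen_migration_stack(
    n_cells: int,
    interface_z_um: float = 20.0,
    depth_distribution: tuple[str, float, float] = ("normal", 10.0, 6.0),
    z_step_um: float = 2.0,
    seed: int = 0,
    xy_shape: tuple[int, int] = (192, 192),
    px_size_um: float = 1.0,
    z_extent_um: float = 60.0,
    blob_radius_um: float = 5.0,
    n_embedded: int | None = None,
    margin_guard_um: float | None = None,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a two-channel confocal-like z-stack with cells at known depths.

    The tissue channel occupies ``z >= interface_z_um``; cells are 3D
    Gaussian blobs centred at depth ``d`` below the interface (positive =
    into tissue), sampled from ``depth_distribution`` — ``("normal", mu,
    sd)`` or ``("uniform", lo, hi)`` — truncated to the rendered z range.
    A cell is embedded iff its entire blob support (radius
    ``blob_radius_um``) lies within the tissue, i.e. depth >=
    blob_radius_um.  ``n_embedded`` forces exactly that many embedded
    cells.  Sampled depths are kept at least ``margin_guard_um`` (default
    one z-step) away from the embedding threshold, since at finite z
    resolution the flag is ill-defined for borderline cells.

    Returns ``(cell_channel, tissue_channel, truth)``; both channels are
    ``(nz, ny, nx)`` float arrays with plane i at ``z = i * z_step_um``.
    """
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if interface_z_um <= 0 or interface_z_um >= z_extent_um:
        raise ValueError("z range must span the interface")
    if n_embedded is not None and n_embedded > n_cells:
        raise ValueError("n_embedded cannot exceed n_cells")
    guard = z_step_um if margin_guard_um is None else margin_guard_um

    rng = np.random.default_rng(seed)
    nz = int(round(z_extent_um / z_step_um)) + 1
    ny, nx = xy_shape
    z_um = np.arange(nz) * z_step_um

    tissue = np.zeros((nz, ny, nx), dtype=np.float64)
    tissue[z_um >= interface_z_um] = 1.0

    max_depth = z_extent_um - interface_z_um - blob_radius_um
    min_depth = -interface_z_um + blob_radius_um

    def draw_depth(embedded: bool | None) -> float:
        name, p1, p2 = depth_distribution
        for _ in range(10000):
            if name == "normal":
                d = rng.normal(p1, p2)
            elif name == "uniform":
                d = rng.uniform(p1, p2)
            else:
                raise ValueError(f"unknown depth distribution {name!r}")
            if not (min_depth <= d <= max_depth):
                continue
            if abs(d - blob_radius_um) < guard:
                continue  # guard band around the embedding threshold
            if embedded is None or (d >= blob_radius_um) == embedded:
                return float(d)
        raise RuntimeError("could not sample a depth satisfying constraints")

    # non-overlapping xy placement so each blob is an isolated maximum
    min_sep_px = 2.5 * blob_radius_um / px_size_um
    pad = blob_radius_um / px_size_um + 2
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n_cells:
        attempts += 1
        if attempts > 50000:
            raise PlacementError("could not place cells without overlap")
        y = rng.uniform(pad, ny - 1 - pad)
        x = rng.uniform(pad, nx - 1 - pad)
        if all(np.hypot(y - py, x - px_) >= min_sep_px for py, px_ in positions):
            positions.append((y, x))

    want_embedded: list[bool | None]
    if n_embedded is None:
        want_embedded = [None] * n_cells
    else:
        want_embedded = [i < n_embedded for i in range(n_cells)]
        rng.shuffle(want_embedded)  # type: ignore[arg-type]

    sigma_um = blob_radius_um / 2.0
    cell = np.zeros((nz, ny, nx), dtype=np.float64)
    truth = GroundTruth(interface_z_um=float(interface_z_um))
    zz = z_um[:, None, None]
    yy = np.arange(ny)[None, :, None] * px_size_um
    xx = np.arange(nx)[None, None, :] * px_size_um
    for (y, x), emb in zip(positions, want_embedded):
        d = draw_depth(emb)
        cz = interface_z_um + d
        cy, cx = y * px_size_um, x * px_size_um
        blob = np.exp(
            -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_um**2)
        )
        cell += blob
        truth.cell_xyz_um.append((float(cx), float(cy), float(cz)))
        truth.true_depths_um.append(d)
        truth.embedded.append(bool(d >= blob_radius_um))

    if noise_sd > 0:
        cell += rng.normal(0, noise_sd, size=cell.shape)
        tissue += rng.normal(0, noise_sd, size=tissue.shape)
    truth.extra["z_step_um"] = z_step_um
    truth.extra["px_size_um"] = px_size_um
    truth.extra["blob_radius_um"] = blob_radius_um
    return cell, tissue, truth


# ---------------------------------------------------------------------------
# scratch-wound series


def gen_scratch_series(
    frame_shape: tuple[int, int] = (500, 512),
    initial_width_px: int = 100,
    closure_px_per_frame: float = 25.0,
    n_frames: int = 5,
    seed: int = 0,
    void_level: float = 0.05,
    noise_sd: float = 0.01,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Time series of a confluent monolayer with a linearly closing scratch.

    Cells are a high-variance speckle texture; the scratch is a central
    vertical low-intensity, low-variance band whose width shrinks by
    ``closure_px_per_frame`` each frame until zero.  True scratch area per
    frame (width x frame height, in px^2) is recorded in the truth.
    """
    h, w = frame_shape
    if initial_width_px >= w:
        raise ValueError("initial_width_px must be smaller than the frame width")
    rng = np.random.default_rng(seed)
    frames: list[np.ndarray] = []
    truth = GroundTruth()
    for i in range(n_frames):
        width = max(0.0, initial_width_px - i * closure_px_per_frame)
        texture = rng.uniform(0.3, 1.0, size=(h, w))
        frame = texture
        if width > 0:
            c0 = int(round((w - width) / 2))
            c1 = int(round((w + width) / 2))
            frame[:, c0:c1] = void_level
            width = c1 - c0  # realized integer width
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, size=frame.shape)
        frames.append(frame)
        truth.true_scratch_area_px.append(float(width * h))
    return frames, truth


# ---------------------------------------------------------------------------
# differential-expression tables


def gen_de_table(
    n_genes: int = 1000,
    frac_de: float = 0.1,
    effect_log2fc_range: tuple[float, float] = (1.5, 4.0),
    seed: int = 0,
):
    """Synthetic DE result table with a known set of true effects.

    True-effect genes get ``|log2fc|`` uniform in ``effect_log2fc_range``
    (which must exceed 1, the fold-change-of-2 cut) and adjusted p below
    0.05; null genes get small log2fc noise and adjusted p in [0.05, 1].
    Returns ``(DataFrame[gene_id, log2fc, padj], GroundTruth)`` where the
    truth lists the DE gene ids.
    """
    import pandas as pd

    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must lie in [0, 1]")
    if effect_log2fc_range[0] <= 1.0:
        raise ValueError("effect_log2fc_range must start above 1 (|FC| > 2)")
    rng = np.random.default_rng(seed)
    n_de = int(round(n_genes * frac_de))
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True

    log2fc = rng.normal(0.0, 0.25, size=n_genes)
    log2fc = np.clip(log2fc, -0.9, 0.9)
    padj = rng.uniform(0.05, 1.0, size=n_genes)
    mag = rng.uniform(*effect_log2fc_range, size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc[de_idx] = mag * sign
    padj[de_idx] = 10 ** rng.uniform(-8, np.log10(0.049), size=n_de)

    table = pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "padj": padj})
    truth = GroundTruth(true_de_genes=sorted(np.array(gene_ids)[is_de].tolist()))
    return table, truth
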