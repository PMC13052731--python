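"""Nascent-matrix area normalized to nucleus count.

Newly synthesized extracellular matrix (metabolically labeled and
click-stained) is quantified as thresholded foreground area in the matrix
channel divided by the number of nuclei in the paired nuclei channel,
giving px^2 of nascent matrix per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from . import segment

__all__ = ["MatrixResult", "matrix_area_per_nucleus"]


@dataclass
class MatrixResult:
    matrix_area_px2: float
    n_nuclei: int
    area_per_nucleus: float
    #: True when >20% of foreground sits at the saturation level — dense
    #: overlapping staining that cannot be interpreted reliably
    saturation_flag: bool = False


def matrix_area_per_nucleus(
    matrix_channel: np.ndarray,
    nuclei_channel: np.ndarray,
    min_area_px: int = 50,
    matrix_threshold: float | None = None,
    saturation_level: float | None = None,
) -> MatrixResult:
    """Thresholded nascent-matrix area per nucleus.

    The matrix channel is Otsu-thresholded (or cut at
    ``matrix_threshold``), speckles below ``min_area_px`` are removed, and
    the remaining foreground area is divided by the nucleus count from the
    nuclei channel.  A QC flag is raised when more than 20% of the
    foreground sits at ``saturation_level`` (default: the dtype maximum
    for integer images, the image maximum otherwise).
    """
    matrix_channel = np.asarray(matrix_channel)
    nuclei_channel = np.asarray(nuclei_channel)
    if matrix_channel.shape != nuclei_channel.shape:
        raise ValueError("matrix and nuclei channels must share a shape")

    n_nuclei = segment.count_cells(nuclei_channel, min_area_px=min_area_px)
    if n_nuclei == 0:
        raise ValueError("no nuclei detected; area per nucleus undefined")

    img = matrix_channel.astype(np.float64)
    if img.max() == img.min():
        area = 0.0
        sat = False
    else:
        thr = threshold_otsu(img) if matrix_threshold is None else matrix_threshold
        fg = img > thr
        lbl, _ = ndi.label(fg)
        sizes = np.bincount(lbl.ravel())
        keep = sizes >= min_area_px
        keep[0] = False
        fg = keep[lbl]
        area = float(fg.sum())
        if saturation_level is None:
            if np.issubdtype(matrix_channel.dtype, np.integer):
                saturation_level = float(np.iinfo(matrix_channel.dtype).max)
            else:
                saturation_level = float(img.max())
        sat = bool(
            area > 0
            and np.count_nonzero(img[fg] >= saturation_level) > 0.2 * area
        )
    return MatrixResult(
        matrix_area_px2=area,
        n_nuclei=n_nuclei,
        area_per_nucleus=area / n_nuclei,
        saturation_flag=sat,
    )
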