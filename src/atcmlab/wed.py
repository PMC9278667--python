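"""Water-equivalent diameter (WED) from HU slice images.

The WED of a cross-section is the diameter of the water cylinder with the
same x-ray attenuating area as the object:

    A_w = sum over object pixels of max(0, 1 + HU/1000) * pixel_area
    WED = 2 * sqrt(A_w / pi)

Object segmentation: pixels above an HU threshold (default -800 HU, i.e.
anything denser than air), reduced to the largest connected component, with
interior holes filled so that internal air cavities (lung-like holes, air
rods) stay inside the object mask and contribute their — floored-at-zero —
water-equivalent area, as the water-equivalent-area convention requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

DEFAULT_THRESHOLD_HU = -800.0


@dataclass(frozen=True)
class WEDProfile:
    """Water-equivalent diameter as a function of table position.

    ``z`` is stored strictly ascending (a strictly descending input is
    flipped together with ``wed``). ``source`` records whether the profile
    came from closed-form geometry or from measured images.
    """

    z: np.ndarray
    wed: np.ndarray
    source: str = "analytic"
    label: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        w = np.asarray(self.wed, dtype=float)
        if z.ndim != 1 or z.shape != w.shape or z.size == 0:
            raise ValueError("z and wed must be matching non-empty 1-D arrays")
        if not (np.isfinite(z).all() and np.isfinite(w).all()):
            raise ValueError("profile values must be finite")
        dz = np.diff(z)
        if z.size > 1 and np.all(dz < 0):
            z, w = z[::-1], w[::-1]
        elif z.size > 1 and not np.all(dz > 0):
            raise ValueError("table positions must be strictly monotone")
        if (w < 0).any():
            raise ValueError("WED values must be non-negative")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "wed", w)

    def __len__(self) -> int:
        return self.z.size

    def interp(self, z: np.ndarray | float) -> np.ndarray:
        """WED linearly interpolated at ``z``; air (0 mm) outside the range."""
        return np.interp(np.asarray(z, dtype=float), self.z, self.wed,
                         left=0.0, right=0.0)

    def support(self) -> tuple[float, float]:
        """(zmin, zmax) of positions with non-zero WED; profile range if none."""
        nz = np.nonzero(self.wed > 0)[0]
        if nz.size == 0:
            return float(self.z[0]), float(self.z[-1])
        return float(self.z[nz[0]]), float(self.z[nz[-1]])


def as_table_positions(profile: WEDProfile, table_offset: float | None = None
                       ) -> WEDProfile:
    """Map a phantom-frame profile (z=0 at the Head end) to table positions.

    The scanner table coordinate runs opposite to the phantom axis, with the
    Head end at positive values: t = table_offset - z. By default the offset
    centres the profile, t in [-span/2, +span/2].
    """
    if table_offset is None:
        table_offset = 0.5 * (profile.z[0] + profile.z[-1])
    return replace(profile, z=table_offset - profile.z[::-1],
                   wed=profile.wed[::-1])


def compute_wed(image: np.ndarray, pixel_size: float,
                threshold: float = DEFAULT_THRESHOLD_HU) -> float:
    """Water-equivalent diameter (mm) of one HU slice image.

    Returns 0 for an all-air image (empty object mask). Per-pixel
    water-equivalent contributions (1 + HU/1000) are floored at zero so
    sub--1000 HU artefacts cannot produce negative area.
    """
    img = np.asarray(image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("image must be finite")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    mask = img > threshold
    if not mask.any():
        return 0.0
    labels, nlab = ndi.label(mask)
    if nlab > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    mask = ndi.binary_fill_holes(mask)
    contrib = np.clip(1.0 + img[mask] / 1000.0, 0.0, None)
    a_w = float(contrib.sum()) * pixel_size ** 2
    return 2.0 * math.sqrt(a_w / math.pi)


def wed_series(slices, threshold: float = DEFAULT_THRESHOLD_HU) -> WEDProfile:
    """Per-slice WED of a reconstructed series, ordered by table position.

    ``slices`` is any sequence of records exposing ``table_position``,
    ``image`` and ``pixel_size`` attributes (e.g. :class:`~atcmlab.atcm_sim.
    SliceRecord`). Duplicate table positions are rejected.
    """
    slices = list(slices)
    if not slices:
        raise ValueError("need at least one slice")
    positions = np.array([s.table_position for s in slices], dtype=float)
    if np.unique(positions).size != positions.size:
        raise ValueError("duplicate table positions in series")
    order = np.argsort(positions)
    wed = np.array([compute_wed(slices[i].image, slices[i].pixel_size,
                                threshold) for i in order])
    if positions.size == 1:
        z = positions
    else:
        z = positions[order]
    return WEDProfile(z=z, wed=wed, source="image")
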