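"""Core domain types: image volumes, contours, structure sets, model bundles.

All geometry is expressed in physical millimetres.  A contour is a 3D boolean
voxel mask living on the grid of its CT image; the grid is described by a
positive voxel spacing ``(dx, dy, dz)`` and an origin giving the physical
position of the centre of voxel ``(0, 0, 0)``.  Axis convention: positive x
lateral, positive y vertical, positive z longitudinal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: canonical name of the reference organ used for relative centroids
REFERENCE_OAR = "brainstem"
#: reference used when the subject contour *is* the brainstem
SECONDARY_REFERENCE_OAR = "pituitary"

ERROR_CATEGORIES = ("boundary", "volume", "nonadjacent_slice", "position")
SEVERITIES = ("moderate", "major")


@dataclass
class ImageVolume:
    """A scalar 3D image (CT numbers in HU) with its grid geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ErrorMeta:
    """Provenance of an injected contouring error."""

    category: str
    severity: str
    detail: str = ""
    magnitude_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in ERROR_CATEGORIES:
            raise ValueError(f"unknown error category {self.category!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass
class Contour:
    """One organ's 3D binary mask plus metadata.

    ``truth_label`` is ``"acceptable"``, ``"erroneous"`` or ``None`` when the
    quality is unknown (the normal inference-time situation).
    """

    mask: np.ndarray
    oar_type: str
    set_id: str = ""
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    truth_label: Optional[str] = None
    error_meta: Optional[ErrorMeta] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def voxel_centers_mm(self) -> np.ndarray:
        """(n, 3) physical coordinates of the centres of occupied voxels."""
        idx = np.argwhere(self.mask)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise ValueError(f"contour {self.oar_type!r} is empty")
        idx = np.argwhere(self.mask).mean(axis=0)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def volume_cc(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "Contour") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def replaced(self, mask: np.ndarray, truth_label: Optional[str] = None,
                 error_meta: Optional[ErrorMeta] = None) -> "Contour":
        """A copy of this contour with a new mask (used by error injection)."""
        return Contour(
            mask=mask, oar_type=self.oar_type, set_id=self.set_id,
            spacing=self.spacing, origin=self.origin,
            truth_label=truth_label if truth_label is not None else self.truth_label,
            error_meta=error_meta,
        )


@dataclass
class StructureSet:
    """A patient's collection of contours, keyed by OAR type."""

    contours: dict[str, Contour] = field(default_factory=dict)
    image: Optional[ImageVolume] = None
    body: Optional[Contour] = None
    set_id: str = ""

    def add(self, contour: Contour) -> None:
        if contour.oar_type in self.contours:
            raise ValueError(f"duplicate contour for {contour.oar_type!r}")
        if self.image is not None and contour.mask.shape != self.image.shape:
            raise ValueError("contour mask shape does not match image shape")
        self.contours[contour.oar_type] = contour

    def __contains__(self, oar_type: str) -> bool:
        return oar_type in self.contours

    def __getitem__(self, oar_type: str) -> Contour:
        return self.contours[oar_type]

    def __iter__(self) -> Iterator[Contour]:
        return iter(self.contours.values())

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def oar_types(self) -> list[str]:
        return list(self.contours)

    def with_replaced(self, contour: Contour) -> "StructureSet":
        """Shallow copy of the set with one contour swapped out."""
        contours = dict(self.contours)
        contours[contour.oar_type] = contour
        return StructureSet(contours=contours, image=self.image,
                            body=self.body, set_id=self.set_id)


@dataclass
class CcrBound:
    """Acceptance interval for one pairwise relation feature.

    ``feature`` is ``"min_distance"`` (mm, gamma-distributed in training) or
    ``"fractional_overlap"`` (beta-distributed).  ``lower``/``upper`` are the
    final bounds after tolerance expansion and domain clipping.
    """

    selected_oar: str
    comparison_oar: str
    feature: str
    lower: float
    upper: float
    dist_params: Optional[tuple[float, float]] = None  # (k, theta) or (alpha, beta)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.feature not in ("min_distance", "fractional_overlap"):
            raise ValueError(f"unknown CCR feature {self.feature!r}")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class OarModelBundle:
    """All trained artifacts for one OAR type.

    Feature statistics (``feature_mean`` etc.) are on sign-standardised
    features: principal-component orientation features have been flipped
    toward the stored representative eigenvectors before fitting.
    """

    oar_type: str
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    feature_median: np.ndarray
    feature_mad: np.ndarray
    md_mean: np.ndarray
    md_cov: np.ndarray
    md_cov_inv: np.ndarray
    rep_pc1: np.ndarray
    rep_pc2: np.ndarray
    ae_weights: dict[str, np.ndarray]
    ccr_bounds: list[CcrBound] = field(default_factory=list)
    parts_threshold: int = 1
    parts_gamma: Optional[tuple[float, float]] = None
    tuned_thresholds: dict[str, float] = field(default_factory=dict)
    n_train: int = 0
    n_removed_mad: int = 0
    version: str = "1"

    def __post_init__(self) -> None:
        for name in ("feature_mean", "feature_std", "feature_median",
                     "feature_mad", "md_mean", "rep_pc1", "rep_pc2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.md_cov = np.asarray(self.md_cov, dtype=float)
        self.md_cov_inv = np.asarray(self.md_cov_inv, dtype=float)
        if np.any(self.feature_std < 0) or np.any(self.feature_mad < 0):
            raise ValueError("negative spread statistic")
        if self.parts_threshold < 1:
            raise ValueError("parts_threshold must be >= 1")
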