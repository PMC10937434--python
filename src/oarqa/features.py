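"""Geometric, shape, orientation and CT-number features of contour masks.

The 20 single-contour features (fixed order, see :data:`FEATURE_NAMES`):

* centroid x/y/z [mm], relative to the brainstem centroid (the pituitary is
  the reference when the subject contour is itself the brainstem);
* the x/y/z components of the first and second principal-component
  eigenvectors of the occupied voxel-centre coordinates (unitless);
* volume [cc];
* the ratios of the second and third covariance eigenvalues to the first;
* extent along x/y/z [mm] (span of occupied voxel centres);
* Wadell sphericity;
* CT minimum / maximum / mean / sample standard deviation [HU].

Pairwise (contour-to-contour relationship) features are the minimum surface
distance in mm and the directional fractional volume overlap.  All distances
use voxel-centre coordinates in physical mm, so anisotropic slice spacing is
handled correctly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .core import (Contour, ImageVolume, REFERENCE_OAR,
                   SECONDARY_REFERENCE_OAR, StructureSet)

FEATURE_NAMES: tuple[str, ...] = (
    "centroid_x", "centroid_y", "centroid_z",
    "pc1_x", "pc1_y", "pc1_z",
    "pc2_x", "pc2_y", "pc2_z",
    "volume_cc",
    "lambda2_ratio", "lambda3_ratio",
    "extent_x", "extent_y", "extent_z",
    "sphericity",
    "ct_min", "ct_max", "ct_mean", "ct_std",
)

#: feature columns that carry principal-component vector components; their
#: sign is standardised against per-OAR representative eigenvectors at
#: train/inference time rather than at extraction time.
PC1_COLUMNS = ("pc1_x", "pc1_y", "pc1_z")
PC2_COLUMNS = ("pc2_x", "pc2_y", "pc2_z")
CT_COLUMNS = ("ct_min", "ct_max", "ct_mean", "ct_std")

# 26-connectivity: any face/edge/corner neighbour joins a component
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class MissingReferenceError(RuntimeError):
    """Raised when the centroid reference contour is absent from a set."""


def reference_centroid(structure_set: StructureSet, oar_type: str) -> np.ndarray:
    """Centroid (mm) of the reference organ for ``oar_type``.

    The brainstem anchors every contour's relative centroid; the brainstem
    itself is anchored to the pituitary so that its own location remains
    informative.
    """
    ref = REFERENCE_OAR if oar_type != REFERENCE_OAR else SECONDARY_REFERENCE_OAR
    if ref not in structure_set:
        raise MissingReferenceError(
            f"reference contour {ref!r} missing from set {structure_set.set_id!r}")
    return structure_set[ref].centroid_mm()


def relative_centroid(contour: Contour, structure_set: StructureSet) -> np.ndarray:
    """Contour centroid minus the reference-organ centroid, in mm."""
    return contour.centroid_mm() - reference_centroid(structure_set, contour.oar_type)


def extents(contour: Contour) -> np.ndarray:
    """Per-axis span (max - min) of occupied voxel-centre coordinates, mm.

    A single-voxel contour has extent (0, 0, 0) by this voxel-centre
    convention.
    """
    if contour.is_empty:
        raise ValueError("empty contour")
    idx = np.argwhere(contour.mask)
    span = idx.max(axis=0) - idx.min(axis=0)
    return span * np.asarray(contour.spacing)


def pca_shape_orientation(contour: Contour) -> dict:
    """PCA of the occupied voxel-centre coordinates (mm).

    Returns unit eigenvectors ``pc1``/``pc2`` (arbitrary sign) and the
    eigenvalue ratios ``lambda2_ratio`` = lam2/lam1, ``lambda3_ratio`` =
    lam3/lam1 with eigenvalues sorted descending.  Rank-deficient point
    clouds yield zero ratios and a ``degenerate`` flag.
    """
    coords = contour.voxel_centers_mm()
    if coords.shape[0] < 3:
        raise ValueError("PCA needs at least 3 voxels")
    cov = np.cov(coords, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    lam1 = evals[0]
    degenerate = lam1 <= 0 or evals[2] <= 0
    if lam1 <= 0:
        ratios = (0.0, 0.0)
    else:
        ratios = (float(evals[1] / lam1), float(evals[2] / lam1))
    return {
        "pc1": evecs[:, 0], "pc2": evecs[:, 1],
        "lambda2_ratio": ratios[0], "lambda3_ratio": ratios[1],
        "degenerate": bool(degenerate),
    }


def representative_eigenvector(vectors: np.ndarray) -> np.ndarray:
    """The member of ``vectors`` most aligned with the rest of the set.

    Picks the vector maximising the summed absolute dot product with all
    other members; ties resolve to the lowest index.  Used to standardise
    the otherwise arbitrary sign of PCA eigenvectors across a training
    corpus.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] == 0:
        raise ValueError("empty eigenvector set")
    dots = np.abs(v @ v.T)
    np.fill_diagonal(dots, 0.0)
    scores = dots.sum(axis=1)
    return v[int(np.argmax(scores))].copy()


def orient_eigenvector(vec: np.ndarray, representative: np.ndarray) -> np.ndarray:
    """Flip ``vec`` so its dot product with the representative is >= 0."""
    vec = np.asarray(vec, dtype=float)
    return -vec if float(vec @ representative) < 0 else vec.copy()


def sphericity(contour: Contour) -> float:
    """Wadell sphericity pi^(1/3) (6V)^(2/3) / A of the mask.

    V is the voxel volume; A is the area of a marching-cubes iso-surface of
    the mask at physical spacing, after half-voxel Gaussian anti-aliasing
    of the binary mask (a raw binary iso-surface overstates the area of
    smooth organs by the staircase effect).  Slightly exceeding 1 is
    possible for small masks.  A single-voxel mask falls back to the
    voxel-box surface area.
    """
    if contour.is_empty:
        raise ValueError("empty contour")
    volume = contour.n_voxels * float(np.prod(contour.spacing))
    if contour.n_voxels == 1:
        dx, dy, dz = contour.spacing
        area = 2.0 * (dx * dy + dy * dz + dz * dx)
    else:
        padded = np.pad(contour.mask, 2).astype(np.float32)
        padded = ndimage.gaussian_filter(padded, 0.5)  # half-voxel AA
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=contour.spacing)
        area = measure.mesh_surface_area(verts, faces)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def ct_statistics(contour: Contour, image: ImageVolume) -> tuple[float, float, float, float]:
    """(min, max, mean, sample std) of HU values under the mask."""
    if image is None:
        raise ValueError("no image attached")
    if contour.mask.shape != image.shape:
        raise ValueError("mask and image grids differ")
    vals = image.voxels[contour.mask]
    if vals.size == 0:
        raise ValueError("empty contour")
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.min()), float(vals.max()), float(vals.mean()), std


def count_parts(contour: Contour) -> int:
    """Number of 26-connected components of the mask."""
    if contour.is_empty:
        raise ValueError("empty contour")
    _, n = ndimage.label(contour.mask, structure=_STRUCT_26)
    return int(n)


def min_surface_distance(a: Contour, b: Contour,
                         edt_b: np.ndarray | None = None) -> float:
    """Minimum distance in mm between the two masks' voxel centres.

    Zero when the masks intersect.  ``edt_b`` may supply a precomputed
    Euclidean distance transform of ``~b.mask`` (sampling = spacing) to
    amortise repeated comparisons against the same contour.
    """
    if a.is_empty or b.is_empty:
        raise ValueError("empty contour")
    if a.mask.shape != b.mask.shape:
        raise ValueError("contours are on different grids")
    if np.any(a.mask & b.mask):
        return 0.0
    if edt_b is None:
        edt_b = distance_map(b)
    return float(edt_b[a.mask].min())


def distance_map(contour: Contour) -> np.ndarray:
    """Distance (mm) from each voxel centre to the contour's nearest voxel."""
    return ndimage.distance_transform_edt(~contour.mask, sampling=contour.spacing)


def fractional_overlap(selected: Contour, comparison: Contour) -> float:
    """Fraction of the selected contour's volume inside the comparison.

    Directional: |selected AND comparison| / |selected|.
    """
    if selected.mask.shape != comparison.mask.shape:
        raise ValueError("contours are on different grids")
    n_sel = selected.n_voxels
    if n_sel == 0:
        raise ValueError("empty selected contour")
    return float(np.count_nonzero(selected.mask & comparison.mask) / n_sel)


def extract_features(structure_set: StructureSet) -> pd.DataFrame:
    """One row of the 20 single-contour features per contour in the set.

    Principal-component vectors are stored with their raw (arbitrary) sign;
    standardisation happens at model training/inference against the stored
    per-OAR representative eigenvectors.  Sets without a CT image get NaN CT
    features.  Per-contour failures are warned about and skipped.
    """
    rows = []
    for contour in structure_set:
        try:
            rows.append(_feature_row(contour, structure_set))
        except MissingReferenceError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"feature extraction failed for {contour.oar_type!r} in set "
                f"{structure_set.set_id!r}: {exc}")
    df = pd.DataFrame(rows, columns=["set_id", "oar_type", *FEATURE_NAMES])
    return df


def _feature_row(contour: Contour, structure_set: StructureSet) -> dict:
    if contour.is_empty:
        raise ValueError("empty contour")
    rel = relative_centroid(contour, structure_set)
    pca = pca_shape_orientation(contour)
    ext = extents(contour)
    row = {
        "set_id": contour.set_id or structure_set.set_id,
        "oar_type": contour.oar_type,
        "centroid_x": rel[0], "centroid_y": rel[1], "centroid_z": rel[2],
        "pc1_x": pca["pc1"][0], "pc1_y": pca["pc1"][1], "pc1_z": pca["pc1"][2],
        "pc2_x": pca["pc2"][0], "pc2_y": pca["pc2"][1], "pc2_z": pca["pc2"][2],
        "volume_cc": contour.volume_cc(),
        "lambda2_ratio": pca["lambda2_ratio"],
        "lambda3_ratio": pca["lambda3_ratio"],
        "extent_x": ext[0], "extent_y": ext[1], "extent_z": ext[2],
        "sphericity": sphericity(contour),
    }
    if structure_set.image is not None:
        ct = ct_statistics(contour, structure_set.image)
        row.update(ct_min=ct[0], ct_max=ct[1], ct_mean=ct[2], ct_std=ct[3])
    else:
        row.update(ct_min=np.nan, ct_max=np.nan, ct_mean=np.nan, ct_std=np.nan)
    return row


def pair_features(selected: Contour, comparison: Contour,
                  edt_comparison: np.ndarray | None = None) -> tuple[float, float]:
    """(min_distance mm, fractional_overlap) for a selected/comparison pair."""
    overlap = fractional_overlap(selected, comparison)
    dist = 0.0 if overlap > 0 else min_surface_distance(
        selected, comparison, edt_b=edt_comparison)
    return dist, overlap


def prune_correlated(feature_table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Greedily drop features until no pair correlates beyond ``threshold``.

    While any absolute Pearson correlation exceeds the threshold, the member
    of the worst-correlated pair with the larger mean absolute correlation
    to all other features is removed.  Constant columns (undefined
    correlation) are treated as uncorrelated.  Returns the retained feature
    names in original order.
    """
    numeric = feature_table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = numeric.corr().abs().fillna(0.0)
    names = list(corr.columns)
    while True:
        c = corr.loc[names, names].to_numpy(copy=True)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= threshold:
            break
        mean_i = c[i].sum() / (len(names) - 1)
        mean_j = c[j].sum() / (len(names) - 1)
        drop = names[i] if mean_i >= mean_j else names[j]
        names.remove(drop)
    return [n for n in corr.columns if n in names]
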