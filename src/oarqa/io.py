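"""Readers and writers: RT structure sets, label volumes, model bundles.

Structure sets can come from DICOM (an RT-Struct file plus its CT image
series) or from a co-registered 3D label volume (NIfTI or NRRD) with a
label map.  Polygon contours are rasterised to masks on the CT grid by the
voxel-centre-in-polygon rule.  Organ names are mapped to canonical OAR
types through a user-supplied alias table, since structure naming varies
between institutions.

Trained per-OAR model bundles persist as versioned JSON (arrays stored as
nested lists; Python's JSON float formatting round-trips doubles exactly).
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CcrBound, Contour, ImageVolume, OarModelBundle, StructureSet

BUNDLE_FORMAT_VERSION = "1"

_ARRAY_FIELDS = ("feature_mean", "feature_std", "feature_median",
                 "feature_mad", "md_mean", "md_cov", "md_cov_inv",
                 "rep_pc1", "rep_pc2")


# ---------------------------------------------------------------------------
# alias tables


def load_alias_table(path) -> dict[str, str]:
    """YAML mapping of institutional structure names to canonical OAR types.

    The file maps ``canonical: [alias, alias, ...]``; lookups are
    case-insensitive and whitespace-insensitive.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = {}
    for canonical, aliases in raw.items():
        table[_norm(canonical)] = canonical
        for alias in aliases or []:
            table[_norm(alias)] = canonical
    return table


def canonical_name(label: str, alias_table: dict[str, str] | None) -> str | None:
    """Canonical OAR type for a structure label, or None when unknown."""
    if alias_table is None:
        return label
    return alias_table.get(_norm(label))


def _norm(s: str) -> str:
    return "".join(str(s).lower().split())


# ---------------------------------------------------------------------------
# DICOM RT-Struct + CT series


def load_dicom_structure_set(rtstruct_path, ct_dir,
                             alias_table: dict[str, str] | None = None,
                             set_id: str = "") -> StructureSet:
    """Load a DICOM RT-Struct and its CT series into a StructureSet.

    Assumes an axial, axis-aligned CT series (identity row/column
    orientation), the overwhelmingly common case for planning CT; anything
    else is rejected.  ROIs whose names are absent from the alias table are
    skipped with a warning, as are ROIs without contour data.
    """
    import pydicom

    slices = []
    for p in sorted(Path(ct_dir).iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise FileNotFoundError(f"no CT slices found under {ct_dir}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = slices[0]
    iop = [round(float(v)) for v in first.ImageOrientationPatient]
    if iop != [1, 0, 0, 0, 1, 0]:
        raise ValueError("only axis-aligned axial CT series are supported")
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = [float(d.ImagePositionPatient[2]) for d in slices]
    dz = float(np.diff(zs).mean()) if len(zs) > 1 else float(
        getattr(first, "SliceThickness", 1.0))
    origin = (float(first.ImagePositionPatient[0]),
              float(first.ImagePositionPatient[1]), zs[0])
    # voxel array indexed (x, y, z); DICOM pixel arrays are (row=y, col=x)
    vol = np.stack([d.pixel_array.T.astype(np.float64)
                    * float(getattr(d, "RescaleSlope", 1.0))
                    + float(getattr(d, "RescaleIntercept", 0.0))
                    for d in slices], axis=-1)
    image = ImageVolume(voxels=vol, spacing=(dx, dy, dz), origin=origin)

    rt = pydicom.dcmread(rtstruct_path)
    roi_names = {int(r.ROINumber): str(r.ROIName)
                 for r in rt.StructureSetROISequence}
    sset = StructureSet(image=image, set_id=set_id)
    for roi in getattr(rt, "ROIContourSequence", []):
        name = roi_names.get(int(roi.ReferencedROINumber), "")
        oar_type = canonical_name(name, alias_table)
        if oar_type is None:
            warnings.warn(f"unknown structure label {name!r}; skipped")
            continue
        contours = getattr(roi, "ContourSequence", None)
        if not contours:
            warnings.warn(f"ROI {name!r} has no contour data; skipped")
            continue
        mask = _rasterize_roi(contours, image)
        if oar_type == "body":
            sset.body = Contour(mask=mask, oar_type="body", set_id=set_id,
                                spacing=image.spacing, origin=image.origin)
        else:
            sset.add(Contour(mask=mask, oar_type=oar_type, set_id=set_id,
                             spacing=image.spacing, origin=image.origin))
    return sset


def _rasterize_roi(contour_sequence, image: ImageVolume) -> np.ndarray:
    from matplotlib.path import Path as MplPath

    nx, ny, nz = image.shape
    dx, dy, dz = image.spacing
    ox, oy, oz = image.origin
    mask = np.zeros(image.shape, dtype=bool)
    xc = ox + np.arange(nx) * dx
    yc = oy + np.arange(ny) * dy
    grid = np.stack(np.meshgrid(xc, yc, indexing="ij"), axis=-1).reshape(-1, 2)
    for item in contour_sequence:
        pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
        if pts.shape[0] < 3:
            continue
        k = int(round((pts[0, 2] - oz) / dz))
        if not 0 <= k < nz:
            continue
        inside = MplPath(pts[:, :2]).contains_points(grid)
        # XOR supports holes and multiple rings on one slice
        mask[:, :, k] ^= inside.reshape(nx, ny)
    return mask


# ---------------------------------------------------------------------------
# label volumes


def load_label_structure_set(path, label_map: dict[int, str],
                             alias_table: dict[str, str] | None = None,
                             set_id: str = "",
                             image_path=None) -> StructureSet:
    """Load contours from an integer label volume (NIfTI or NRRD).

    ``label_map`` maps integer labels to structure names.  An optional
    co-registered scalar image may be attached.  Note that a single label
    volume cannot represent overlapping (nested) contours.
    """
    voxels, spacing, origin = _read_volume(path)
    labels = voxels.astype(int)
    image = None
    if image_path is not None:
        ivox, ispacing, iorigin = _read_volume(image_path)
        image = ImageVolume(voxels=ivox, spacing=ispacing, origin=iorigin)
    sset = StructureSet(image=image, set_id=set_id)
    for value, name in sorted(label_map.items()):
        oar_type = canonical_name(name, alias_table)
        if oar_type is None:
            warnings.warn(f"unknown structure label {name!r}; skipped")
            continue
        mask = labels == int(value)
        if not mask.any():
            warnings.warn(f"label {value} ({name!r}) has no voxels; skipped")
            continue
        contour = Contour(mask=mask, oar_type=oar_type, set_id=set_id,
                          spacing=spacing, origin=origin)
        if oar_type == "body":
            sset.body = contour
        else:
            sset.add(contour)
    return sset


def _read_volume(path):
    path = Path(path)
    if path.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        voxels = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    import nibabel as nib

    img = nib.load(str(path))
    voxels = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return voxels, zooms, origin


def save_label_volume(structure_set: StructureSet, path,
                      label_map: dict[str, int] | None = None) -> dict[str, int]:
    """Write a set's contours as a NIfTI label volume; returns the label map.

    Contours are painted in roster order, later contours overriding
    earlier ones where organs overlap.
    """
    import nibabel as nib

    contours = list(structure_set)
    if not contours:
        raise ValueError("structure set has no contours")
    if label_map is None:
        label_map = {c.oar_type: i + 1 for i, c in enumerate(contours)}
    first = contours[0]
    labels = np.zeros(first.mask.shape, dtype=np.int16)
    for c in contours:
        labels[c.mask] = label_map[c.oar_type]
    affine = np.diag([*first.spacing, 1.0])
    affine[:3, 3] = first.origin
    nib.save(nib.Nifti1Image(labels, affine), str(path))
    return label_map


def save_corpus(sets, out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write a corpus as NIfTI volumes + manifest CSV; returns manifest path.

    Each set produces a 4D mask stack ``<set_id>_masks.nii.gz`` (one binary
    channel per contour, so nested/overlapping organs survive the round
    trip, unlike a single label volume), a CT volume ``<set_id>_ct.nii.gz``
    when an image is attached, and rows in the manifest:
    ``set_id,oar_type,channel,truth_label,category,severity``.  The body
    contour, when present, is stored as channel ``-1`` appended last.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sset in sets:
        contours = list(sset)
        if not contours:
            raise ValueError(f"structure set {sset.set_id!r} has no contours")
        first = contours[0]
        affine = np.diag([*first.spacing, 1.0])
        affine[:3, 3] = first.origin
        stack = [c.mask for c in contours]
        if sset.body is not None:
            stack.append(sset.body.mask)
        arr = np.stack(stack, axis=-1).astype(np.uint8)
        nib.save(nib.Nifti1Image(arr, affine),
                 str(out_dir / f"{sset.set_id}_masks.nii.gz"))
        if sset.image is not None:
            nib.save(nib.Nifti1Image(
                sset.image.voxels.astype(np.float32), affine),
                str(out_dir / f"{sset.set_id}_ct.nii.gz"))
        for ch, c in enumerate(contours):
            meta = c.error_meta
            rows.append({
                "set_id": sset.set_id, "oar_type": c.oar_type, "channel": ch,
                "truth_label": c.truth_label or "",
                "category": meta.category if meta else "",
                "severity": meta.severity if meta else "",
            })
        if sset.body is not None:
            rows.append({"set_id": sset.set_id, "oar_type": "body",
                         "channel": -1, "truth_label": "", "category": "",
                         "severity": ""})
    manifest = out_dir / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def load_corpus(corpus_dir, manifest_name: str = "manifest.csv"):
    """Load a corpus written by :func:`save_corpus`."""
    import nibabel as nib

    corpus_dir = Path(corpus_dir)
    manifest = pd.read_csv(corpus_dir / manifest_name,
                           keep_default_na=False)
    from .core import ErrorMeta

    sets = []
    for set_id, group in manifest.groupby("set_id", sort=True):
        img = nib.load(str(corpus_dir / f"{set_id}_masks.nii.gz"))
        arr = np.asanyarray(img.dataobj).astype(bool)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        ct_path = corpus_dir / f"{set_id}_ct.nii.gz"
        image = None
        if ct_path.exists():
            cimg = nib.load(str(ct_path))
            image = ImageVolume(voxels=np.asanyarray(cimg.dataobj).astype(float),
                                spacing=spacing, origin=origin)
        sset = StructureSet(image=image, set_id=str(set_id))
        for _, row in group.iterrows():
            ch = int(row["channel"])
            mask = arr[..., ch] if ch >= 0 else arr[..., -1]
            meta = None
            if row["category"]:
                meta = ErrorMeta(category=row["category"],
                                 severity=row["severity"])
            contour = Contour(mask=mask, oar_type=str(row["oar_type"]),
                              set_id=str(set_id), spacing=spacing,
                              origin=origin,
                              truth_label=row["truth_label"] or None,
                              error_meta=meta)
            if row["oar_type"] == "body":
                sset.body = contour
            else:
                sset.add(contour)
        sets.append(sset)
    return sets


# ---------------------------------------------------------------------------
# model bundle persistence


def save_bundle(bundle: OarModelBundle, path) -> None:
    """Persist a per-OAR model bundle as versioned JSON (exact round trip)."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "oar_type": bundle.oar_type,
        "feature_names": list(bundle.feature_names),
        "parts_threshold": int(bundle.parts_threshold),
        "parts_gamma": list(bundle.parts_gamma) if bundle.parts_gamma else None,
        "tuned_thresholds": dict(bundle.tuned_thresholds),
        "n_train": int(bundle.n_train),
        "n_removed_mad": int(bundle.n_removed_mad),
        "ae_weights": {k: np.asarray(v).tolist()
                       for k, v in bundle.ae_weights.items()},
        "ccr_bounds": [
            {"selected_oar": b.selected_oar, "comparison_oar": b.comparison_oar,
             "feature": b.feature, "lower": b.lower, "upper": b.upper,
             "dist_params": list(b.dist_params) if b.dist_params else None,
             "degenerate": b.degenerate}
            for b in bundle.ccr_bounds
        ],
    }
    for name in _ARRAY_FIELDS:
        payload[name] = np.asarray(getattr(bundle, name)).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bundle(path) -> OarModelBundle:
    """Load a bundle written by :func:`save_bundle`."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"could not parse bundle file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"bundle format version {version!r} is not supported "
            f"(expected {BUNDLE_FORMAT_VERSION!r})")
    bounds = [
        CcrBound(selected_oar=b["selected_oar"],
                 comparison_oar=b["comparison_oar"], feature=b["feature"],
                 lower=b["lower"], upper=b["upper"],
                 dist_params=tuple(b["dist_params"]) if b["dist_params"] else None,
                 degenerate=b["degenerate"])
        for b in payload["ccr_bounds"]
    ]
    arrays = {name: np.asarray(payload[name], dtype=float)
              for name in _ARRAY_FIELDS}
    return OarModelBundle(
        oar_type=payload["oar_type"],
        feature_names=list(payload["feature_names"]),
        ae_weights={k: np.asarray(v, dtype=float)
                    for k, v in payload["ae_weights"].items()},
        ccr_bounds=bounds,
        parts_threshold=payload["parts_threshold"],
        parts_gamma=tuple(payload["parts_gamma"]) if payload["parts_gamma"] else None,
        tuned_thresholds=payload["tuned_thresholds"],
        n_train=payload["n_train"],
        n_removed_mad=payload["n_removed_mad"],
        version=version,
        **arrays,
    )


def save_feature_table(table: pd.DataFrame, path) -> None:
    """Feature CSV with header ``set_id,oar_type,<feature columns>``."""
    table.to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
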