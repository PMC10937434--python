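"""Synthetic head-and-neck phantom structure sets with injectable errors.

The generator emulates the topology of a clinical head-and-neck structure
set: a roster of organs of varied shape (ellipsoids, tubes, boxes, paired
lateral organs, a two-lobed thyroid) positioned relative to a brainstem
anchor.  Patient-to-patient variation combines global and per-organ scale
jitter, shared postural offsets per anatomical region (head pose, neck
flexion), per-organ translation jitter and oblique orientations.
Anatomical relations hold by construction: the spinal cord abuts (shares
voxels with) the brainstem, the brainstem is partially nested in the
brain, each lens is nested in its eye, the submandibular glands and the
oral cavity abut the mandible, and the thyroid abuts the larynx.  A
synthetic CT assigns each tissue class a per-patient mean HU plus Gaussian
noise, smoothed by a scanner-like point-spread function.

Four categories of contouring error can be injected at moderate or major
severity, mirroring failures seen with manual contouring and
autocontouring tools:

* **boundary** — dilation or erosion of the surface, either the whole
  surface (isotropic) or one side of a random plane (sectorized, like a
  small registration shift);
* **volume** — addition/removal of a convex blob, or truncation of
  terminal slices;
* **nonadjacent_slice** — a single-slice disconnected "ditzel" placed at
  least a configured gap away from the organ, or jagged per-slice shifts;
* **position** — translation of the whole mask by a large offset, or a
  swap with another organ's mask (label mix-up).

Default magnitudes: moderate = boundary 2 mm, volume 10-20%, ditzel with
>= 5 mm gap, translation 10-15 mm; major = boundary 4-6 mm, volume 30-50%,
multi-slice jag, translation 25-35 mm or label swap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Contour, ErrorMeta, ImageVolume, StructureSet

DEFAULT_SPACING = (1.27, 1.27, 2.0)
DEFAULT_SHAPE = (76, 76, 72)

#: clinical error-category mix used for validation/test corpora
#: (boundary : volume : nonadjacent_slice : position)
ERROR_CATEGORY_WEIGHTS = {
    "boundary": 74, "volume": 99, "nonadjacent_slice": 14, "position": 40,
}
#: major : moderate severity mix
SEVERITY_WEIGHTS = {"major": 111, "moderate": 116}


@dataclass
class OarSpec:
    """Geometry and tissue parameters of one roster organ.

    ``offset`` is the organ-centre offset in mm from the brainstem anchor
    (or, for attached organs, from the parent centre on non-contact axes).
    ``size``: ellipsoid radii / box half-sizes (3,), or (r, r, half_length)
    for a z-aligned tube; ``lobe_dx`` > 0 turns an ellipsoid into two
    lobes mirrored in x (thyroid-like, two 26-connected parts).

    ``attach`` names a parent organ whose realised geometry anchors this
    one, reproducing the consistent local relations of real anatomy:
    with ``nested`` the child sits fully inside the parent (lens in eye),
    otherwise the child abuts the parent along ``attach_axis`` with
    ``attach_overlap_mm`` of shared depth (cord under brainstem, glands
    against the mandible, thyroid under the larynx).
    """

    name: str
    shape: str  # 'ellipsoid' | 'tube' | 'box'
    offset: tuple[float, float, float]
    size: tuple[float, float, float]
    hu_mean: float
    hu_std: float
    hu_patient_sd: float = 4.0  # between-patient variation of the mean HU
    lobe_dx: float = 0.0
    attach: str | None = None
    attach_axis: int = 2
    attach_sign: int = -1
    attach_overlap_mm: float = 3.0
    nested: bool = False
    yaw_deg: float = 0.0    # base in-plane orientation (organs sit obliquely)
    pitch_deg: float = 0.0  # base tilt out of the axial plane
    rot_deg: float = 4.0    # per-set orientation jitter sd, both angles
    region: str = "mid"  # 'cranial' | 'mid' | 'neck': organs of a region
    #                      share a per-set postural offset (head pose, neck
    #                      flexion), so neighbours move together as in real
    #                      anatomy while absolute positions vary more


def default_roster() -> list[OarSpec]:
    """17 head-and-neck organs; paint order = list order (later wins on CT)."""
    r = [
        OarSpec("brain", "ellipsoid", (0, -2, 28), (33, 26, 22), 35, 6,
                yaw_deg=10.0, pitch_deg=5.0, region="cranial"),
        OarSpec("brainstem", "ellipsoid", (0, 0, 0), (7.5, 6.5, 18), 32, 5,
                yaw_deg=15.0, pitch_deg=8.0, region="cranial"),
        OarSpec("pituitary", "ellipsoid", (0, -14, 10), (4.4, 3.7, 3.0), 38, 6,
                yaw_deg=20.0, pitch_deg=6.0, region="cranial"),
        OarSpec("cord", "tube", (0, 0, 0), (5.9, 5.1, 18), 38, 5,
                yaw_deg=20.0, pitch_deg=6.0, attach="brainstem", attach_axis=2, attach_sign=-1,
                attach_overlap_mm=6.0, region="cranial"),
        OarSpec("eye_l", "ellipsoid", (15, -20, 26), (12.4, 10.8, 9.3), 25, 6,
                yaw_deg=25.0, pitch_deg=10.0, region="cranial"),
        OarSpec("eye_r", "ellipsoid", (-15, -20, 26), (12.4, 10.8, 9.3), 25, 6,
                yaw_deg=-25.0, pitch_deg=10.0, region="cranial"),
        OarSpec("lens_l", "ellipsoid", (0, 0, 0), (3.8, 3.3, 2.8), 90, 8,
                yaw_deg=15.0, pitch_deg=8.0, attach="eye_l", attach_axis=1, attach_sign=-1, nested=True,
                region="cranial"),
        OarSpec("lens_r", "ellipsoid", (0, 0, 0), (3.8, 3.3, 2.8), 90, 8,
                yaw_deg=-15.0, pitch_deg=8.0, attach="eye_r", attach_axis=1, attach_sign=-1, nested=True,
                region="cranial"),
        OarSpec("mandible", "box", (0, -22, -18), (22, 7, 10), 600, 180,
                yaw_deg=8.0, pitch_deg=4.0, hu_patient_sd=40.0),
        OarSpec("submandibular_l", "ellipsoid", (13, 3, 0), (8.4, 7.2, 6.2), 35, 7,
                yaw_deg=30.0, pitch_deg=12.0, attach="mandible", attach_axis=2, attach_sign=-1,
                attach_overlap_mm=3.0),
        OarSpec("submandibular_r", "ellipsoid", (-13, 3, 0), (8.4, 7.2, 6.2), 35, 7,
                yaw_deg=-30.0, pitch_deg=12.0, attach="mandible", attach_axis=2, attach_sign=-1,
                attach_overlap_mm=3.0),
        OarSpec("oral_cavity", "ellipsoid", (0, 2, 0), (14, 9.5, 8.2), -20, 60,
                yaw_deg=8.0, pitch_deg=5.0,
                hu_patient_sd=25.0,
                attach="mandible", attach_axis=2, attach_sign=1,
                attach_overlap_mm=6.0),
        OarSpec("parotid_l", "ellipsoid", (24, 0, -2), (9, 12, 14), 18, 8,
                yaw_deg=20.0, pitch_deg=10.0, hu_patient_sd=8.0),
        OarSpec("parotid_r", "ellipsoid", (-24, 0, -2), (9, 12, 14), 18, 8,
                yaw_deg=-20.0, pitch_deg=10.0, hu_patient_sd=8.0),
        OarSpec("larynx", "ellipsoid", (0, -10, -34), (10.2, 8.8, 12), 20, 25,
                yaw_deg=8.0, pitch_deg=5.0, hu_patient_sd=10.0,
                region="neck"),
        OarSpec("thyroid", "ellipsoid", (0, 2, 0), (6, 5, 9), 90, 15,
                yaw_deg=10.0, pitch_deg=5.0, lobe_dx=9.0, attach="larynx", attach_axis=2, attach_sign=-1,
                attach_overlap_mm=5.0, region="neck"),
        OarSpec("esophagus", "tube", (0, 14, -42), (4.9, 4.1, 12), 30, 10,
                yaw_deg=25.0, pitch_deg=6.0, region="neck"),
    ]
    return r


#: contour pairs with consistent anatomical relations, used as the default
#: CCR matrix of the phantom (selected, comparison)
DEFAULT_CCR_PAIRS = (
    # nested / abutting organ pairs
    ("brainstem", "brain"),
    ("cord", "brainstem"),
    ("pituitary", "brainstem"),
    ("lens_l", "eye_l"),
    ("lens_r", "eye_r"),
    ("submandibular_l", "mandible"),
    ("submandibular_r", "mandible"),
    ("oral_cavity", "mandible"),
    ("thyroid", "larynx"),
    # nearby organs with a consistent separation
    ("parotid_l", "mandible"),
    ("parotid_r", "mandible"),
    ("thyroid", "esophagus"),
    # containment in the external body contour (surface-near organs only)
    ("brain", "body"),
    ("eye_l", "body"),
    ("eye_r", "body"),
    ("parotid_l", "body"),
    ("parotid_r", "body"),
    ("submandibular_l", "body"),
    ("submandibular_r", "body"),
)


@dataclass
class PhantomConfig:
    """Grid, roster and variation parameters of the phantom population."""

    grid_shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    roster: list[OarSpec] = field(default_factory=default_roster)
    anchor_z_mm: float = 70.0
    global_scale_sd: float = 0.05
    organ_scale_sd: float = 0.04
    translation_sd_mm: float = 1.5
    region_sd_mm: float = 4.0
    anchor_sd_mm: float = 2.5
    body_radius_mm: float = 42.0
    body_hu: tuple[float, float] = (30.0, 15.0)
    air_hu: tuple[float, float] = (-1000.0, 10.0)

    def oar_names(self) -> list[str]:
        return [s.name for s in self.roster]


@dataclass
class ErrorSpec:
    """One injected-error request (category, severity, RNG seed, knobs)."""

    category: str
    severity: str
    seed: int = 0
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# structure-set generation


def _grid_axes(config: PhantomConfig):
    sp = np.asarray(config.spacing)
    return [np.arange(n) * sp[i] for i, n in enumerate(config.grid_shape)]


def _rasterize(spec: OarSpec, center: np.ndarray, scale: np.ndarray,
               yaw_rad: float, axes, pitch_rad: float = 0.0) -> np.ndarray:
    """Boolean mask of one organ on the grid (voxel-centre-in-shape)."""
    X = (axes[0] - center[0])[:, None, None]
    Y = (axes[1] - center[1])[None, :, None]
    Z = (axes[2] - center[2])[None, None, :]
    ca, sa = np.cos(yaw_rad), np.sin(yaw_rad)
    U = ca * X + sa * Y
    V0 = -sa * X + ca * Y
    cp, sp = np.cos(pitch_rad), np.sin(pitch_rad)
    V = cp * V0 + sp * Z
    Z = -sp * V0 + cp * Z
    a, b, c = np.asarray(spec.size) * scale
    if spec.shape == "ellipsoid":
        if spec.lobe_dx > 0:
            dx = spec.lobe_dx * scale[0]
            m = ((((U - dx) / a) ** 2 + (V / b) ** 2 + (Z / c) ** 2) <= 1.0)
            m |= ((((U + dx) / a) ** 2 + (V / b) ** 2 + (Z / c) ** 2) <= 1.0)
            return m
        return ((U / a) ** 2 + (V / b) ** 2 + (Z / c) ** 2) <= 1.0
    if spec.shape == "tube":
        return (((U / a) ** 2 + (V / b) ** 2) <= 1.0) & (np.abs(Z) <= c)
    if spec.shape == "box":
        return (np.abs(U) <= a) & (np.abs(V) <= b) & (np.abs(Z) <= c)
    raise ValueError(f"unknown shape {spec.shape!r}")


def generate_structure_set(config: PhantomConfig, seed: int,
                           set_id: str = "") -> StructureSet:
    """One synthetic structure set with CT image; deterministic given seed."""
    rng = np.random.default_rng(seed)
    axes = _grid_axes(config)
    sp = np.asarray(config.spacing)
    shape = tuple(config.grid_shape)
    extent = sp * (np.asarray(shape) - 1)
    center_xy = extent[:2] / 2.0

    anchor = np.array([center_xy[0], center_xy[1], config.anchor_z_mm])
    anchor = anchor + rng.normal(0.0, config.anchor_sd_mm, size=3)
    gs = float(np.clip(rng.normal(1.0, config.global_scale_sd), 0.85, 1.15))
    # postural offsets shared by each anatomical region: the cranial region
    # defines the reference frame (the brainstem anchors the centroid
    # features), so only mid-face and neck move relative to it
    region_offset = {
        "cranial": np.zeros(3),
        "mid": rng.normal(0.0, config.region_sd_mm, size=3),
        "neck": rng.normal(0.0, config.region_sd_mm, size=3),
    }

    realized: dict[str, dict] = {}
    masks: dict[str, np.ndarray] = {}
    for spec in config.roster:
        scale = gs * np.clip(rng.normal(1.0, config.organ_scale_sd, 3), 0.88, 1.12)
        jitter = rng.normal(0.0, config.translation_sd_mm, size=3)
        yaw = np.deg2rad(spec.yaw_deg + rng.normal(0.0, spec.rot_deg))
        pitch = np.deg2rad(spec.pitch_deg + rng.normal(0.0, spec.rot_deg))
        if spec.attach is None:
            center = (anchor + np.asarray(spec.offset) * gs + jitter
                      + region_offset[spec.region])
        else:
            parent = realized[spec.attach]
            ax, sign = spec.attach_axis, spec.attach_sign
            if spec.nested:
                scale = np.minimum(
                    scale, 0.4 * parent["size_mm"] / np.asarray(spec.size))
            c_half = spec.size[ax] * scale[ax]
            p_half = parent["size_mm"][ax]
            # non-contact axes: parent centre + offset + small local jitter
            center = (parent["center"] + np.asarray(spec.offset) * gs
                      + rng.normal(0.0, 1.0, size=3))
            if spec.nested:
                center[ax] = parent["center"][ax] + sign * (
                    p_half - c_half - 2.0)
            else:
                center[ax] = parent["center"][ax] + sign * (
                    p_half + c_half - spec.attach_overlap_mm)

        mask = _rasterize(spec, center, scale, yaw, axes, pitch)
        if _touches_edge(mask) or not mask.any():
            # clamped retry: drop the jitter that pushed the organ out
            warnings.warn(f"{spec.name} left the grid; regenerating with "
                          "clamped jitter")
            center = anchor + np.asarray(spec.offset) * gs if spec.attach is None else center
            mask = _rasterize(spec, center, scale,
                              np.deg2rad(spec.yaw_deg), axes,
                              np.deg2rad(spec.pitch_deg))
        realized[spec.name] = {"center": center,
                               "size_mm": np.asarray(spec.size) * scale}
        masks[spec.name] = mask

    body_r = config.body_radius_mm * gs
    body_mask = (((axes[0] - center_xy[0])[:, None, None]) ** 2
                 + ((axes[1] - center_xy[1])[None, :, None]) ** 2
                 <= body_r ** 2) & np.ones(shape, dtype=bool)

    ct = rng.normal(config.air_hu[0], config.air_hu[1], size=shape)
    body_mu = config.body_hu[0] + rng.normal(0.0, 4.0)
    ct[body_mask] = rng.normal(body_mu, config.body_hu[1],
                               size=int(body_mask.sum()))
    for spec in config.roster:  # paint order: later organs override
        m = masks[spec.name]
        # tissue composition varies between patients, so each organ draws a
        # per-set mean HU around its nominal value
        mu = spec.hu_mean + rng.normal(0.0, spec.hu_patient_sd)
        ct[m] = rng.normal(mu, spec.hu_std, size=int(m.sum()))
    ct = ndimage.gaussian_filter(ct, sigma=0.7)

    image = ImageVolume(voxels=ct, spacing=config.spacing)
    sset = StructureSet(image=image, set_id=set_id)
    sset.body = Contour(mask=body_mask, oar_type="body", set_id=set_id,
                        spacing=config.spacing)
    for spec in config.roster:
        sset.add(Contour(mask=masks[spec.name], oar_type=spec.name,
                         set_id=set_id, spacing=config.spacing,
                         truth_label="acceptable"))
    return sset


def generate_corpus(config: PhantomConfig, n_sets: int, seed: int,
                    id_prefix: str = "phantom") -> list[StructureSet]:
    """A population of independent phantom sets, seeded reproducibly."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_sets) % (2 ** 31)
    return [
        generate_structure_set(config, int(s), set_id=f"{id_prefix}_{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


def _touches_edge(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any()
                or mask[:, -1].any() or mask[:, :, 0].any()
                or mask[:, :, -1].any())


# ---------------------------------------------------------------------------
# error injection


def inject_error(contour: Contour, image: ImageVolume | None,
                 spec: ErrorSpec) -> Contour:
    """Apply one error category to a copy of ``contour``.

    Deterministic given ``spec.seed``.  The returned contour carries
    ``truth_label="erroneous"`` and an :class:`ErrorMeta` describing what
    was done.  Raises when the requested magnitude annihilates the mask
    (e.g. erosion of a small organ).
    """
    if contour.is_empty:
        raise ValueError("cannot inject an error into an empty contour")
    rng = np.random.default_rng(spec.seed)
    dispatch = {
        "boundary": _boundary_error,
        "volume": _volume_error,
        "nonadjacent_slice": _slice_error,
        "position": _position_error,
    }
    if spec.category not in dispatch:
        raise ValueError(f"unknown error category {spec.category!r}")
    mask, detail, magnitude = dispatch[spec.category](contour, spec, rng)
    if mask.sum() < 3:
        raise ValueError(f"{spec.category} error (almost) emptied the mask; "
                         "magnitude too large for this organ")
    if np.array_equal(mask, contour.mask):
        raise ValueError(f"{spec.category} error left the mask unchanged")
    meta = ErrorMeta(category=spec.category, severity=spec.severity,
                     detail=detail, magnitude_mm=magnitude)
    return contour.replaced(mask=mask, truth_label="erroneous", error_meta=meta)


def _boundary_error(contour, spec, rng):
    """Uniform or one-sided (sectorized) border expansion/subtraction.

    The sectorized variant perturbs only the boundary on one side of a
    random plane through the centroid, mimicking a small registration
    shift or locally poor delineation.
    """
    radius = (2.0 if spec.severity == "moderate"
              else float(rng.uniform(4.0, 6.0)))
    radius = float(spec.params.get("radius_mm", radius))
    grow = spec.params.get("direction",
                           "dilate" if rng.random() < 0.5 else "erode")
    sector = spec.params.get("mode",
                             "sector" if rng.random() < 0.5 else "isotropic")
    half = None
    if sector == "sector":
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        centroid = contour.centroid_mm()
        sp = np.asarray(contour.spacing)
        xs = (np.arange(contour.mask.shape[0]) * sp[0] - centroid[0])[:, None, None]
        ys = (np.arange(contour.mask.shape[1]) * sp[1] - centroid[1])[None, :, None]
        zs = (np.arange(contour.mask.shape[2]) * sp[2] - centroid[2])[None, None, :]
        half = xs * u[0] + ys * u[1] + zs * u[2] > 0
    if grow == "dilate":
        dist = ndimage.distance_transform_edt(~contour.mask,
                                              sampling=contour.spacing)
        shell = ~contour.mask & (dist <= radius)
        if half is not None:
            shell &= half
        mask = contour.mask | shell
    else:
        dist = ndimage.distance_transform_edt(contour.mask,
                                              sampling=contour.spacing)
        removed = contour.mask & ~(dist > radius)
        if half is not None:
            removed &= half
        mask = contour.mask & ~removed
        if not mask.any():
            raise ValueError("erosion magnitude too large for this organ")
    detail = f"{grow}_{sector}" if sector == "sector" else grow
    return mask, detail, radius


def _volume_error(contour, spec, rng):
    frac = (float(rng.uniform(0.10, 0.20)) if spec.severity == "moderate"
            else float(rng.uniform(0.30, 0.50)))
    frac = float(spec.params.get("fraction", frac))
    mode = spec.params.get("mode",
                           rng.choice(["blob_add", "blob_remove", "truncate"]))
    if mode == "truncate":
        return _truncate_slices(contour, frac, rng) + (frac,)
    # convex blob centred on a random surface voxel
    vol_mm3 = contour.n_voxels * np.prod(contour.spacing)
    r = (3.0 * frac * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    eroded = ndimage.binary_erosion(contour.mask)
    surface = np.argwhere(contour.mask & ~eroded)
    center_idx = surface[rng.integers(len(surface))]
    sphere = _sphere_mask(contour.mask.shape, contour.spacing,
                          center_idx * np.asarray(contour.spacing), r)
    if mode == "blob_add":
        return contour.mask | sphere, "blob_add", frac
    mask = contour.mask & ~sphere
    if not mask.any():
        raise ValueError("blob removal emptied the mask")
    return mask, "blob_remove", frac


def _truncate_slices(contour, frac, rng):
    zs = np.flatnonzero(contour.mask.any(axis=(0, 1)))
    counts = contour.mask.sum(axis=(0, 1))[zs]
    target = frac * counts.sum()
    from_top = bool(rng.random() < 0.5)
    order = zs[::-1] if from_top else zs
    removed, cut = 0, []
    for z in order:
        if removed >= target or len(cut) >= len(zs) - 1:
            break
        cut.append(z)
        removed += contour.mask[:, :, z].sum()
    if not cut:
        cut = [order[0]]
    mask = contour.mask.copy()
    mask[:, :, cut] = False
    return mask, "truncate"


def _slice_error(contour, spec, rng):
    if spec.severity == "moderate" or spec.params.get("mode") == "ditzel":
        gap = float(spec.params.get("gap_mm", 5.0))
        return _add_ditzel(contour, gap, rng)
    # major: jagged per-slice in-plane shifts
    mask = contour.mask.copy()
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    for z in zs[::2]:
        shift = rng.integers(-2, 3, size=2)
        if shift.any():
            mask[:, :, z] = np.roll(np.roll(mask[:, :, z], shift[0], axis=0),
                                    shift[1], axis=1)
    return mask, "jag", 2.0 * max(contour.spacing[:2])


def _add_ditzel(contour, gap_mm, rng):
    """Single-slice disconnected fragment >= gap_mm away from the organ."""
    rad = float(rng.uniform(2.0, 3.5))
    dist = ndimage.distance_transform_edt(~contour.mask,
                                          sampling=contour.spacing)
    allowed = dist >= (gap_mm + rad + max(contour.spacing))
    allowed[[0, -1], :, :] = False
    allowed[:, [0, -1], :] = False
    allowed[:, :, [0, -1]] = False
    # a misclick lands near the contour being edited: keep the fragment just
    # beyond the gap so it barely perturbs whole-contour features
    allowed &= dist <= gap_mm + rad + max(contour.spacing) + 8.0
    cand = np.argwhere(allowed)
    if len(cand) == 0:
        raise ValueError("no room for a ditzel at the requested gap")
    ci = cand[rng.integers(len(cand))]
    sp = np.asarray(contour.spacing)
    xs = (np.arange(contour.mask.shape[0]) - ci[0]) * sp[0]
    ys = (np.arange(contour.mask.shape[1]) - ci[1]) * sp[1]
    disk = (xs[:, None] ** 2 + ys[None, :] ** 2) <= rad ** 2
    mask = contour.mask.copy()
    mask[:, :, ci[2]] |= disk
    return mask, "ditzel", gap_mm


def _position_error(contour, spec, rng):
    if spec.params.get("mode") == "swap":
        other = spec.params["swap_with"]
        return other.mask.copy(), f"swap:{other.oar_type}", float("nan")
    lo, hi = (10.0, 15.0) if spec.severity == "moderate" else (25.0, 35.0)
    magnitude = float(spec.params.get("offset_mm", rng.uniform(lo, hi)))
    direction = spec.params.get("direction")
    for _ in range(20):
        if direction is None:
            d = rng.normal(size=3)
            d[2] *= 0.3  # mostly in-plane, like a laterality mix-up
            d /= np.linalg.norm(d)
        else:
            d = np.asarray(direction, dtype=float)
            d /= np.linalg.norm(d)
        shift_vox = np.round(magnitude * d / np.asarray(contour.spacing)).astype(int)
        mask = _shift_mask(contour.mask, shift_vox)
        if mask.sum() >= 0.5 * contour.n_voxels:
            return mask, "translate", magnitude
        direction = None  # clipped too much at the edge; redraw
    raise ValueError("could not place the translated mask inside the grid")


def _shift_mask(mask: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    src, dst = [], []
    for ax, s in enumerate(shift_vox):
        n = mask.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s)); dst.append(slice(s, n))
        else:
            src.append(slice(-s, n)); dst.append(slice(0, n + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _sphere_mask(shape, spacing, center_mm, radius_mm):
    sp = np.asarray(spacing)
    xs = (np.arange(shape[0]) * sp[0] - center_mm[0])[:, None, None]
    ys = (np.arange(shape[1]) * sp[1] - center_mm[1])[None, :, None]
    zs = (np.arange(shape[2]) * sp[2] - center_mm[2])[None, None, :]
    return xs ** 2 + ys ** 2 + zs ** 2 <= radius_mm ** 2


def plan_error_mix(n_errors: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """(category, severity) draws following the clinical error mix."""
    cats = list(ERROR_CATEGORY_WEIGHTS)
    cat_p = np.array([ERROR_CATEGORY_WEIGHTS[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    sevs = list(SEVERITY_WEIGHTS)
    sev_p = np.array([SEVERITY_WEIGHTS[s] for s in sevs], dtype=float)
    sev_p /= sev_p.sum()
    return [(cats[rng.choice(len(cats), p=cat_p)],
             sevs[rng.choice(len(sevs), p=sev_p)]) for _ in range(n_errors)]
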