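"""Synthetic abdominal-CT phantoms with exact ground truth.

Each phantom is a stack of axial slices containing the concentric anatomy
the segmentation networks must learn: air background outside an elliptical
body outline, a subcutaneous fat ring, a muscle wall, bone sites (spine and
ribs) and an interior cavity.  The top fraction of slices carries a
thoracic cavity with low-attenuation lung; the remaining slices carry an
abdominal cavity filled with soft-tissue "organs", bowel gas pockets and
visceral fat blobs.  Per-voxel HU values are sampled from configurable
tissue distributions and clipped to each tissue's legal HU range, so
HU-threshold tissue classification recovers the intended tissue
deterministically.

Ground truth is produced at generation time: a dense region label map, a
sparse copy in which only every fifth slice is annotated (the rest carry
the ignore label, mirroring an annotation-effort-saving protocol), and
exact per-slice voxel counts of subcutaneous fat, visceral fat and muscle
obtained by direct enumeration of the synthesized grid — the oracle that
the quantification module is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import (ABDOMINAL_CAVITY, BONES, HU_MAX, HU_MIN, IGNORE,
                        MUSCLE, SUBCUTANEOUS, THORACIC_CAVITY, CTVolume,
                        LabelMap)

__all__ = [
    "TissueDistribution", "PhantomConfig", "PhantomTruth",
    "generate_phantom", "generate_dataset", "sparsify_annotations",
    "annotated_slices",
]

# HU ranges the tissue classifier uses; phantom tissues are clipped into
# (or away from) these so truth-labelled voxels classify unambiguously.
ADIPOSE_RANGE = (-190, -30)
MUSCLE_RANGE = (-29, 150)


@dataclass(frozen=True)
class TissueDistribution:
    """Gaussian HU prior clipped to a legal range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


def _default_tissues() -> dict[str, TissueDistribution]:
    return {
        "air": TissueDistribution(-1010, 15, HU_MIN, -950),
        "subcutaneous_fat": TissueDistribution(-100, 20, *ADIPOSE_RANGE),
        "visceral_fat": TissueDistribution(-100, 20, *ADIPOSE_RANGE),
        "muscle": TissueDistribution(45, 15, *MUSCLE_RANGE),
        "bone": TissueDistribution(400, 150, 151, HU_MAX),
        "soft_tissue": TissueDistribution(40, 20, *MUSCLE_RANGE),
        "lung": TissueDistribution(-800, 50, HU_MIN, -191),
        "gas": TissueDistribution(-950, 40, HU_MIN, -300),
    }


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (20, 64, 64)   # (n_slices, H, W)
    spacing: tuple[float, float, float] = (5.0, 6.25, 6.25)  # mm, 400 mm FOV
    body_ry: float = 0.82        # body ellipse radii, fraction of half-extent
    body_rx: float = 0.88
    # ring thicknesses as fractions of the min body radius: ~3.5 cm of
    # subcutaneous fat and ~3 cm of muscle wall on a 40 cm field of view,
    # thick enough to be resolved after the 2x in-plane training downscale
    subcut_thickness: float = 0.22
    muscle_thickness: float = 0.20
    spine_radius: float = 0.14       # fraction of the in-plane extent
    rib_radius: float = 0.055
    # thin pre/retroperitoneal fat plane lining the inside of the muscle
    # wall (fraction of the min body radius) — the interface that makes the
    # wall's inner boundary visible in real CT, since muscle and visceral
    # soft tissue overlap in HU; its voxels count as visceral fat
    peritoneal_fat_thickness: float = 0.07
    # cohort variability: each phantom draws a global body scale and ring
    # thickness multipliers, emulating the large inter-patient spread of
    # habitus that real per-slice agreement statistics pool over
    body_scale_range: tuple[float, float] = (0.80, 1.08)
    ring_jitter_range: tuple[float, float] = (0.80, 1.25)
    # target fat fraction of the abdominal cavity; None draws per phantom
    visceral_fat_fraction: float | None = None
    visceral_fat_range: tuple[float, float] = (0.20, 0.50)
    # top fraction of slices carrying the thoracic cavity; 0.25 on a 20-slice
    # stack aligns the slab with the every-5th-slice annotation grid so the
    # thoracic class is represented in the sparse ground truth
    thoracic_slice_fraction: float = 0.25
    connective_speckle: float = 0.05  # soft-tissue fraction inside the fat ring
    intramuscular_fat: float = 0.03   # fat fraction inside the muscle wall
    # bowel-gas pockets in the abdominal cavity; off by default because at
    # this coarse grid air pockets are locally indistinguishable from lung,
    # which the sparse annotation cannot disambiguate by context
    bowel_gas_fraction: float = 0.0
    tissues: dict[str, TissueDistribution] = field(default_factory=_default_tissues)
    annotation_stride: int = 5
    seed: int = 0

    def __post_init__(self):
        nz, h, w = self.shape
        if nz < 1 or h < 8 or w < 8:
            raise ValueError(f"phantom grid {self.shape} too small")
        if not (0 < self.body_ry <= 1 and 0 < self.body_rx <= 1):
            raise ValueError("body radii are fractions in (0, 1] of the half-extent")
        if self.subcut_thickness + self.muscle_thickness >= 0.9:
            raise ValueError("tissue rings leave no room for the cavity")


@dataclass
class PhantomTruth:
    """Dense + sparse annotation and exact per-slice tissue voxel counts."""

    dense: LabelMap
    sparse: LabelMap
    counts: pd.DataFrame  # columns: slice, sat_voxels, vat_voxels, muscle_voxels


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _add_blobs(rng, mask_allowed, target_fraction, r_lo, r_hi, max_blobs=200):
    """Union of random ellipsoidal blobs inside ``mask_allowed`` (3D)."""
    nz, h, w = mask_allowed.shape
    allowed_idx = np.argwhere(mask_allowed)
    blobs = np.zeros_like(mask_allowed)
    if target_fraction <= 0 or len(allowed_idx) == 0:
        return blobs
    total = int(mask_allowed.sum())
    zz, yy, xx = np.mgrid[0:nz, 0:h, 0:w]
    for _ in range(max_blobs):
        cz, cy, cx = allowed_idx[rng.integers(len(allowed_idx))]
        rz = rng.uniform(1.0, 2.5)
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        ball = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                + ((xx - cx) / rx) ** 2) <= 1.0
        blobs |= ball & mask_allowed
        if blobs.sum() >= target_fraction * total:
            break
    return blobs


def generate_phantom(config: PhantomConfig | None = None,
                     seed: int | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Synthesize one phantom; bit-identical for identical seeds."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nz, h, w = config.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # per-phantom anatomy draws
    body_scale = rng.uniform(*config.body_scale_range)
    sub_jit = rng.uniform(*config.ring_jitter_range)
    mus_jit = rng.uniform(*config.ring_jitter_range)
    if config.visceral_fat_fraction is None:
        fat_fraction = rng.uniform(*config.visceral_fat_range)
    else:
        fat_fraction = config.visceral_fat_fraction
    # the annotation grid starts at an arbitrary slice, as it would when an
    # annotator labels every fifth slice of a scan of arbitrary extent
    ann_offset = int(rng.integers(config.annotation_stride))

    labels = np.zeros(config.shape, dtype=np.uint8)
    # per-voxel tissue identity for HU synthesis (labels alone are coarser:
    # e.g. the abdominal cavity region contains organs, gas and visceral fat)
    tissue = np.full(config.shape, "air", dtype=object)

    n_thoracic = int(round(config.thoracic_slice_fraction * nz))
    thoracic_slices = set(range(nz - n_thoracic, nz))  # cranial end at high z

    ry_max = config.body_ry * body_scale * (h - 1) / 2.0
    rx_max = config.body_rx * body_scale * (w - 1) / 2.0
    if ry_max >= h / 2.0 + 1 or rx_max >= w / 2.0 + 1:
        raise ValueError("body ellipse radii exceed the grid")

    cavity_mask = np.zeros(config.shape, dtype=bool)
    for z in range(nz):
        s = 0.85 + 0.15 * np.sin(np.pi * (z + 0.5) / nz)  # gentle axial taper
        ry, rx = ry_max * s, rx_max * s
        t_sub = config.subcut_thickness * sub_jit * min(ry, rx)
        t_mus = config.muscle_thickness * mus_jit * min(ry, rx)

        body = _ellipse_mask(h, w, cy, cx, ry, rx)
        sub_in = _ellipse_mask(h, w, cy, cx, ry - t_sub, rx - t_sub)
        mus_in = _ellipse_mask(h, w, cy, cx, ry - t_sub - t_mus, rx - t_sub - t_mus)

        sl = labels[z]
        ts = tissue[z]
        ring_sub = body & ~sub_in
        ring_mus = sub_in & ~mus_in
        sl[ring_sub] = SUBCUTANEOUS
        ts[ring_sub] = "subcutaneous_fat"
        sl[ring_mus] = MUSCLE
        ts[ring_mus] = "muscle"

        cavity_code = THORACIC_CAVITY if z in thoracic_slices else ABDOMINAL_CAVITY
        sl[mus_in] = cavity_code
        ts[mus_in] = "soft_tissue"
        if z not in thoracic_slices and config.peritoneal_fat_thickness > 0:
            t_fat = config.peritoneal_fat_thickness * min(ry, rx)
            fat_in = _ellipse_mask(h, w, cy, cx, ry - t_sub - t_mus - t_fat,
                                   rx - t_sub - t_mus - t_fat)
            ts[mus_in & ~fat_in] = "visceral_fat"
        if z in thoracic_slices:
            # two large lung fields fill most of the thoracic cavity, leaving
            # a narrow mediastinum — the low-attenuation cue that separates
            # this cavity from the abdominal one
            lr = 0.45 * min(ry, rx)
            for side in (-1, 1):
                lung = _ellipse_mask(h, w, cy - 0.05 * ry, cx + side * 0.40 * rx,
                                     1.6 * lr, lr) & mus_in
                ts[lung] = "lung"
        else:
            cavity_mask[z] = mus_in

        # spine: posterior bone ellipse, present on every slice
        sr = config.spine_radius * min(h, w) / 2.0
        spine = _ellipse_mask(h, w, cy + 0.62 * ry, cx, 1.2 * sr, sr) & body
        sl[spine] = BONES
        ts[spine] = "bone"
        # ribs: small lateral ossa inside the muscle wall
        rr = max(1.2, config.rib_radius * min(h, w))
        for side in (-1, 1):
            rib = _ellipse_mask(h, w, cy - 0.1 * ry, cx + side * (rx - t_sub - t_mus / 2),
                                rr, rr) & (ring_mus | ring_sub)
            sl[rib] = BONES
            ts[rib] = "bone"

    cavity_mask &= labels == ABDOMINAL_CAVITY

    # visceral fat blobs and organs inside the abdominal cavity
    r_unit = min(h, w) / 16.0
    fat = _add_blobs(rng, cavity_mask, fat_fraction,
                     0.8 * r_unit, 1.8 * r_unit)
    tissue[fat] = "visceral_fat"
    gas = _add_blobs(rng, cavity_mask & ~fat, config.bowel_gas_fraction,
                     0.4 * r_unit, 0.8 * r_unit)
    tissue[gas] = "gas"

    # speckle: connective tissue in the fat ring, fat streaks in the muscle
    speckle = (rng.random(config.shape) < config.connective_speckle)
    tissue[(labels == SUBCUTANEOUS) & speckle & (tissue == "subcutaneous_fat")] = "soft_tissue"
    imf = rng.random(config.shape) < config.intramuscular_fat
    tissue[(labels == MUSCLE) & imf] = "visceral_fat"

    hu = np.empty(config.shape, dtype=np.float64)
    for name, dist in config.tissues.items():
        m = tissue == name
        n = int(m.sum())
        if n:
            hu[m] = dist.sample(rng, n)

    ct = CTVolume(voxels=np.rint(hu), spacing=config.spacing)
    dense = LabelMap(labels=labels, spacing=config.spacing)
    sparse = sparsify_annotations(dense, config.annotation_stride, ann_offset)

    adip = (ct.voxels >= ADIPOSE_RANGE[0]) & (ct.voxels <= ADIPOSE_RANGE[1])
    musc = (ct.voxels >= MUSCLE_RANGE[0]) & (ct.voxels <= MUSCLE_RANGE[1])
    counts = pd.DataFrame({
        "slice": np.arange(nz),
        "sat_voxels": (adip & (labels == SUBCUTANEOUS)).sum(axis=(1, 2)),
        "vat_voxels": (adip & (labels == ABDOMINAL_CAVITY)).sum(axis=(1, 2)),
        "muscle_voxels": (musc & (labels == MUSCLE)).sum(axis=(1, 2)),
    })
    return ct, PhantomTruth(dense=dense, sparse=sparse, counts=counts)


def generate_dataset(n: int, config: PhantomConfig | None = None,
                     seed: int = 0) -> list[tuple[CTVolume, PhantomTruth]]:
    """Generate ``n`` phantoms with independent sub-seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate_phantom(config, seed=int(s)) for s in sub]


def sparsify_annotations(dense: LabelMap, stride: int = 5,
                         offset: int = 0) -> LabelMap:
    """Keep every ``stride``-th slice annotated; mark the rest as ignore."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    lab = dense.labels.copy()
    keep = np.arange(lab.shape[0]) % stride == offset % stride
    lab[~keep] = IGNORE
    return LabelMap(labels=lab, spacing=dense.spacing, affine=dense.affine)


def annotated_slices(sparse: LabelMap) -> np.ndarray:
    """Indices of slices that carry any annotation (not all-ignore)."""
    return np.flatnonzero((sparse.labels != IGNORE).any(axis=(1, 2)))
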