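"""Synthetic multimodal tumor phantoms and BraTS-style NIfTI slice loading.

The phantom generator emulates the statistical structure the framework
assumes: four co-registered MRI contrasts (T1, T1ce, T2, FLAIR) over a
nested lesion hierarchy — an edema ring around a tumor core that itself
contains an enhancing rim.  Modality contrast follows clinical roles: the
core is salient on T1/T1ce and edema on T2/FLAIR.  Labels use the BraTS
convention {0 background, 1 necrotic/non-enhancing core, 2 edema,
4 enhancing tumor}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MultimodalSample",
    "PhantomConfig",
    "DatasetSplit",
    "MODALITIES",
    "BRATS_LABELS",
    "generate_phantom",
    "generate_dataset",
    "load_brats_slice",
    "enhance_contrast_brightness",
    "split_cases",
    "save_phantom_nifti",
    "load_phantom_nifti",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
BRATS_LABELS = (0, 1, 2, 4)


@dataclass
class MultimodalSample:
    """One axial slice: four aligned modality images plus an integer label map."""

    t1: np.ndarray
    t1ce: np.ndarray
    t2: np.ndarray
    flair: np.ndarray
    label: np.ndarray
    case_id: str = "case"
    slice_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m: getattr(self, m).shape for m in MODALITIES}
        shapes["label"] = self.label.shape
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modality/label shapes disagree: {shapes}")
        bad = set(np.unique(self.label)) - set(BRATS_LABELS)
        if bad:
            raise ValueError(f"label values outside {{0,1,2,4}}: {sorted(bad)}")

    def modality(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise KeyError(f"unknown modality {name!r}")
        return getattr(self, name)

    def stacked(self) -> np.ndarray:
        """(4, H, W) array in the fixed modality order t1, t1ce, t2, flair."""
        return np.stack([getattr(self, m) for m in MODALITIES], axis=0)


@dataclass
class PhantomConfig:
    """Generator settings for one synthetic tumor phantom.

    All geometric quantities are in pixels.  A max tumor radius of 0
    produces a tumor-free slice (background tissue only).
    """

    image_size: int = 160
    tumor_radius_range: tuple[float, float] = (15.0, 37.0)
    edema_margin_range: tuple[float, float] = (7.5, 27.5)
    core_fraction_range: tuple[float, float] = (0.45, 0.7)
    enhancing_fraction_range: tuple[float, float] = (0.4, 0.65)
    noise_sigma: float = 0.10
    seed: int = 0

    @classmethod
    def desk(cls, image_size: int = 64, **overrides) -> "PhantomConfig":
        """Desk-scale profile: geometry scaled to a small image size."""
        s = image_size / 160.0
        cfg = cls(
            image_size=image_size,
            tumor_radius_range=(15.0 * s, 37.0 * s),
            edema_margin_range=(7.5 * s, 27.5 * s),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        for name in (
            "tumor_radius_range",
            "edema_margin_range",
            "core_fraction_range",
            "enhancing_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be an ordered nonnegative pair, got {(lo, hi)}")
        for name in ("core_fraction_range", "enhancing_fraction_range"):
            lo, hi = getattr(self, name)
            if hi > 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def validate(self, all_ids: list[str]) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        union = parts[0] | parts[1] | parts[2]
        if union != set(all_ids):
            raise ValueError("split union does not equal the full case list")
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("splits are not disjoint")


# ---------------------------------------------------------------------------
# phantom generation

# Mean tissue intensity per (modality, region).  Chosen once to mirror the
# clinical contrast roles: core/enhancing salient on T1/T1ce, edema salient
# on T2/FLAIR; edema is only faintly hypointense on T1/T1ce, so whole-tumor
# extent is genuinely hard from those modalities alone.
_CONTRAST = {
    #          background  edema  core   enhancing
    "t1":    (0.42, 0.40, 0.62, 0.68),
    "t1ce":  (0.40, 0.38, 0.58, 0.85),
    "t2":    (0.38, 0.75, 0.55, 0.52),
    "flair": (0.35, 0.80, 0.52, 0.50),
}


def _ellipse_mask(
    size: int, cy: float, cx: float, ry: float, rx: float, angle: float
) -> np.ndarray:
    if ry <= 0 or rx <= 0:
        return np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, rng_seed: int | None = None) -> MultimodalSample:
    """Generate one synthetic multimodal slice with nested tumor labels.

    Deterministic for a fixed seed.  Tumors are off-center ellipses with
    randomized eccentricity and orientation so lesions land in arbitrary
    quadrants of the image.
    """
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    n = config.image_size
    label = np.zeros((n, n), dtype=np.int64)

    # background brain: big smooth ellipse with mild texture
    brain = _ellipse_mask(n, n / 2, n / 2, 0.46 * n, 0.42 * n, rng.uniform(0, np.pi))
    texture = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=max(2.0, n / 40))
    texture /= max(np.abs(texture).max(), 1e-8)

    r_lo, r_hi = config.tumor_radius_range
    has_tumor = r_hi > 0
    wt = core = enh = np.zeros((n, n), dtype=bool)
    if has_tumor:
        radius = rng.uniform(r_lo, r_hi) if r_hi > r_lo else r_hi
        margin = rng.uniform(*config.edema_margin_range)
        ecc = rng.uniform(0.7, 1.0)
        angle = rng.uniform(0, np.pi)
        # keep the lesion inside the brain but off-center
        max_off = max(1.0, 0.42 * n - radius - margin - 2)
        off = rng.uniform(0, max_off)
        theta = rng.uniform(0, 2 * np.pi)
        cy = n / 2 + off * np.sin(theta)
        cx = n / 2 + off * np.cos(theta)

        core_r = radius * rng.uniform(*config.core_fraction_range)
        core = _ellipse_mask(n, cy, cx, core_r, core_r * ecc, angle)
        inner_r = core_r * rng.uniform(*config.enhancing_fraction_range)
        inner = _ellipse_mask(n, cy, cx, inner_r, inner_r * ecc, angle)
        enh = core & ~inner  # enhancing rim: outer shell of the core

        # Edema: an irregular, independently oriented lobulated region that
        # contains the core.  Its shape is NOT inferable from the core's:
        # its own eccentricity/orientation, an off-center core position and
        # a smoothed-noise boundary perturbation decouple the whole-tumor
        # margin from the core geometry.
        ed_ecc = rng.uniform(0.6, 1.0)
        ed_angle = rng.uniform(0, np.pi)
        ed_r = radius + margin
        ed_cy = cy + rng.uniform(-0.4, 0.4) * margin
        ed_cx = cx + rng.uniform(-0.4, 0.4) * margin
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        c, s = np.cos(ed_angle), np.sin(ed_angle)
        u = c * (xx - ed_cx) + s * (yy - ed_cy)
        v = -s * (xx - ed_cx) + c * (yy - ed_cy)
        dist = (u / (ed_r * ed_ecc)) ** 2 + (v / ed_r) ** 2
        bump = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=max(3.0, n / 16))
        bump /= max(np.abs(bump).max(), 1e-8)
        wt = (dist + 0.75 * bump) <= 1.0
        wt |= core  # nesting guarantee

        wt &= brain
        core &= brain
        enh &= brain
        core &= wt
        enh &= wt
        label[wt] = 2
        label[core] = 1
        label[enh] = 4

    edema = label == 2
    necro = label == 1
    images = {}
    for m in MODALITIES:
        bg, ed, co, en = _CONTRAST[m]
        img = np.zeros((n, n), dtype=np.float64)
        img[brain] = bg
        img += 0.04 * texture * brain
        img[edema] = ed
        img[necro] = co
        img[enh] = en
        img = gaussian_filter(img, sigma=0.7)  # soft tissue boundaries
        img += rng.normal(0.0, config.noise_sigma, (n, n))
        images[m] = np.clip(img, 0.0, 1.0).astype(np.float32)

    return MultimodalSample(
        t1=images["t1"],
        t1ce=images["t1ce"],
        t2=images["t2"],
        flair=images["flair"],
        label=label,
        case_id=f"phantom-{seed:05d}",
        slice_index=0,
        meta={"seed": int(seed), "image_size": n},
    )


def generate_dataset(
    n_cases: int, config: PhantomConfig, base_seed: int = 0
) -> list[MultimodalSample]:
    """Generate `n_cases` phantoms with per-case seeds base_seed + i."""
    return [generate_phantom(config, rng_seed=base_seed + i) for i in range(n_cases)]


# ---------------------------------------------------------------------------
# BraTS-style NIfTI I/O


def _minmax_normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def _center_crop(img: np.ndarray, size: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    if h < size or w < size:
        raise ValueError(f"slice {img.shape} smaller than crop size {size}")
    y0 = (h - size) // 2
    x0 = (w - size) // 2
    return img[y0 : y0 + size, x0 : x0 + size], (y0, x0)


def load_brats_slice(
    volume_paths: dict[str, str | Path],
    label_path: str | Path,
    slice_index: int,
    crop_size: int = 160,
    gain: float = 1.0,
    bias: float = 0.0,
) -> MultimodalSample:
    """Extract one axial slice from co-registered NIfTI volumes.

    The slice is center-cropped to ``crop_size`` and each modality is
    min-max normalized to [0, 1] (a constant-valued slice normalizes to
    zeros); the label map passes through unchanged.  The crop origin is
    recorded in ``sample.meta['crop_origin']``.
    """
    missing = set(MODALITIES) - set(volume_paths)
    if missing:
        raise ValueError(f"missing modality paths: {sorted(missing)}")
    vols = {m: np.asanyarray(nib.load(str(volume_paths[m])).dataobj) for m in MODALITIES}
    lab_vol = np.asanyarray(nib.load(str(label_path)).dataobj)
    shapes = {m: v.shape for m, v in vols.items()}
    shapes["label"] = lab_vol.shape
    if len(set(shapes.values())) != 1:
        raise ValueError(f"volume shapes disagree: {shapes}")
    depth = lab_vol.shape[2]
    if not 0 <= slice_index < depth:
        raise IndexError(f"slice_index {slice_index} out of range [0, {depth})")

    images = {}
    origin = None
    for m in MODALITIES:
        sl = np.asarray(vols[m][:, :, slice_index], dtype=np.float64)
        sl, origin = _center_crop(sl, crop_size)
        sl = _minmax_normalize(sl)
        images[m] = enhance_contrast_brightness(sl, gain=gain, bias=bias)
    lab, _ = _center_crop(np.asarray(lab_vol[:, :, slice_index]), crop_size)
    return MultimodalSample(
        t1=images["t1"],
        t1ce=images["t1ce"],
        t2=images["t2"],
        flair=images["flair"],
        label=lab.astype(np.int64),
        case_id=Path(str(label_path)).stem.replace(".nii", ""),
        slice_index=slice_index,
        meta={"crop_origin": origin},
    )


def enhance_contrast_brightness(
    image: np.ndarray, gain: float = 1.0, bias: float = 0.0
) -> np.ndarray:
    """Linear contrast/brightness adjustment: clip(gain*image + bias, 0, 1).

    Defaults are the identity; the adjustment is optional preprocessing.
    """
    return np.clip(gain * image + bias, 0.0, 1.0).astype(np.float32)


def split_cases(
    case_ids: list[str],
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> DatasetSplit:
    """Deterministic shuffled train/val/test partition (default 80/10/10)."""
    if len(case_ids) < 10:
        raise ValueError(f"need at least 10 cases to split, got {len(case_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - n_val - 1)
    split = DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        fractions=fractions,
    )
    split.validate(ids)
    return split


def save_phantom_nifti(sample: MultimodalSample, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom as per-modality NIfTI files plus a JSON manifest."""
    out = Path(out_dir) / sample.case_id
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    affine = np.eye(4)
    for m in MODALITIES:
        p = out / f"{sample.case_id}_{m}.nii.gz"
        nib.save(nib.Nifti1Image(sample.modality(m)[:, :, None].astype(np.float32), affine), str(p))
        paths[m] = p
    p = out / f"{sample.case_id}_seg.nii.gz"
    nib.save(nib.Nifti1Image(sample.label[:, :, None].astype(np.int16), affine), str(p))
    paths["label"] = p
    manifest = {
        "case_id": sample.case_id,
        "slice_index": sample.slice_index,
        "meta": {k: v for k, v in sample.meta.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def load_phantom_nifti(case_dir: str | Path) -> MultimodalSample:
    case_dir = Path(case_dir)
    case_id = case_dir.name
    arrays = {}
    for m in MODALITIES:
        arrays[m] = np.asanyarray(
            nib.load(str(case_dir / f"{case_id}_{m}.nii.gz")).dataobj
        )[:, :, 0].astype(np.float32)
    label = np.asanyarray(nib.load(str(case_dir / f"{case_id}_seg.nii.gz")).dataobj)[
        :, :, 0
    ].astype(np.int64)
    manifest_path = case_dir / "manifest.json"
    meta = {}
    slice_index = 0
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        meta = manifest.get("meta", {})
        slice_index = manifest.get("slice_index", 0)
    return MultimodalSample(
        t1=arrays["t1"],
        t1ce=arrays["t1ce"],
        t2=arrays["t2"],
        flair=arrays["flair"],
        label=label,
        case_id=case_id,
        slice_index=slice_index,
        meta=meta,
    )
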