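"""Conditioned slice-pair preparation and six-fold augmentation.

Registered volume pairs are turned into the model's training unit: a
224 x 224 preoperative/postoperative image pair with a one-hot condition
label encoding the slice's distance band from the fovea.  The steps are

1. per B-scan, locate the intensity centre of mass (COM) of the
   preoperative slice;
2. crop a 448-pixel square centred on the COM (zero-padded at borders) and
   downscale by half with Lanczos windowed-sinc interpolation — at native
   6 mm / 512-column sampling the crop spans exactly 5250.0 um laterally and
   1164.8 um axially;
3. keep the 200 slices centred on the fovea;
4. augment each training pair six-fold: original, horizontal flip,
   counterclockwise rotations of 4 and 8 degrees about the COM, and lateral
   shifts of 15 pixels towards the temporal and nasal sides — the identical
   geometric operation is applied to both members of a pair, and the
   postoperative member reuses the preoperative COM;
5. label each slice with a condition in {0,1,2,3} by distance band from the
   fovea (per-case band sizes 43/42/43/72) and attach inverse-frequency
   sampling weights so a weighted sampler draws conditions uniformly.

Validation and test slices are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .volume_io import (
    AUGMENTATION_TAGS,
    MANIFEST_COLUMNS,
    OCTVolume,
)

__all__ = [
    "SliceImage",
    "SlicePair",
    "center_of_mass",
    "crop_resize",
    "augment_pair",
    "select_slices",
    "assign_condition",
    "condition_lookup",
    "condition_histogram",
    "sampling_weights",
    "build_dataset",
    "CONDITION_BAND_EDGES",
    "SLICE_WINDOW",
]

#: number of fovea-centred slices retained per case
SLICE_WINDOW = 200

#: condition bands as inclusive window-position ranges over the 200-slice
#: window (position 100 = foveal slice).  Band sizes are 43/42/43/72 for
#: conditions 0/1/2/3; odd sizes force a one-slice asymmetry, placed on the
#: high-index side.
CONDITION_BAND_EDGES = {
    0: ((78, 120),),
    1: ((57, 77), (121, 141)),
    2: ((36, 56), (142, 163)),
    3: ((0, 35), (164, 199)),
}

#: augmentation geometry: CCW rotation degrees and lateral shift in pixels
ROTATION_DEGREES = (4.0, 8.0)
SHIFT_PX = 15


@dataclass
class SliceImage:
    """A 224 x 224 (or configured size) image with intensities in [0, 1]."""

    pixels: np.ndarray
    case_id: str = ""
    slice_index: int = -1
    augmentation_tag: str = "orig"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"slice image must be square 2-D, got {self.pixels.shape}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("slice intensities must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SlicePair:
    """A conditioned pre/post training pair."""

    pre: SliceImage
    post: SliceImage
    condition: int

    def __post_init__(self) -> None:
        if not 0 <= self.condition <= 3:
            raise ValueError("condition must be in {0,1,2,3}")
        if self.pre.size != self.post.size:
            raise ValueError("pair members must share a size")

    @property
    def one_hot(self) -> np.ndarray:
        v = np.zeros(4)
        v[self.condition] = 1.0
        return v


def center_of_mass(image: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean (row, col) of a 2-D image, fractional pixels."""
    image = np.asarray(image, dtype=float)
    total = image.sum()
    if total <= 0:
        raise ValueError("cannot take the centre of mass of an all-zero image")
    rows = np.arange(image.shape[0])
    cols = np.arange(image.shape[1])
    r = float((image.sum(axis=1) * rows).sum() / total)
    c = float((image.sum(axis=0) * cols).sum() / total)
    return r, c


def crop_resize(
    slice_2d: np.ndarray,
    com: tuple[float, float],
    crop_size: int = 448,
    out_size: int = 224,
) -> np.ndarray:
    """COM-centred square crop, Lanczos-downscaled, normalised to [0, 1].

    The crop window is centred on the rounded COM and zero-padded where it
    exceeds the slice bounds; downscaling uses 4-lobed windowed-sinc
    (Lanczos) interpolation.  Returns an ``out_size`` square float array.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float32)
    r0 = int(round(com[0])) - crop_size // 2
    c0 = int(round(com[1])) - crop_size // 2
    crop = np.zeros((crop_size, crop_size), dtype=np.float32)
    rs, re = max(r0, 0), min(r0 + crop_size, slice_2d.shape[0])
    cs, ce = max(c0, 0), min(c0 + crop_size, slice_2d.shape[1])
    if rs < re and cs < ce:
        crop[rs - r0 : re - r0, cs - c0 : ce - c0] = slice_2d[rs:re, cs:ce]
    img = Image.fromarray(crop, mode="F").resize(
        (out_size, out_size), resample=Image.Resampling.LANCZOS
    )
    out = np.asarray(img, dtype=np.float64) / 255.0
    return np.clip(out, 0.0, 1.0)


def _transform(pixels: np.ndarray, tag: str) -> np.ndarray:
    """Apply one augmentation to a [0,1] image (bilinear, zero fill).

    Rotations pivot about the image centre — the crop is COM-centred, so the
    centre *is* the COM.  Shifts move the image content towards the temporal
    (negative column) or nasal (positive column) side.
    """
    if tag == "orig":
        return pixels
    if tag == "flip":
        return pixels[:, ::-1].copy()
    if tag in ("rot4", "rot8"):
        deg = ROTATION_DEGREES[0] if tag == "rot4" else ROTATION_DEGREES[1]
        out = ndimage.rotate(
            pixels, deg, reshape=False, order=1, mode="constant", cval=0.0
        )
        return np.clip(out, 0.0, 1.0)
    if tag in ("shift_t", "shift_n"):
        px = -SHIFT_PX if tag == "shift_t" else SHIFT_PX
        out = ndimage.shift(pixels, (0, px), order=1, mode="constant", cval=0.0)
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown augmentation tag {tag!r}")


def augment_pair(pre: SliceImage, post: SliceImage, condition: int) -> list[SlicePair]:
    """Expand one pair into the six augmented pairs (original included).

    The identical geometric operation is applied to both members, so the
    spatial correspondence between the preoperative input and its
    postoperative target is preserved.
    """
    pairs = []
    for tag in AUGMENTATION_TAGS:
        pairs.append(
            SlicePair(
                pre=SliceImage(
                    _transform(pre.pixels, tag), pre.case_id, pre.slice_index, tag
                ),
                post=SliceImage(
                    _transform(post.pixels, tag), post.case_id, post.slice_index, tag
                ),
                condition=condition,
            )
        )
    return pairs


def select_slices(
    n_slices: int | OCTVolume,
    fovea_slice: int,
    window: int = SLICE_WINDOW,
) -> np.ndarray:
    """Indices of the ``window`` contiguous slices centred on the fovea.

    The window is ``[fovea - window//2, fovea + window//2 - 1]``, shifted to
    stay inside the volume when the fovea sits near an edge; always exactly
    ``window`` indices.
    """
    if isinstance(n_slices, OCTVolume):
        n_slices = n_slices.n_slices
    if n_slices < window:
        raise ValueError(f"volume has {n_slices} slices; need at least {window}")
    start = int(np.clip(fovea_slice - window // 2, 0, n_slices - window))
    return np.arange(start, start + window)


def condition_lookup(window: int = SLICE_WINDOW) -> np.ndarray:
    """Condition label for every window position.

    For the canonical 200-slice window this is the documented 43/42/43/72
    banding; smaller windows scale the band edges proportionally.
    """
    canon = np.empty(SLICE_WINDOW, dtype=int)
    for cond, ranges in CONDITION_BAND_EDGES.items():
        for lo, hi in ranges:
            canon[lo : hi + 1] = cond
    if window == SLICE_WINDOW:
        return canon
    pos = (np.arange(window) * SLICE_WINDOW) // window
    return canon[pos]


def assign_condition(slice_offset_from_fovea: int, window: int = SLICE_WINDOW) -> int:
    """Condition of a slice given its signed offset from the foveal slice."""
    pos = slice_offset_from_fovea + window // 2
    if not 0 <= pos < window:
        raise ValueError(
            f"offset {slice_offset_from_fovea} outside the {window}-slice window"
        )
    return int(condition_lookup(window)[pos])


def condition_histogram(window: int = SLICE_WINDOW) -> dict[int, int]:
    """Per-case condition counts over the fovea-centred window."""
    lut = condition_lookup(window)
    return {c: int((lut == c).sum()) for c in range(4)}


def sampling_weights(manifest: pd.DataFrame) -> np.ndarray:
    """Inverse-condition-frequency weight per manifest row.

    With these weights a weighted random sampler draws each condition with
    equal probability, correcting the 43/42/43/72 imbalance.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    counts = manifest["condition"].value_counts()
    w = manifest["condition"].map(lambda c: 1.0 / counts[c]).to_numpy(dtype=float)
    return w


def build_dataset(
    cases,
    split_df: pd.DataFrame,
    out_dir: str | Path | None = None,
    window: int = SLICE_WINDOW,
    crop_size: int = 448,
    out_size: int = 224,
    render: bool = True,
) -> pd.DataFrame:
    """Assemble the full training manifest (and optionally the image files).

    ``cases`` maps case_id -> either a :class:`~fovecast.phantoms.PhantomCase`
    (with the preoperative member already registered) or a bare object with
    ``pre``/``post`` volumes and a ``truth.fovea_slice``.  Training-split
    slices are augmented six-fold; validation and test keep originals only.
    With ``render=False`` only the manifest bookkeeping is produced (no image
    I/O), which is enough for pair-count audits.

    100 training cases at the canonical 200-slice window give
    100 x 200 x 6 = 120,000 training pairs and 25 x 200 = 5,000 validation
    pairs.
    """
    case_map = {c.case_id: c for c in cases} if not isinstance(cases, dict) else cases
    lut = condition_lookup(window)
    rows = []
    images: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)

    for _, rec in split_df.iterrows():
        cid, split = rec["case_id"], rec["split"]
        case = case_map[cid]
        fovea = case.truth.fovea_slice
        n_slices = case.pre.n_slices if render else case.spec.n_slices
        indices = select_slices(n_slices, fovea, window)
        tags = AUGMENTATION_TAGS if split == "train" else ("orig",)
        for pos, idx in enumerate(indices):
            cond = int(lut[pos])
            pre_img = post_img = None
            if render:
                pre_slice = case.pre.slice(int(idx)).astype(np.float32)
                com = center_of_mass(pre_slice)
                pre_px = crop_resize(pre_slice, com, crop_size, out_size)
                post_px = crop_resize(
                    case.post.slice(int(idx)).astype(np.float32), com, crop_size, out_size
                )
                pre_img = SliceImage(pre_px, cid, int(idx), "orig")
                post_img = SliceImage(post_px, cid, int(idx), "orig")
                pairs = {
                    p.pre.augmentation_tag: p
                    for p in augment_pair(pre_img, post_img, cond)
                }
            for tag in tags:
                pre_path = post_path = ""
                if render and out_dir is not None:
                    pair = pairs[tag]
                    pre_path = str(out_dir / "images" / f"{cid}_s{idx:04d}_{tag}_pre.png")
                    post_path = str(out_dir / "images" / f"{cid}_s{idx:04d}_{tag}_post.png")
                    _save_png(pair.pre.pixels, pre_path)
                    _save_png(pair.post.pixels, post_path)
                elif render:
                    pair = pairs[tag]
                    images[f"{cid}_s{idx:04d}_{tag}"] = (
                        pair.pre.pixels,
                        pair.post.pixels,
                    )
                rows.append(
                    {
                        "case_id": cid,
                        "split": split,
                        "slice_index": int(idx),
                        "condition": cond,
                        "augmentation_tag": tag,
                        "sampling_weight": 1.0,
                        "pre_path": pre_path,
                        "post_path": post_path,
                    }
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    train = manifest["split"] == "train"
    if train.any():
        manifest.loc[train, "sampling_weight"] = sampling_weights(manifest[train])
    if render and out_dir is None:
        manifest.attrs["images"] = images
    return manifest


def _save_png(pixels: np.ndarray, path: str) -> None:
    Image.fromarray(np.round(pixels * 255.0).astype(np.uint8), mode="L").save(path)


def load_pair_arrays(manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Materialise (pre, post, condition, weight) arrays from a manifest.

    Reads PNGs when paths are present, otherwise uses in-memory images
    attached by :func:`build_dataset`.
    """
    images = manifest.attrs.get("images", {})
    pres, posts = [], []
    for _, r in manifest.iterrows():
        if r["pre_path"]:
            pre = np.asarray(Image.open(r["pre_path"]), dtype=np.float64) / 255.0
            post = np.asarray(Image.open(r["post_path"]), dtype=np.float64) / 255.0
        else:
            key = f"{r['case_id']}_s{int(r['slice_index']):04d}_{r['augmentation_tag']}"
            pre, post = images[key]
        pres.append(pre)
        posts.append(post)
    return (
        np.stack(pres),
        np.stack(posts),
        manifest["condition"].to_numpy(dtype=int),
        manifest["sampling_weight"].to_numpy(dtype=float),
    )
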