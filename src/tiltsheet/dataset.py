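"""Training-corpus preparation from raw epi/light-sheet image pairs.

The pipeline per pair of 100-frame stacks: average the frames to suppress
Poisson-Gaussian noise, cut patches from the ~5 um-wide illumination centre
strip (where the sheet actually excites), percentile-normalize, and split
deterministically at the pair level so no field of view leaks between the
training and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import ImagePair

__all__ = [
    "DatasetConfig",
    "TrainingPatch",
    "NormAffine",
    "average_frames",
    "crop_center_strips",
    "normalize_patch",
    "denormalize_patch",
    "strip_quality",
    "build_dataset",
]


@dataclass(frozen=True)
class NormAffine:
    """Record of the linear map used for normalization (for inversion).

    ``clip`` bounds the mapped values to [0, 1] (the percentile-based
    dataset convention); fixed physical-unit affines can disable it so no
    signal saturates.
    """

    lo: float
    hi: float
    degenerate: bool = False
    clip: bool = True

    def apply(self, img: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros_like(np.asarray(img, float))
        mapped = (np.asarray(img, float) - self.lo) / (self.hi - self.lo)
        return np.clip(mapped, 0.0, 1.0) if self.clip else mapped

    def invert(self, img: np.ndarray) -> np.ndarray:
        return np.asarray(img, float) * (self.hi - self.lo) + self.lo


@dataclass(frozen=True)
class TrainingPatch:
    input_img: np.ndarray
    target_img: np.ndarray
    source_id: str
    crop_index: int
    norm: NormAffine = field(default=NormAffine(0.0, 1.0))

    def __post_init__(self) -> None:
        if self.input_img.shape != self.target_img.shape:
            raise ValueError("input and target patches must share a shape")


@dataclass
class DatasetConfig:
    """Knobs of the preparation stage (defaults follow the acquisition
    geometry: 157 nm pixels, ~5 um centre strip, 3 crops per pair)."""

    strip_width_um: float = 5.0
    crops_per_pair: int = 3
    pixel_nm: float = 157.0
    n_average: int = 100
    split_fraction: float = 0.9
    lo_pct: float = 0.1
    hi_pct: float = 99.9
    quality_threshold: float = 1.2
    norm_source: str = "target"  # "target" or "input"
    center_col: int | None = None  # None = image centre


def average_frames(stack: np.ndarray, n: int) -> np.ndarray:
    """Pixelwise mean of the first ``n`` frames."""
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    if n < 1 or n > stack.shape[0]:
        raise ValueError(f"cannot average {n} frames of a {stack.shape[0]}-frame stack")
    return stack[:n].mean(axis=0)


def crop_center_strips(
    pair_avg: tuple[np.ndarray, np.ndarray],
    strip_width_um: float = 5.0,
    crops_per_pair: int = 3,
    pixel_nm: float = 157.0,
    center_col: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Cut co-located patches from the illumination centre strip.

    The strip is ``round(strip_width_um * 1000 / pixel_nm)`` pixels wide,
    centred on ``center_col``; ``crops_per_pair`` windows are spaced evenly
    along the strip.  Patch height is the per-crop share of the image
    height, truncated to a multiple of 32 px when that leaves at least
    32 px (network-friendly shapes).  Identical windows are applied to
    input and target.
    """
    if crops_per_pair < 1:
        raise ValueError("crops_per_pair must be >= 1")
    inp, tgt = (np.asarray(a, float) for a in pair_avg)
    if inp.shape != tgt.shape or inp.ndim != 2:
        raise ValueError("pair images must be 2D and share a shape")
    h, w = inp.shape
    width_px = int(round(strip_width_um * 1000.0 / pixel_nm))
    if width_px > w:
        raise ValueError(f"strip of {width_px} px wider than the {w}-px image")
    width_px = max(width_px, 1)
    cc = w // 2 if center_col is None else int(center_col)
    c0 = int(np.clip(cc - width_px // 2, 0, w - width_px))

    ph = h // crops_per_pair
    if ph >= 32:
        ph -= ph % 32
    if ph < 1:
        raise ValueError("more crops than image rows")
    if crops_per_pair == 1:
        starts = [(h - ph) // 2] if ph < h else [0]
    else:
        starts = [round(i * (h - ph) / (crops_per_pair - 1)) for i in range(crops_per_pair)]
    out = []
    for idx, r0 in enumerate(starts):
        sl = (slice(r0, r0 + ph), slice(c0, c0 + width_px))
        out.append((inp[sl].copy(), tgt[sl].copy(), idx))
    return out


def normalize_patch(
    img: np.ndarray,
    lo_pct: float = 0.1,
    hi_pct: float = 99.9,
    affine: NormAffine | None = None,
) -> tuple[np.ndarray, NormAffine]:
    """Percentile normalization: lo_pct -> 0, hi_pct -> 1, clipped to [0, 1].

    When ``affine`` is given it is applied instead of recomputing the
    percentiles (so one map can be shared between input and target); the
    affine parameters are returned for inversion.  A constant image maps to
    all zeros with a degeneracy flag.
    """
    img = np.asarray(img, float)
    if affine is None:
        if hi_pct <= lo_pct:
            raise ValueError("hi_pct must exceed lo_pct")
        lo = float(np.percentile(img, lo_pct))
        hi = float(np.percentile(img, hi_pct))
        if hi <= lo:
            affine = NormAffine(lo, lo + 1.0, degenerate=True)
        else:
            affine = NormAffine(lo, hi)
    return affine.apply(img), affine


def denormalize_patch(img: np.ndarray, affine: NormAffine) -> np.ndarray:
    return affine.invert(img)


def strip_quality(target_strip: np.ndarray) -> float:
    """Contrast proxy used for 'high-quality pair' selection: mean of the
    brightest decile of pixels over the mean of the dimmest half, computed
    on raw counts so the camera offset acts as the background floor (a
    structure-free strip scores ~1)."""
    v = np.sort(np.asarray(target_strip, float).ravel())
    top = v[int(0.9 * v.size):]
    bottom = v[: max(v.size // 2, 1)]
    denom = bottom.mean()
    if denom <= 0:
        return np.inf if top.mean() > 0 else 1.0
    return float(top.mean() / denom)


def build_dataset(
    pairs: list[ImagePair | tuple],
    config: DatasetConfig | None = None,
    seed: int = 0,
) -> tuple[list[TrainingPatch], list[TrainingPatch], pd.DataFrame]:
    """Average -> quality-filter -> crop -> normalize -> pair-level split.

    ``pairs`` are ``ImagePair`` objects or ``(epi_stack, sheet_stack, id)``
    tuples.  The split is seeded and applied to pair identities, so no pair
    contributes patches to both sets.  The manifest records provenance and
    the normalization affine of every patch.
    """
    config = config or DatasetConfig()
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to build a split dataset")

    prepared: list[tuple[str, np.ndarray, np.ndarray, float]] = []
    for i, pair in enumerate(pairs):
        if isinstance(pair, ImagePair):
            epi, sheet, pid = pair.epi_stack, pair.sheet_stack, f"pair{i:05d}"
        else:
            epi, sheet, pid = pair
        n_avg = min(config.n_average, epi.shape[0])
        epi_avg = average_frames(epi, n_avg)
        sheet_avg = average_frames(sheet, n_avg)
        quality = strip_quality(sheet_avg)
        if quality < config.quality_threshold:
            continue
        prepared.append((str(pid), epi_avg, sheet_avg, quality))
    if len(prepared) < 2:
        raise ValueError("fewer than 2 pairs survive the quality filter")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(prepared))
    n_train = int(round(config.split_fraction * len(prepared)))
    n_train = min(max(n_train, 1), len(prepared) - 1)
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[prepared[idx][0]] = "train" if rank < n_train else "val"

    train: list[TrainingPatch] = []
    val: list[TrainingPatch] = []
    rows = []
    for pid, epi_avg, sheet_avg, quality in prepared:
        crops = crop_center_strips(
            (epi_avg, sheet_avg),
            config.strip_width_um,
            config.crops_per_pair,
            config.pixel_nm,
            config.center_col,
        )
        for inp, tgt, crop_idx in crops:
            ref = tgt if config.norm_source == "target" else inp
            _, affine = normalize_patch(ref, config.lo_pct, config.hi_pct)
            inp_n, _ = normalize_patch(inp, affine=affine)
            tgt_n, _ = normalize_patch(tgt, affine=affine)
            patch = TrainingPatch(inp_n, tgt_n, pid, crop_idx, affine)
            (train if split_of[pid] == "train" else val).append(patch)
            rows.append(
                {
                    "patch_id": f"{pid}_c{crop_idx}",
                    "source_id": pid,
                    "crop_index": crop_idx,
                    "split": split_of[pid],
                    "norm_lo": affine.lo,
                    "norm_hi": affine.hi,
                    "norm_source": config.norm_source,
                    "quality": quality,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    return train, val, manifest
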