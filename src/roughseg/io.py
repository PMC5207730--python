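"""Readers and writers: PNG/TIFF, NIfTI slices, label maps, run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage import color

from .em_engine import FitConfig, SegmentationResult
from .grid import ImageGrid
from .rough_regions import BO, PO, RoughPartition

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _rescale_integer(arr: np.ndarray) -> np.ndarray:
    info = np.iinfo(arr.dtype)
    return arr.astype(np.float64) / info.max


def _lab_rescale(rgb: np.ndarray) -> np.ndarray:
    """RGB in [0,1] -> Lab with each channel rescaled to [0,1].

    L spans [0, 100]; a and b are mapped from the conventional
    [-128, 127] byte range.
    """
    lab = color.rgb2lab(rgb)
    out = np.empty_like(lab)
    out[:, :, 0] = lab[:, :, 0] / 100.0
    out[:, :, 1] = (lab[:, :, 1] + 128.0) / 255.0
    out[:, :, 2] = (lab[:, :, 2] + 128.0) / 255.0
    return out


def read_image(path, color_space: str = "gray",
               slice_index: int | None = None) -> ImageGrid:
    """Load a PNG/TIFF or NIfTI image as an :class:`ImageGrid` in [0, 1].

    Grayscale inputs become single-channel; RGB inputs are converted to
    the Lab color space (channels rescaled to [0, 1]) when
    ``color_space='lab'``, or to luminance when ``'gray'``. 3-D NIfTI
    volumes require ``slice_index`` (an axial slice is extracted);
    NIfTI intensities are min-max rescaled.
    """
    path = Path(path)
    if color_space not in ("gray", "lab"):
        raise ValueError("color_space must be 'gray' or 'lab'")
    if _is_nifti(path):
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError("3-D NIfTI volume: a slice index is required")
            vol = vol[:, :, slice_index]
        elif vol.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
        lo, hi = vol.min(), vol.max()
        if hi > lo:
            vol = (vol - lo) / (hi - lo)
        return ImageGrid(vol)

    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path.suffix}")
    arr = iio.imread(path)
    integer = np.issubdtype(arr.dtype, np.integer)
    if integer:
        arr = _rescale_integer(arr)
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        if color_space == "lab":
            return ImageGrid(_lab_rescale(arr))
        return ImageGrid(color.rgb2gray(arr), integer_levels=False)
    return ImageGrid(arr, integer_levels=integer)


def write_label_png(labels: np.ndarray, path) -> None:
    """Write an integer label map losslessly as an 8-bit PNG."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("labels must fit in uint8 for PNG export")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def read_label_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)), dtype=np.int64)


def export_region_maps(rough: RoughPartition, out_dir) -> list[Path]:
    """One PNG per cluster rendering Po=255 (bright), Bo=128, Ne=0."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(rough.region.shape[2]):
        img = np.zeros(rough.region.shape[:2], dtype=np.uint8)
        img[rough.region[:, :, k] == BO] = 128
        img[rough.region[:, :, k] == PO] = 255
        p = out_dir / f"regions_cluster{k + 1}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def write_result(result: SegmentationResult, out_dir,
                 config: FitConfig | None = None,
                 nifti_like=None) -> dict:
    """Write a segmentation to disk: label map, posteriors, metadata.

    Produces ``labels.png`` (raw 1..K values), one ``posterior_k.png``
    per cluster (z-tilde scaled to 0..255), ``labels.nii.gz`` when a
    reference NIfTI image is given, and ``metadata.json`` holding the
    fit configuration, iteration count and objective trace.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_label_png(result.labels, out_dir / "labels.png")
    H, W = result.labels.shape
    K = result.posteriors.shape[1]
    for k in range(K):
        post = result.posteriors[:, k].reshape(H, W)
        iio.imwrite(out_dir / f"posterior_{k + 1}.png",
                    np.clip(post * 255.0, 0, 255).astype(np.uint8))
    if nifti_like is not None:
        ref = nib.load(str(nifti_like))
        nib.save(nib.Nifti1Image(result.labels.astype(np.int16), ref.affine),
                 str(out_dir / "labels.nii.gz"))
    meta = {
        "config": None if config is None else {
            "n_clusters": config.n_clusters,
            "n_components": config.n_components,
            "mc_samples": config.mc_samples,
            "max_iter": config.max_iter,
            "tol": config.tol,
            "seed": config.seed,
            "recompute_regions": config.recompute_regions,
            "freeze_samples": config.freeze_samples,
            "unbounded": config.unbounded,
        },
        "n_iter": result.n_iter,
        "converged": result.converged,
        "objective_trace": [float(v) for v in result.objective_trace],
        "thresholds": None if result.thresholds is None else
            {"t1": result.thresholds.t1, "t2": result.thresholds.t2},
    }
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return meta
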