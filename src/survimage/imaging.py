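"""Survival-ordered pairwise difference images ("dimension raising").

Every unordered pair of patients with distinct survival times yields two
difference vectors over the shared gene order:

* ``TLS`` — shorter-survivor's TPM subtracted from the longer-survivor's
  (the expression pattern of *longer* survival, the positive class), and
* ``TSL`` — the negation (pattern of shorter survival, the negative class),

so the two classes are exactly balanced by construction. Each length-G
vector is reshaped row-major into the smallest square matrix (side
``ceil(sqrt(G))``; 246 for the 60,483-gene default), linearly rescaled so the
most negative difference maps to 0 and the most positive to 255, rounded
half-up to 8-bit grayscale, with the trailing ``side² − G`` cells zero-padded,
and can be written losslessly as a single-channel PNG.

Scaling is per-image by default: each image uses its own extremes, which
makes the TSL image the exact 255-complement of its TLS partner at every
data cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .cohort import Cohort

__all__ = [
    "DifferenceImage",
    "ImagingError",
    "matrix_side",
    "generate_pairs",
    "difference_vector",
    "raise_dimension",
    "build_image_set",
    "write_png",
    "read_png",
    "write_image_set",
    "recover_difference",
    "LABELS",
]

LABELS = ("TLS", "TSL")


class ImagingError(ValueError):
    """Raised for invalid imaging inputs (ties, non-finite values, geometry)."""


def matrix_side(n_genes: int) -> int:
    """Side of the smallest square matrix holding ``n_genes`` cells."""
    if n_genes < 1:
        raise ImagingError("need at least one gene")
    return math.isqrt(n_genes - 1) + 1


@dataclass
class DifferenceImage:
    """One TLS or TSL grayscale difference image.

    ``vmin``/``vmax`` are the difference-vector extremes used for the linear
    0–255 scaling; keeping them makes the quantization invertible to within
    half a gray step.
    """

    label: str
    longer_id: str
    shorter_id: str
    pixels: np.ndarray  # (side, side) uint8
    n_genes: int
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ImagingError(f"label must be one of {LABELS}, got {self.label!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        side = matrix_side(self.n_genes)
        if self.pixels.shape != (side, side):
            raise ImagingError(
                f"pixels shape {self.pixels.shape} does not match side {side} "
                f"for {self.n_genes} genes"
            )
        if self.pad_count and np.any(self.pixels.ravel()[self.n_genes:] != 0):
            raise ImagingError("padding cells must be zero")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def pad_count(self) -> int:
        return self.side * self.side - self.n_genes

    @property
    def filename(self) -> str:
        return f"{self.label}_{self.longer_id}_{self.shorter_id}.png"


def generate_pairs(c: Cohort) -> list[tuple[str, str]]:
    """All unordered patient pairs, oriented longer-survivor first.

    The list is ordered by decreasing survival of the longer member, then
    decreasing survival of the shorter member, so for patients N1..N5 sorted
    by decreasing survival the pairs open (N1,N2), (N1,N3), (N1,N4), (N1,N5),
    (N2,N3), ...  For n patients there are n(n−1)/2 pairs.

    Raises
    ------
    ImagingError
        If two patients share a survival time (the cohort filter is supposed
        to have removed ties).
    """
    surv = {r.sample_id: r.survival_days for r in c.records}
    if any(v is None for v in surv.values()):
        raise ImagingError("all patients need a survival time; filter the cohort first")
    if len(set(surv.values())) != len(surv):
        raise ImagingError("tied survival times; filter the cohort first")
    ordered = sorted(surv, key=lambda s: -surv[s])
    return [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    ]


def difference_vector(
    longer: np.ndarray, shorter: np.ndarray, label: str
) -> np.ndarray:
    """Pairwise expression difference in the requested orientation.

    ``TLS`` is ``longer − shorter``; ``TSL`` is ``shorter − longer`` (its
    negation).
    """
    longer = np.asarray(longer, dtype=np.float64)
    shorter = np.asarray(shorter, dtype=np.float64)
    if longer.shape != shorter.shape or longer.ndim != 1:
        raise ImagingError(
            f"vector shapes differ: {longer.shape} vs {shorter.shape}"
        )
    if label == "TLS":
        return longer - shorter
    if label == "TSL":
        return shorter - longer
    raise ImagingError(f"label must be one of {LABELS}, got {label!r}")


def raise_dimension(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Reshape a difference vector into the smallest square 8-bit image.

    Values fill the matrix row-major (left→right, top→bottom), are linearly
    mapped so ``min(v) → 0`` and ``max(v) → 255`` with round-half-up
    quantization, and the trailing ``side² − len(v)`` cells are zero. A
    constant vector (no range) maps every data cell to 0.

    Returns
    -------
    (pixels, vmin, vmax)
        The uint8 image and the extremes used for scaling.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size < 1:
        raise ImagingError("expected a non-empty 1-D vector")
    if not np.isfinite(v).all():
        raise ImagingError("difference vector contains non-finite values")
    side = matrix_side(v.size)
    vmin = float(v.min())
    vmax = float(v.max())
    flat = np.zeros(side * side, dtype=np.uint8)
    if vmax > vmin:
        scaled = 255.0 * (v - vmin) / (vmax - vmin)
        flat[: v.size] = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return flat.reshape(side, side), vmin, vmax


def make_image(
    longer_vec: np.ndarray,
    shorter_vec: np.ndarray,
    label: str,
    longer_id: str,
    shorter_id: str,
) -> DifferenceImage:
    """Difference vector → grayscale image for one oriented pair."""
    v = difference_vector(longer_vec, shorter_vec, label)
    pixels, vmin, vmax = raise_dimension(v)
    return DifferenceImage(
        label=label,
        longer_id=longer_id,
        shorter_id=shorter_id,
        pixels=pixels,
        n_genes=v.size,
        vmin=vmin,
        vmax=vmax,
    )


def build_image_set(
    c: Cohort, sample_ids: list[str] | None = None
) -> list[DifferenceImage]:
    """One TLS and one TSL image per pair: n(n−1) images, classes balanced.

    ``sample_ids`` restricts pairing to a subset (e.g. one stratum's training
    ids); pairs are never formed across the subset boundary.
    """
    if c.expression.unit != "TPM":
        raise ImagingError(
            f"image generation requires TPM expression, got {c.expression.unit}"
        )
    sub = c if sample_ids is None else c.subset(list(sample_ids))
    cols = {sid: sub.expression.column(sid) for sid in sub.sample_ids}
    images: list[DifferenceImage] = []
    for longer_id, shorter_id in generate_pairs(sub):
        for label in LABELS:
            images.append(
                make_image(cols[longer_id], cols[shorter_id], label, longer_id, shorter_id)
            )
    return images


def write_png(img: DifferenceImage, path) -> None:
    """Save as an 8-bit single-channel grayscale PNG (lossless)."""
    try:
        Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise ImagingError(f"cannot write PNG to {path}: {exc}") from exc


def read_png(path, expected_side: int | None = None) -> np.ndarray:
    """Read a grayscale PNG back to a uint8 pixel matrix.

    Raises
    ------
    ImagingError
        If the file is not square 8-bit grayscale, or does not match
        ``expected_side``.
    """
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                raise ImagingError(f"{path}: expected 8-bit grayscale, got mode {im.mode}")
            pixels = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError as exc:
        raise ImagingError(f"cannot read PNG {path}: {exc}") from exc
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ImagingError(f"{path}: expected a square image, got {pixels.shape}")
    if expected_side is not None and pixels.shape[0] != expected_side:
        raise ImagingError(
            f"{path}: expected side {expected_side}, got {pixels.shape[0]}"
        )
    return pixels


def write_image_set(images: list[DifferenceImage], out_dir) -> Path:
    """Write PNGs named ``<label>_<longerID>_<shorterID>.png`` plus a manifest.

    The JSON manifest records label, pair ids, gene count and the scaling
    extremes per image, so labels and (approximate) difference vectors are
    recoverable from disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for img in images:
        write_png(img, out / img.filename)
        manifest.append(
            {
                "file": img.filename,
                "label": img.label,
                "longer_id": img.longer_id,
                "shorter_id": img.shorter_id,
                "n_genes": img.n_genes,
                "vmin": img.vmin,
                "vmax": img.vmax,
            }
        )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def recover_difference(img: DifferenceImage) -> np.ndarray:
    """Invert the grayscale quantization at the data cells.

    Exact to within half a gray step, i.e. ``(vmax − vmin) / 510``.
    """
    flat = img.pixels.ravel()[: img.n_genes].astype(np.float64)
    if img.vmax == img.vmin:
        return np.full(img.n_genes, img.vmin)
    return img.vmin + flat / 255.0 * (img.vmax - img.vmin)
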