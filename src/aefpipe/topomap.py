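"""Render per-sensor normalized energies as scalp topography images.

Energies are interpolated over the projected scalp disc (piecewise-cubic
Clough-Tocher interpolation on a Delaunay triangulation of the sensor sites,
exact at the sites; the annulus between the convex hull and the disc rim is
filled with the nearest site's value), then mapped through a fixed
perceptually-uniform colormap to a 224 x 224 RGB image — the input size of
inception-style image classifiers. Pixels outside the head disc are the
background color. Rendering is deterministic.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay, cKDTree

from .enhancement import EnergyVector

DEFAULT_SIZE = 224
DEFAULT_CMAP = "viridis"
BACKGROUND = np.zeros(3)  # black, distinct from viridis' dark-blue floor


@dataclass
class TopoImage:
    """A rendered scalp map: RGB pixels in [0, 1] plus the scalar field."""

    pixels: np.ndarray  # (size, size, 3) float32 in [0, 1]
    field: np.ndarray  # (size, size) scalar field, NaN outside the disc
    meta: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255).astype(np.uint8)


class TopomapRenderer:
    """Reusable renderer for a fixed sensor layout.

    Precomputes the triangulation, the pixel grid and the nearest-site fill
    map once, so rendering many trials of the same session is cheap.
    """

    def __init__(self, coords2d: np.ndarray, size: int = DEFAULT_SIZE, cmap: str = DEFAULT_CMAP):
        coords2d = np.asarray(coords2d, dtype=float)
        if coords2d.ndim != 2 or coords2d.shape[1] != 2:
            raise ValueError("coords2d must be (n, 2)")
        if coords2d.shape[0] < 3:
            raise ValueError("need at least 3 sensors to interpolate")
        r = np.linalg.norm(coords2d, axis=1)
        if np.any(r > 1 + 1e-9):
            raise ValueError("planar coordinates must lie within the unit disc")
        self.coords = coords2d
        self.size = int(size)
        self.cmap = colormaps[cmap]
        self.cmap_name = cmap

        ax = np.linspace(-1, 1, self.size)
        gx, gy = np.meshgrid(ax, ax)
        self._grid = np.column_stack([gx.ravel(), gy.ravel()])
        self._inside = (gx.ravel() ** 2 + gy.ravel() ** 2) <= 1.0
        # virtual boundary ring just outside the disc so every disc pixel lies
        # inside the triangulation; ring values are inverse-distance-weighted
        # averages of the nearest sensors (a constant field stays constant)
        n_ring = 72
        ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
        ring = 1.02 * np.column_stack([np.cos(ang), np.sin(ang)])
        d, idx = cKDTree(coords2d).query(ring, k=min(3, coords2d.shape[0]))
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        self._ring_weights = 1.0 / np.maximum(d, 1e-6) ** 2
        self._ring_weights /= self._ring_weights.sum(axis=1, keepdims=True)
        self._ring_idx = idx
        self._tri = Delaunay(np.vstack([coords2d, ring]))
        # nearest sensor for any residual out-of-hull pixel (safety fallback)
        _, self._nearest = cKDTree(coords2d).query(self._grid[self._inside])

    def pixel_of_sensor(self, i: int) -> tuple[int, int]:
        """(row, col) pixel index of sensor i's planar coordinate."""
        x, y = self.coords[i]
        col = int(round((x + 1) / 2 * (self.size - 1)))
        row = int(round((y + 1) / 2 * (self.size - 1)))
        return row, col

    def render(self, energy: EnergyVector) -> TopoImage:
        if not energy.normalized:
            raise ValueError("render expects normalized energies (max = 1)")
        values = np.asarray(energy.energies, dtype=float)
        if values.size != self.coords.shape[0]:
            raise ValueError("energy length does not match sensor count")

        ring_values = (self._ring_weights * values[self._ring_idx]).sum(axis=1)
        interp = CloughTocher2DInterpolator(self._tri, np.concatenate([values, ring_values]))
        fld = np.full(self.size * self.size, np.nan)
        inside_vals = interp(self._grid[self._inside])
        nan = np.isnan(inside_vals)
        if np.any(nan):
            inside_vals[nan] = values[self._nearest[nan]]
        fld[self._inside] = np.clip(inside_vals, 0.0, 1.0)
        fld = fld.reshape(self.size, self.size)

        rgb = np.empty((self.size, self.size, 3), dtype=np.float32)
        rgb[:] = BACKGROUND
        in2d = ~np.isnan(fld)
        rgb[in2d] = self.cmap(fld[in2d])[:, :3]

        checksum = hashlib.sha1(values.tobytes()).hexdigest()[:12]
        meta = {"colormap": self.cmap_name, "mask_radius": 1.0, "energy_checksum": checksum}
        return TopoImage(pixels=rgb, field=fld, meta=meta)


def render_topomap(
    energy: EnergyVector,
    coords2d: np.ndarray,
    size: int = DEFAULT_SIZE,
    cmap: str = DEFAULT_CMAP,
) -> TopoImage:
    """Render one normalized energy vector as a scalp image.

    For rendering many trials over the same layout, construct a
    :class:`TopomapRenderer` once and call its ``render`` method instead.
    """
    return TopomapRenderer(coords2d, size=size, cmap=cmap).render(energy)


# ---------------------------------------------------------------------------
# image dataset on disk
# ---------------------------------------------------------------------------

CLASS_LABELS = ("aef", "noise")


def write_image_dataset(
    images: list[TopoImage],
    labels: list[str],
    directory,
    source_ids: list[str] | None = None,
    append: bool = False,
) -> list[dict]:
    """Write images as PNGs into per-class subdirectories with a manifest.

    Returns the manifest: one dict per image with keys ``path`` (relative to
    ``directory``), ``label`` and ``source_trial_id``. Also written as
    ``manifest.csv``. PNG storage is lossless at 8 bits per channel. With
    ``append``, new images extend an existing dataset in the directory.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels must align")
    for lb in labels:
        if lb not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {lb!r}")
    if source_ids is None:
        source_ids = [f"img{i:04d}" for i in range(len(images))]
    directory = Path(directory)
    for cls in CLASS_LABELS:
        (directory / cls).mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    counters = {cls: 0 for cls in CLASS_LABELS}
    if append and (directory / "manifest.csv").exists():
        manifest = read_manifest(directory)
        for row in manifest:
            counters[row["label"]] += 1
    for img, lb, sid in zip(images, labels, source_ids):
        name = f"{lb}_{counters[lb]:04d}.png"
        counters[lb] += 1
        rel = f"{lb}/{name}"
        Image.fromarray(img.to_uint8()).save(directory / rel)
        manifest.append({"path": rel, "label": lb, "source_trial_id": sid})
    with open(directory / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["path", "label", "source_trial_id"])
        w.writeheader()
        w.writerows(manifest)
    return manifest


def read_manifest(directory) -> list[dict]:
    with open(Path(directory) / "manifest.csv", newline="") as fh:
        return list(csv.DictReader(fh))


def load_image(path) -> np.ndarray:
    """Load a PNG back as a (size, size, 3) float32 array in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return arr / 255.0


def load_image_dataset(directory, manifest: list[dict] | None = None):
    """Load (images, labels, ids) from a written dataset directory."""
    directory = Path(directory)
    if manifest is None:
        manifest = read_manifest(directory)
    images = [load_image(directory / row["path"]) for row in manifest]
    labels = [row["label"] for row in manifest]
    ids = [row["source_trial_id"] for row in manifest]
    return images, labels, ids
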