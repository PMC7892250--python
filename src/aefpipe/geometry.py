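"""Sensor-array geometry: neighborhoods and scalp projection.

The enhancement stage needs, for every MEG sensor, the set of sensors within a
fixed Euclidean radius (the sensor's *neighborhood*), and the imaging stage
needs a 2-D layout of the cap. Both live here, together with a plain-text
layout file format.

Coordinates are in meters in a head frame centered on the fitting-sphere
center: +x anterior (nose), +y left, +z toward the vertex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default neighborhood radius in meters: 1.7 x the ~2.2 cm mean inter-sensor
#: spacing of a 274-channel whole-head array.
DEFAULT_RADIUS = 0.022 * 1.7


@dataclass
class SensorArray:
    """Labeled 3-D sensor positions on a head-covering cap.

    Parameters
    ----------
    labels : list of str
        Unique sensor identifiers.
    positions : (n, 3) ndarray
        Sensor positions in meters, head frame (origin at sphere center,
        +z toward the vertex).
    region_tags : dict, optional
        Map label -> anatomical tag (e.g. ``"temporal-right"``).
    """

    labels: list[str]
    positions: np.ndarray
    region_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("labels and positions disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        if len(self.labels) < 1:
            raise ValueError("need at least one sensor")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    @property
    def radii(self) -> np.ndarray:
        """Distance of each sensor from the head-frame origin."""
        return np.linalg.norm(self.positions, axis=1)

    def is_spherical_cap(self, head_radius: float, tol: float = 0.10) -> bool:
        """Whether all sensors lie within head_radius +/- tol (cap assumption)."""
        r = self.radii
        return bool(np.all((r >= head_radius * (1 - tol)) & (r <= head_radius * (1 + tol))))

    @staticmethod
    def from_mapping(mapping: dict, region_tags: dict | None = None) -> "SensorArray":
        """Adapter: build an array from a {label: (x, y, z) in meters} mapping.

        Standard M/EEG containers expose such mappings (e.g. an MNE Info's
        channel positions); this is the read-only import contract.
        """
        labels = list(mapping)
        positions = np.array([mapping[lb] for lb in labels], dtype=float)
        return SensorArray(labels=labels, positions=positions, region_tags=region_tags or {})

    def indices_with_tag(self, tag: str) -> np.ndarray:
        """Indices of sensors whose region tag equals ``tag``."""
        return np.array(
            [i for i, lb in enumerate(self.labels) if self.region_tags.get(lb) == tag],
            dtype=int,
        )


@dataclass
class NeighbourhoodGraph:
    """Fixed-radius neighborhood structure over a sensor array.

    ``neighbors[i]`` lists the indices of all sensors other than ``i`` within
    ``radius`` meters of sensor ``i`` (closed ball: ties at exactly the radius
    are included). The relation is symmetric by construction.
    """

    radius: float
    neighbors: list[np.ndarray]
    degrees: np.ndarray

    @property
    def n_sensors(self) -> int:
        return len(self.neighbors)


def build_neighbourhoods(array: SensorArray, radius: float = DEFAULT_RADIUS) -> NeighbourhoodGraph:
    """Build the fixed-radius neighborhood graph of a sensor array.

    Parameters
    ----------
    array : SensorArray
    radius : float
        Neighborhood radius in meters; default ``0.022 * 1.7``.

    Returns
    -------
    NeighbourhoodGraph
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    pos = array.positions
    # pairwise distances; arrays here are a few hundred sensors, O(n^2) is fine
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    n = array.n_sensors
    off_diag = ~np.eye(n, dtype=bool)
    if n > 1 and (dist[off_diag] < 1e-12).any():
        logger.warning("duplicate sensor positions detected in array")
    within = dist <= radius
    np.fill_diagonal(within, False)
    neighbors = [np.flatnonzero(within[i]) for i in range(n)]
    degrees = np.array([len(nb) for nb in neighbors], dtype=int)
    return NeighbourhoodGraph(radius=float(radius), neighbors=neighbors, degrees=degrees)


def default_radius(array: SensorArray, factor: float = 1.7) -> float:
    """Neighborhood radius as ``factor`` x mean nearest-neighbor distance.

    Generalizes the 1.7 x (mean inter-sensor spacing) rule to arbitrary
    arrays.
    """
    if array.n_sensors < 2:
        raise ValueError("default_radius needs at least 2 sensors")
    if factor <= 0:
        raise ValueError("factor must be positive")
    pos = array.positions
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    return float(factor * dist.min(axis=1).mean())


def project_to_plane(array: SensorArray) -> np.ndarray:
    """Azimuthal-equidistant projection of the cap onto the unit disc.

    Each sensor maps to planar polar coordinates (r, phi) with r proportional
    to its polar angle from the vertex (+z axis) and phi its azimuth; the
    vertex maps to the origin. The output is scaled so the cap rim (the
    maximum polar angle present in the array) maps to the unit circle.

    Returns
    -------
    (n, 2) ndarray of planar coordinates in the unit disc.
    """
    pos = array.positions
    r3 = np.linalg.norm(pos, axis=1)
    if np.any(r3 == 0):
        raise ValueError("sensor at the head-frame origin cannot be projected")
    polar = np.arccos(np.clip(pos[:, 2] / r3, -1.0, 1.0))
    # well-defined anywhere strictly above the antipode of the vertex
    if np.any(polar >= np.pi * (170.0 / 180.0)):
        raise ValueError("sensor at or near the projection antipode")
    azim = np.arctan2(pos[:, 1], pos[:, 0])
    rim = polar.max()
    if rim == 0:  # all sensors at the vertex
        return np.zeros((array.n_sensors, 2))
    r2 = polar / rim
    return np.column_stack([r2 * np.cos(azim), r2 * np.sin(azim)])


def write_layout(path, array: SensorArray) -> None:
    """Write a sensor layout as a plain-text table: label x y z [tag]."""
    with open(path, "w") as fh:
        fh.write("# label\tx_m\ty_m\tz_m\ttag\n")
        for lb, p in zip(array.labels, array.positions):
            tag = array.region_tags.get(lb, "-")
            fh.write(f"{lb}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\t{tag}\n")


def read_layout(path) -> SensorArray:
    """Read a sensor layout written by :func:`write_layout`."""
    labels: list[str] = []
    rows: list[list[float]] = []
    tags: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed layout line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
            if len(parts) >= 5 and parts[4] != "-":
                tags[parts[0]] = parts[4]
    return SensorArray(labels=labels, positions=np.array(rows), region_tags=tags)
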