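"""Neighborhood-correlation signal enhancement and per-sensor energy.

The core idea: a genuine evoked field is seen coherently by several adjacent
sensors, while sensor noise is not. For each sensor, the Pearson correlations
with its neighborhood sensors are computed on the raw single-trial window;
neighbors whose |correlation| reaches a threshold (default 0.8) contribute a
correlation-weighted copy of their signal to the selected sensor. Channels
with no qualifying neighbor are left untouched, so noise-dominated regions
stay at their original level while source regions are amplified — the signal
energy then concentrates over the source.

With Q the set of qualifying neighbors of channel i and n = |Q|:

    n = 0 :  X_i' = X_i
    n = 1 :  X_i' = X_i + c_ij X_j
    n >= 2:  X_i' = X_i + (sum_{j in Q} c_ij X_j) / (n - 1)

Weights keep their sign: an anticorrelated neighbor (c <= -threshold)
contributes with a sign flip, i.e. constructively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import NeighbourhoodGraph
from .recording import TrialSegment

logger = logging.getLogger(__name__)

#: Supported denominator conventions for the n >= 2 branch.
ENHANCE_MODES = ("n_minus_1", "n", "n_plus_1")


@dataclass
class EnhancedTrial:
    """A trial after neighborhood-correlation enhancement.

    ``weights_used[i]`` lists the (neighbor index, correlation) pairs that
    qualified for channel i; ``n_qualified[i]`` is their count.
    """

    data: np.ndarray
    onset: float
    duration: float
    rate: float
    trial_id: str = ""
    channel_labels: list[str] = field(default_factory=list)
    weights_used: list[list[tuple[int, float]]] = field(default_factory=list)
    n_qualified: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EnergyVector:
    """Per-sensor signal energy (sum of squares over the trial window)."""

    energies: np.ndarray
    normalized: bool
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(self.energies < 0):
            raise ValueError("energies must be nonnegative")
        if self.normalized and self.energies.size:
            if not np.isclose(self.energies.max(), 1.0):
                raise ValueError("normalized energies must have max 1")


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient with population (1/N) moments.

    c = (E[xy] - E[x]E[y]) / sqrt(Var x * Var y), clamped to [-1, 1]
    against floating-point rounding. Zero variance in either input is an
    error; the caller decides the fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx = (x * x).mean() - mx * mx
    vy = (y * y).mean() - my * my
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance input to pearson_correlation")
    c = ((x * y).mean() - mx * my) / np.sqrt(vx * vy)
    return float(np.clip(c, -1.0, 1.0))


def _neighbor_correlations(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full channel correlation matrix plus a valid-channel (nonzero var) mask."""
    X = np.asarray(data, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    var = (Xc**2).mean(axis=1)
    valid = var > 0
    sd = np.sqrt(np.where(valid, var, 1.0))
    Z = Xc / sd[:, None]
    C = (Z @ Z.T) / X.shape[1]
    np.clip(C, -1.0, 1.0, out=C)
    return C, valid


def enhance_trial(
    trial: TrialSegment,
    graph: NeighbourhoodGraph,
    threshold: float = 0.8,
    mode: str = "n_minus_1",
) -> EnhancedTrial:
    """Apply neighborhood-correlation enhancement to one trial.

    All correlations are computed on the ORIGINAL trial data and every output
    channel is a function of original channels only (no sequential update).

    Parameters
    ----------
    trial : TrialSegment
    graph : NeighbourhoodGraph
        Must cover exactly the trial's channel set.
    threshold : float
        Qualification threshold on |c|, in (0, 1]; ties (|c| == threshold)
        are included. Default 0.8.
    mode : str
        Denominator convention for the n >= 2 branch: ``"n_minus_1"``
        (default), ``"n"``, or ``"n_plus_1"`` (the latter divides the whole
        sum, selected signal included, by n + 1).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ENHANCE_MODES:
        raise ValueError(f"mode must be one of {ENHANCE_MODES}")
    if trial.n_channels != graph.n_sensors:
        raise ValueError(
            f"trial has {trial.n_channels} channels but graph covers "
            f"{graph.n_sensors} sensors"
        )
    X = np.asarray(trial.data, dtype=float)
    C, valid = _neighbor_correlations(X)
    if not valid.all():
        logger.warning("%d zero-variance channel(s): left unenhanced", (~valid).sum())

    out = X.copy()
    weights_used: list[list[tuple[int, float]]] = []
    n_qualified = np.zeros(trial.n_channels, dtype=int)
    for i in range(trial.n_channels):
        if not valid[i]:
            weights_used.append([])
            continue
        nbrs = graph.neighbors[i]
        nbrs = nbrs[valid[nbrs]] if nbrs.size else nbrs
        if nbrs.size == 0:
            weights_used.append([])
            continue
        c = C[i, nbrs]
        q = np.abs(c) >= threshold
        qn, qc = nbrs[q], c[q]
        n = qn.size
        n_qualified[i] = n
        weights_used.append([(int(j), float(w)) for j, w in zip(qn, qc)])
        if n == 0:
            continue
        contrib = qc @ X[qn]
        if n == 1:
            out[i] = X[i] + contrib
        elif mode == "n_minus_1":
            out[i] = X[i] + contrib / (n - 1)
        elif mode == "n":
            out[i] = X[i] + contrib / n
        else:  # n_plus_1: the whole superposition divided by n + 1
            out[i] = (X[i] + contrib) / (n + 1)

    return EnhancedTrial(
        data=out,
        onset=trial.onset,
        duration=trial.duration,
        rate=trial.rate,
        trial_id=trial.trial_id,
        channel_labels=list(trial.channel_labels),
        weights_used=weights_used,
        n_qualified=n_qualified,
    )


def trial_energy(trial: TrialSegment | EnhancedTrial, normalize: bool = True) -> EnergyVector:
    """Per-channel energy (sum of squares over the window).

    With ``normalize`` the energies are divided by their maximum so the
    hottest sensor reads 1; an all-zero trial cannot be normalized.
    """
    data = np.asarray(trial.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty trial")
    e = (data**2).sum(axis=1)
    if normalize:
        m = e.max()
        if m == 0:
            raise ValueError("all-zero trial: normalization undefined")
        e = e / m
    return EnergyVector(
        energies=e, normalized=normalize, labels=list(getattr(trial, "channel_labels", []))
    )


def write_energy_table(path, energy: EnergyVector) -> None:
    """Write energies as a 2-column text table (label, energy)."""
    labels = energy.labels or [f"ch{i:03d}" for i in range(energy.energies.size)]
    with open(path, "w") as fh:
        for lb, e in zip(labels, energy.energies):
            fh.write(f"{lb}\t{e:.9g}\n")
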