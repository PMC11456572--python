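"""Deterministic FACT streamline tracking and the fiber-number connectome.

FACT (fiber assignment by continuous tracking) advances a streamline
piecewise-linearly: within each voxel it follows that voxel's principal
eigenvector to the voxel boundary, then adopts the next voxel's eigenvector
(sign-aligned with the direction of travel).  Tracking terminates when the
next voxel's FA falls below ``fa_stop``, the turning angle exceeds
``angle_max_deg``, or the streamline leaves the grid.  Every voxel with
FA >= ``fa_stop`` seeds one streamline from its center, tracked in both
directions.

The connectome counts streamlines whose two endpoints lie in distinct
labeled regions of a parcellation (fiber number, FN).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .volumes import ScalarVolume

_EPS = 1e-12


@dataclass
class Streamline:
    """Ordered points in continuous voxel coordinates plus length in mm."""

    points: np.ndarray
    length_mm: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")


@dataclass
class Connectome:
    """Symmetric fiber-number matrix over parcellation regions."""

    weights: np.ndarray
    region_labels: list[int]
    n_streamlines_total: int

    def __post_init__(self) -> None:
        W = np.asarray(self.weights)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.array_equal(W, W.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weights must have zero diagonal")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")

    def save(self, matrix_path: str, labels_path: str | None = None) -> None:
        np.savetxt(matrix_path, self.weights, fmt="%d", delimiter="\t")
        if labels_path:
            with open(labels_path, "w") as fh:
                fh.write("\n".join(str(r) for r in self.region_labels) + "\n")


def _half_track(
    seed: np.ndarray,
    d0: np.ndarray,
    eig: np.ndarray,
    fa: np.ndarray,
    fa_stop: float,
    cos_min: float,
    max_steps: int,
) -> list[np.ndarray]:
    """Track from a voxel center in one direction; returns the point list."""
    shape = fa.shape
    cur = np.floor(seed).astype(int)
    pos = seed.astype(float)
    d = d0.astype(float)
    pts = [pos.copy()]
    for _ in range(max_steps):
        # distance to the boundary of the current voxel along d, per axis
        t_best = math.inf
        axis = -1
        for a in range(3):
            if d[a] > _EPS:
                t = (cur[a] + 1.0 - pos[a]) / d[a]
            elif d[a] < -_EPS:
                t = (cur[a] - pos[a]) / d[a]
            else:
                continue
            if t < t_best - _EPS:
                t_best = t
                axis = a
        if axis < 0 or not math.isfinite(t_best):
            break
        pos = pos + t_best * d
        if t_best > _EPS:
            pts.append(pos.copy())
        nxt = cur.copy()
        nxt[axis] += 1 if d[axis] > 0 else -1
        if np.any(nxt < 0) or np.any(nxt >= shape):
            break
        if fa[tuple(nxt)] < fa_stop:
            break
        dn = eig[tuple(nxt)].astype(float)
        if float(dn @ d) < 0:
            dn = -dn
        if float(dn @ d) < cos_min:
            break  # turning angle above the maximum
        cur = nxt
        d = dn
    return pts


def fact_track(
    eigenfield: np.ndarray,
    fa: ScalarVolume,
    fa_stop: float = 0.2,
    angle_max_deg: float = 45.0,
    min_length_mm: float | None = None,
    seed_mask: np.ndarray | None = None,
) -> list[Streamline]:
    """Whole-volume deterministic FACT tractography.

    One seed per voxel center with FA >= ``fa_stop`` (optionally restricted
    by ``seed_mask``).  ``min_length_mm`` defaults to three voxel diagonals.
    Raises if a tracked voxel carries a non-unit eigenvector.
    """
    fa_data = fa.data
    vs = np.asarray(fa.voxel_size, dtype=float)
    if min_length_mm is None:
        min_length_mm = 3.0 * float(np.linalg.norm(vs))
    cos_min = math.cos(math.radians(angle_max_deg))
    seeds = fa_data >= fa_stop
    if seed_mask is not None:
        seeds = seeds & np.asarray(seed_mask, dtype=bool)

    norms = np.linalg.norm(eigenfield[seeds], axis=-1)
    if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
        bad = int(np.sum(np.abs(norms - 1.0) > 1e-6))
        raise ValueError(f"{bad} non-unit eigenvectors in tracked region")

    max_steps = int(4 * sum(fa_data.shape))
    out: list[Streamline] = []
    for v in np.argwhere(seeds):
        center = v + 0.5
        d0 = eigenfield[tuple(v)].astype(float)
        fwd = _half_track(center, d0, eigenfield, fa_data, fa_stop, cos_min, max_steps)
        bwd = _half_track(center, -d0, eigenfield, fa_data, fa_stop, cos_min, max_steps)
        pts = bwd[::-1] + fwd[1:]
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        length = float(np.linalg.norm(np.diff(arr, axis=0) * vs, axis=1).sum())
        if length < min_length_mm:
            continue
        out.append(Streamline(arr, length))
    return out


def build_connectome(
    streamlines: list[Streamline], labels: ScalarVolume
) -> Connectome:
    """FN-weighted connectome from streamline endpoints.

    A streamline increments weights[i, j] and weights[j, i] by one iff its
    two endpoints lie in distinct labeled regions i != j; endpoints in
    background (label 0) contribute nothing.
    """
    lab = np.asarray(labels.data).astype(int)
    n_regions = int(lab.max())
    if n_regions < 1:
        raise ValueError("parcellation contains no labeled regions")
    shape = np.asarray(lab.shape)
    W = np.zeros((n_regions, n_regions), dtype=int)
    for sl in streamlines:
        ends = np.clip(
            np.floor(sl.points[[0, -1]]).astype(int), 0, shape - 1
        )
        i = lab[tuple(ends[0])]
        j = lab[tuple(ends[1])]
        if i > 0 and j > 0 and i != j:
            W[i - 1, j - 1] += 1
            W[j - 1, i - 1] += 1
    return Connectome(W, list(range(1, n_regions + 1)), len(streamlines))


def save_streamlines_json(streamlines: list[Streamline], path: str) -> None:
    """Documented JSON serialization: list of {points, length_mm}."""
    payload = [
        {"points": sl.points.tolist(), "length_mm": sl.length_mm}
        for sl in streamlines
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_streamlines_json(path: str) -> list[Streamline]:
    with open(path) as fh:
        payload = json.load(fh)
    return [Streamline(np.asarray(d["points"]), d["length_mm"]) for d in payload]
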