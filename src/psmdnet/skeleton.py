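"""TBSS-style white-matter skeletonization and projection.

The skeleton is built once from the cohort mean FA by locating voxels that
are local maxima of mean FA along the direction perpendicular to the local
tract; every subject's maps are then projected onto the identical skeleton,
so all subjects contribute the same number of voxels to downstream
histograms.  The PSMD analysis mask (mean FA >= 0.3 minus a ventricle-style
exclusion set) is applied after projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .volumes import MAP_NAMES, ScalarVolume

# the 13 unique axis/diagonal directions of a 3x3x3 neighborhood
_DIRS13 = np.array(
    [
        d
        for d in (
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
        )
        if d != (0, 0, 0) and (d > (0, 0, 0))
    ],
    dtype=int,
)

_OFFSETS27 = np.array(
    [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)],
    dtype=float,
).reshape(3, 3, 3, 3)


@dataclass
class Skeleton:
    """Ordered skeleton voxels with perpendicular directions and mean FA."""

    voxels: np.ndarray  # (n, 3) int
    perp_dirs: np.ndarray  # (n, 3) unit float
    mean_fa: np.ndarray  # (n,)
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.voxels)

    def to_volume(self) -> ScalarVolume:
        """Label volume: skeleton voxels get 1-based order indices."""
        vol = np.zeros(self.grid_shape, dtype=int)
        if len(self.voxels):
            vol[tuple(self.voxels.T)] = np.arange(1, len(self.voxels) + 1)
        return ScalarVolume(vol, self.voxel_size)

    def save(self, nifti_path: str, sidecar_path: str) -> None:
        self.to_volume().save(nifti_path)
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "voxels": self.voxels.tolist(),
                    "perp_dirs": self.perp_dirs.tolist(),
                    "mean_fa": self.mean_fa.tolist(),
                    "grid_shape": list(self.grid_shape),
                    "voxel_size": list(self.voxel_size),
                },
                fh,
            )

    @classmethod
    def load(cls, sidecar_path: str) -> "Skeleton":
        with open(sidecar_path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["voxels"], dtype=int),
            np.asarray(d["perp_dirs"], dtype=float),
            np.asarray(d["mean_fa"], dtype=float),
            tuple(d["grid_shape"]),
            tuple(d["voxel_size"]),
        )


@dataclass
class SkeletonSample:
    """One subject's values along the skeleton for one scalar map."""

    subject_id: str
    map_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.map_name not in MAP_NAMES:
            raise ValueError(f"unknown map {self.map_name!r}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class AnalysisMask:
    """Boolean keep-vector over skeleton voxels (FA threshold + exclusion)."""

    keep: np.ndarray
    fa_threshold: float


def mean_fa(fa_volumes, subject_ids=None) -> ScalarVolume:
    """Voxelwise arithmetic mean of registered FA volumes."""
    fa_volumes = list(fa_volumes)
    if not fa_volumes:
        raise ValueError("need at least one FA volume")
    ref = fa_volumes[0]
    acc = np.zeros(ref.shape, dtype=float)
    for i, vol in enumerate(fa_volumes):
        if not vol.same_grid(ref):
            name = subject_ids[i] if subject_ids is not None else f"index {i}"
            raise ValueError(f"grid mismatch for subject {name}")
        acc += vol.data
    return ScalarVolume(acc / len(fa_volumes), ref.voxel_size)


def _perp_direction(pad: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Perpendicular-direction estimate at candidate voxel ``v``.

    FA-weighted center-of-gravity offset of the 3x3x3 neighborhood if its
    magnitude exceeds 0.1 voxel; otherwise the axis/diagonal direction of
    most negative second derivative of mean FA (normalized by |d|^2).
    """
    neigh = pad[v[0] : v[0] + 3, v[1] : v[1] + 3, v[2] : v[2] + 3]
    wsum = neigh.sum()
    if wsum > 0:
        cog = (neigh[..., None] * _OFFSETS27).sum(axis=(0, 1, 2)) / wsum
    else:  # pragma: no cover - candidates always have positive FA
        cog = np.zeros(3)
    norm = np.linalg.norm(cog)
    if norm > 0.1:
        return cog / norm
    center = pad[v[0] + 1, v[1] + 1, v[2] + 1]
    best = None
    best_val = np.inf
    for d in _DIRS13:
        plus = pad[v[0] + 1 + d[0], v[1] + 1 + d[1], v[2] + 1 + d[2]]
        minus = pad[v[0] + 1 - d[0], v[1] + 1 - d[1], v[2] + 1 - d[2]]
        val = (plus + minus - 2.0 * center) / float(d @ d)
        if val < best_val - 1e-15:
            best_val = val
            best = d
    return best / np.linalg.norm(best)


def build_skeleton(mean_fa_vol: ScalarVolume, skeleton_fa_min: float = 0.2) -> Skeleton:
    """Find the white-matter skeleton of a mean-FA volume.

    A candidate voxel (mean FA >= ``skeleton_fa_min``) is on the skeleton iff
    its FA is >= the FA of both neighbors along its perpendicular direction;
    exact ties keep the lexicographically smaller coordinate.  An empty
    candidate set yields an empty skeleton.
    """
    fa = np.asarray(mean_fa_vol.data, dtype=float)
    if not np.all(np.isfinite(fa)):
        raise ValueError("mean FA volume contains non-finite values")
    pad = np.pad(fa, 1)
    candidates = np.argwhere(fa >= skeleton_fa_min)

    kept_vox = []
    kept_dirs = []
    kept_fa = []
    for v in candidates:
        dirv = _perp_direction(pad, v)
        step = np.rint(dirv).astype(int)
        if not step.any():  # degenerate rounding; skip defensively
            continue
        fv = fa[tuple(v)]
        on_ridge = True
        for sgn in (1, -1):
            n = v + sgn * step
            fn = pad[n[0] + 1, n[1] + 1, n[2] + 1]
            if fv > fn:
                continue
            if fv == fn and tuple(v) < tuple(n):
                continue
            on_ridge = False
            break
        if on_ridge:
            kept_vox.append(v)
            kept_dirs.append(dirv)
            kept_fa.append(fv)

    if kept_vox:
        voxels = np.asarray(kept_vox, dtype=int)
        dirs = np.asarray(kept_dirs, dtype=float)
        fas = np.asarray(kept_fa, dtype=float)
    else:
        voxels = np.empty((0, 3), dtype=int)
        dirs = np.empty((0, 3), dtype=float)
        fas = np.empty(0, dtype=float)
    return Skeleton(voxels, dirs, fas, fa.shape, mean_fa_vol.voxel_size)


def project_to_skeleton(
    volumes: dict[str, ScalarVolume],
    skeleton: Skeleton,
    search_radius_vox: int = 8,
    subject_id: str = "subject",
) -> dict[str, SkeletonSample]:
    """Project a subject's FA/MD/AD/RD maps onto the skeleton.

    For each skeleton voxel the subject FA is searched along +/- the stored
    perpendicular direction up to ``search_radius_vox`` voxels (truncated at
    the grid boundary); the location of maximum subject FA supplies the FA
    sample, and MD/AD/RD are read at that same location (shared projection
    parameters).  Ties prefer the smaller offset, positive direction first.
    """
    for name in MAP_NAMES:
        if name not in volumes:
            raise ValueError(f"missing {name} volume")
    fa_vol = volumes["FA"]
    if fa_vol.shape != skeleton.grid_shape:
        raise ValueError("subject grid does not match skeleton grid")
    fa = fa_vol.data
    shape = np.asarray(skeleton.grid_shape)

    n = len(skeleton)
    picked = np.zeros((n, 3), dtype=int)
    for i in range(n):
        v = skeleton.voxels[i]
        d = skeleton.perp_dirs[i]
        best_fa = -np.inf
        best = v
        for t in range(0, search_radius_vox + 1):
            for sgn in (1, -1):
                if t == 0 and sgn == -1:
                    continue
                p = np.rint(v + sgn * t * d).astype(int)
                if np.any(p < 0) or np.any(p >= shape):
                    continue  # truncate at the boundary
                val = fa[tuple(p)]
                if val > best_fa:
                    best_fa = val
                    best = p
        picked[i] = best

    idx = tuple(picked.T) if n else (np.empty(0, int),) * 3
    out = {}
    for name in MAP_NAMES:
        vals = volumes[name].data[idx] if n else np.empty(0)
        out[name] = SkeletonSample(subject_id, name, vals)
    return out


def make_analysis_mask(
    skeleton: Skeleton,
    fa_threshold: float = 0.3,
    exclusion: np.ndarray | None = None,
) -> AnalysisMask:
    """Keep skeleton voxels with template mean FA >= threshold, outside the
    exclusion volume (a boolean array on the skeleton grid)."""
    keep = skeleton.mean_fa >= fa_threshold
    if exclusion is not None:
        excl = np.asarray(exclusion, dtype=bool)
        if excl.shape != tuple(skeleton.grid_shape):
            raise ValueError("exclusion mask grid does not match skeleton grid")
        if len(skeleton):
            keep = keep & ~excl[tuple(skeleton.voxels.T)]
    return AnalysisMask(keep=keep, fa_threshold=fa_threshold)


def apply_analysis_mask(
    values: np.ndarray | SkeletonSample,
    skeleton: Skeleton,
    fa_threshold: float = 0.3,
    exclusion: np.ndarray | None = None,
    mask: AnalysisMask | None = None,
) -> np.ndarray:
    """Return sample values at kept voxels only; error if nothing is kept."""
    vals = values.values if isinstance(values, SkeletonSample) else np.asarray(values)
    if len(vals) != len(skeleton):
        raise ValueError("sample is not aligned to the skeleton")
    if mask is None:
        mask = make_analysis_mask(skeleton, fa_threshold, exclusion)
    if not mask.keep.any():
        raise ValueError("empty analysis mask")
    return vals[mask.keep]
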