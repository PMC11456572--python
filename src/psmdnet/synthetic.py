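"""Synthetic diffusion phantoms and simulated cohorts.

The generator replaces scanner data end to end: it builds tract-like FA/MD
geometry with CSF-adjacent high-MD regions, principal-eigenvector fields for
deterministic tractography, a parcellation, and a cohort table whose clinical
scores are tied to the imaging metrics through a linear-Gaussian score model.

Two properties anchor everything downstream:

* Patients and controls differ in the *spatial heterogeneity* of skeleton MD
  (the quantity PSMD measures), not necessarily in mean MD.  The per-subject
  heterogeneity is a smooth 1-D Gaussian process along each tract arclength,
  exactly zero-meaned and peak-width-normalized over the centerline, so the
  subject's downstream PSMD equals its latent value by construction.
* With every effect multiplier at 1 the two groups are exchangeable.

Default magnitudes (group means/SDs of PSMD, Eg, lambda, demographics and
clinical scores) are calibrated to a first-episode schizophrenia case-control
study of 56 patients and 64 controls; they are conditions of the simulation,
not fitted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter1d
from scipy.spatial import cKDTree

from .volumes import MAP_NAMES, ScalarVolume

# -- calibration constants (group-level study conditions) --------------------
PSMD_CONTROL = 1.67e-4  # mm^2/s
PSMD_PATIENT = 1.76e-4
EG_CONTROL = 12.76
EG_PATIENT = 12.07
LAMBDA_CONTROL = 1.18
LAMBDA_PATIENT = 1.20

MCCB_SCORES = ("SOP", "AV", "WM", "Vrbl_Lrng", "Vis_Lrng", "RPS", "SC")
PANSS_SCORES = ("PANSS_pos", "PANSS_neg", "PANSS_gen", "PANSS_total")
SCORE_NAMES = MCCB_SCORES + PANSS_SCORES

_LATENT_METRICS = ("psmd", "eg", "lambda")
_COVARIATES = ("age", "sex", "education", "tiv")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class TractSpec:
    """A tube-shaped white-matter tract.

    The tract is a parametric centerline (>= 2 points, mm coordinates) swept
    by a disk of the given radius.  FA decays radially from ``fa_peak`` at
    the centerline, either as a Gaussian ``fa_peak * exp(-d^2 / (2 s^2))``
    with scale ``s`` (mm) or as a flat plateau.  The principal eigenvector is
    the centerline tangent.
    """

    centerline: np.ndarray
    radius: float
    fa_peak: float = 0.7
    fa_profile: tuple = ("gaussian", 3.0)
    md_core: float = 7.8e-4

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (K, 3) array of mm points")
        if self.centerline.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if not self.radius > 0:
            raise ValueError(f"tract radius must be positive, got {self.radius}")
        if not 0.0 < self.fa_peak < 1.0:
            raise ValueError(f"fa_peak must be in (0, 1), got {self.fa_peak}")
        if self.md_core <= 0:
            raise ValueError("md_core must be positive")
        kind = self.fa_profile[0]
        if kind not in ("gaussian", "flat"):
            raise ValueError(f"unknown fa_profile {kind!r}")
        if kind == "gaussian" and not self.fa_profile[1] > 0:
            raise ValueError("gaussian profile scale must be positive")

    def radial_fa(self, dist: np.ndarray) -> np.ndarray:
        if self.fa_profile[0] == "flat":
            return np.full_like(dist, self.fa_peak, dtype=float)
        scale = float(self.fa_profile[1])
        return self.fa_peak * np.exp(-0.5 * (dist / scale) ** 2)


@dataclass
class CSFRegion:
    """A box or ellipsoid of CSF-like high mean diffusivity."""

    center: tuple[float, float, float]
    half_axes: tuple[float, float, float]
    md: float = 3.0e-3
    kind: str = "box"

    def __post_init__(self) -> None:
        if self.md <= 0:
            raise ValueError("CSF MD level must be positive")
        if self.kind not in ("box", "ellipsoid"):
            raise ValueError(f"unknown CSF region kind {self.kind!r}")

    def mask(self, centers_mm: np.ndarray) -> np.ndarray:
        rel = (centers_mm - np.asarray(self.center)) / np.asarray(self.half_axes)
        if self.kind == "box":
            return np.all(np.abs(rel) <= 1.0, axis=-1)
        return np.sum(rel**2, axis=-1) <= 1.0


def default_tract_network(
    box_mm: float = 64.0, radius: float = 3.0, fa_peak: float = 0.7
) -> tuple[list[TractSpec], np.ndarray]:
    """A small 6-node tube network filling a cubic FOV.

    Returns the tract list and the (6, 3) node positions in mm.  The network
    has triangles and non-constant node degree so every global topology
    metric (clustering, hierarchy, assortativity) is defined on the
    resulting connectome.
    """
    s = box_mm / 64.0
    nodes = np.array(
        [
            [14, 14, 26],
            [14, 46, 26],
            [46, 46, 26],
            [46, 14, 26],
            [46, 14, 48],
            [46, 46, 48],
        ],
        dtype=float,
    ) * s
    # two triangles sharing the hub (node 2) plus a tail: clustered nodes
    # span degrees 2..4, so hierarchy/assortativity are defined downstream
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (2, 3), (3, 4), (4, 5), (2, 5)]
    tracts = []
    for i, j in edges:
        line = np.linspace(nodes[i], nodes[j], 9)
        tracts.append(
            TractSpec(line, radius=radius * s, fa_peak=fa_peak,
                      fa_profile=("gaussian", radius * s))
        )
    return tracts, nodes


@dataclass
class PhantomConfig:
    """Geometry and noise of one synthetic subject volume set."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tracts: list[TractSpec] = field(default_factory=lambda: default_tract_network()[0])
    csf_regions: list[CSFRegion] = field(
        default_factory=lambda: [CSFRegion((10.0, 30.0, 54.0), (6.0, 6.0, 6.0))]
    )
    noise_sd_fa: float = 0.02
    noise_sd_md: float = 2.0e-6
    background_md: float = 7.0e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(g < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 16, got {self.grid_shape}")
        if self.noise_sd_fa < 0 or self.noise_sd_md < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.background_md <= 0:
            raise ValueError("background_md must be positive")

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size)


@dataclass
class SubjectData:
    """Per-subject volumes, eigenvector field, covariates and scores."""

    subject_id: str
    group: str
    volumes: dict[str, ScalarVolume]
    eigenfield: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    csf_mask: np.ndarray | None = None
    tract_mask: np.ndarray | None = None

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.volumes["FA"].voxel_size


# ---------------------------------------------------------------------------
# phantom rasterization
# ---------------------------------------------------------------------------


class _Raster:
    """Noise-free rasterization of a PhantomConfig, reusable across subjects."""

    def __init__(self, config: PhantomConfig):
        shape = config.grid_shape
        vs = np.asarray(config.voxel_size)
        idx = np.indices(shape).reshape(3, -1).T
        centers = (idx + 0.5) * vs  # mm

        fa = np.zeros(len(centers))
        md = np.full(len(centers), config.background_md)
        eig = np.zeros((len(centers), 3))
        tract_id = np.full(len(centers), -1, dtype=int)
        arc_index = np.zeros(len(centers), dtype=int)  # dense sample index
        self.dense_points: list[np.ndarray] = []
        self.dense_tangents: list[np.ndarray] = []

        fov = config.fov_mm
        step = float(min(config.voxel_size)) / 2.0
        for t, tract in enumerate(config.tracts):
            pts, tans = _densify(tract.centerline, step)
            if np.any(pts < 0) or np.any(pts > fov):
                raise ValueError(
                    f"tract {t} centerline leaves the grid (FOV {fov.tolist()} mm)"
                )
            self.dense_points.append(pts)
            self.dense_tangents.append(tans)
            d, nearest = cKDTree(pts).query(centers)
            inside = d <= tract.radius
            fa_t = tract.radial_fa(d)
            take = inside & (fa_t > fa)
            fa[take] = fa_t[take]
            md[take] = tract.md_core
            eig[take] = tans[nearest[take]]
            tract_id[take] = t
            arc_index[take] = nearest[take]

        csf = np.zeros(len(centers), dtype=bool)
        for region in config.csf_regions:
            m = region.mask(centers)
            csf |= m
            fa[m] = 0.02
            md[m] = region.md
            eig[m] = 0.0
            tract_id[m] = -1

        self.shape = shape
        self.fa0 = fa.reshape(shape)
        self.md0 = md.reshape(shape)
        self.eig = eig.reshape(shape + (3,))
        self.tract_id = tract_id.reshape(shape)
        self.arc_index = arc_index.reshape(shape)
        self.csf_mask = csf.reshape(shape)
        self.tract_mask = self.tract_id >= 0
        self.dense_counts = [len(p) for p in self.dense_points]
        # one dense-sample index per centerline voxel, per tract: the set a
        # thin skeleton will sample, used to normalize heterogeneity fields
        self.centerline_arc_idx: list[np.ndarray] = []
        for t, pts in enumerate(self.dense_points):
            vox = np.floor(pts / vs).astype(int)
            vox = np.clip(vox, 0, np.asarray(shape) - 1)
            _, first = np.unique(vox, axis=0, return_index=True)
            self.centerline_arc_idx.append(np.sort(first))

    def offset_volume(self, line_fields: Sequence[np.ndarray]) -> np.ndarray:
        """Map per-tract arclength fields onto the voxel grid (0 elsewhere)."""
        out = np.zeros(self.shape)
        for t, values in enumerate(line_fields):
            if len(values) != self.dense_counts[t]:
                raise ValueError("line field length mismatch")
            sel = self.tract_id == t
            out[sel] = np.asarray(values)[self.arc_index[sel]]
        return out


def _densify(centerline: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~`step` mm spacing; return points and tangents."""
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arcs[-1]
    if total <= 0:
        raise ValueError("centerline has zero length")
    n = max(int(math.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    pts = np.column_stack(
        [np.interp(s, arcs, centerline[:, a]) for a in range(3)]
    )
    # tangent of the segment each sample falls in
    seg_idx = np.clip(np.searchsorted(arcs, s, side="right") - 1, 0, len(seg) - 1)
    tans = seg[seg_idx] / seg_len[seg_idx, None]
    return pts, tans


def _eigenvalues_from_fa_md(fa: np.ndarray, md: np.ndarray):
    """Axially symmetric tensor eigenvalues matching given FA and MD.

    delta = FA / sqrt(3 - 2 FA^2) gives AD = MD (1 + 2 delta) and
    RD = MD (1 - delta), which reproduces both FA and the trace identity
    MD = (AD + 2 RD) / 3 exactly.
    """
    fa = np.clip(fa, 0.0, 0.999)
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    ad = md * (1.0 + 2.0 * delta)
    rd = md * (1.0 - delta)
    return ad, rd


def generate_phantom(
    config: PhantomConfig,
    md_offset: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    _raster: _Raster | None = None,
    subject_id: str = "phantom",
    group: str = "control",
) -> SubjectData:
    """Generate one subject's FA/MD/AD/RD volumes and eigenvector field.

    ``md_offset`` is an optional additive MD field (mm^2/s) applied before
    noise; the cohort generator uses it to inject controlled heterogeneity.
    Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    raster = _raster if _raster is not None else _Raster(config)
    rng = np.random.default_rng(config.seed) if rng is None else rng

    fa = raster.fa0.copy()
    md = raster.md0.copy()
    if md_offset is not None:
        md = md + md_offset
    if config.noise_sd_fa > 0:
        fa = fa + rng.normal(0.0, config.noise_sd_fa, size=fa.shape)
    if config.noise_sd_md > 0:
        md = md + rng.normal(0.0, config.noise_sd_md, size=md.shape)
    fa = np.clip(fa, 0.0, 0.99)
    md = np.clip(md, 1e-6, None)
    ad, rd = _eigenvalues_from_fa_md(fa, md)

    vs = config.voxel_size
    volumes = {
        "FA": ScalarVolume(fa, vs),
        "MD": ScalarVolume(md, vs),
        "AD": ScalarVolume(ad, vs),
        "RD": ScalarVolume(rd, vs),
    }
    return SubjectData(
        subject_id=subject_id,
        group=group,
        volumes=volumes,
        eigenfield=raster.eig.copy(),
        csf_mask=raster.csf_mask.copy(),
        tract_mask=raster.tract_mask.copy(),
    )


def centerline_voxels(config: PhantomConfig) -> np.ndarray:
    """Unique voxel indices traversed by the tract centerlines (ground truth)."""
    vs = np.asarray(config.voxel_size)
    step = float(min(config.voxel_size)) / 4.0
    out = []
    for tract in config.tracts:
        pts, _ = _densify(tract.centerline, step)
        out.append(np.floor(pts / vs).astype(int))
    vox = np.vstack(out)
    vox = np.clip(vox, 0, np.asarray(config.grid_shape) - 1)
    return np.unique(vox, axis=0)


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------


def generate_parcellation(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed_points: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> ScalarVolume:
    """Voronoi parcellation: labels 1..n_regions tile the brain mask.

    Region seed voxels are drawn uniformly (seeded) unless ``seed_points``
    (voxel coordinates, one per region) are given — e.g. tract endpoints.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    grid_shape = tuple(int(g) for g in grid_shape)
    if brain_mask is None:
        brain_mask = np.ones(grid_shape, dtype=bool)
    n_vox = int(brain_mask.sum())
    if n_regions > n_vox:
        raise ValueError(f"more regions ({n_regions}) than voxels ({n_vox})")

    coords = np.argwhere(brain_mask)
    if seed_points is None:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(coords), size=n_regions, replace=False)
        seeds = coords[pick]
    else:
        seeds = np.asarray(seed_points, dtype=int)
        if len(seeds) != n_regions:
            raise ValueError("seed_points must supply one voxel per region")

    _, lab = cKDTree(seeds.astype(float)).query(coords.astype(float))
    labels = np.zeros(grid_shape, dtype=int)
    labels[tuple(coords.T)] = lab + 1
    return ScalarVolume(labels, voxel_size)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def default_score_model() -> dict:
    """Linear-Gaussian clinical score model.

    Each score: value = mean + group_shift[patient] + sum(loading_m * z_m)
    + sum(cov_loading_c * z_c) + noise, all in raw score units; ``z_m`` are
    latent imaging metrics standardized by their population mean/SD and
    ``z_c`` standardized covariates.  The reasoning/problem-solving score
    (RPS) carries the negative PSMD and lambda loadings; Eg loads zero.
    PANSS scales exist for patients only and load on nothing.
    """
    mccb = {
        #            mean    sd    patient shift
        "SOP": (40.42, 10.05, -11.90),
        "AV": (46.58, 12.24, -15.10),
        "WM": (46.10, 6.71, -5.55),
        "Vrbl_Lrng": (41.07, 10.34, -6.55),
        "Vis_Lrng": (44.67, 9.99, -4.84),
        "RPS": (36.68, 7.12, 0.0),  # deficit arrives through PSMD/lambda
        "SC": (43.77, 9.47, -3.25),
    }
    model: dict[str, dict] = {}
    for name, (mean, sd, shift) in mccb.items():
        model[name] = {
            "mean": mean,
            "sd": sd,
            "group_shift": shift,
            "loadings": {},
            "cov_loadings": {"education": 0.15 * sd},
            "noise_sd": sd,
            "patients_only": False,
        }
    rps = model["RPS"]
    rps["loadings"] = {"psmd": -0.426 * rps["sd"], "lambda": -0.490 * rps["sd"]}
    rps["noise_sd"] = rps["sd"] * math.sqrt(max(1.0 - 0.426**2 - 0.490**2, 0.05))
    panss = {
        "PANSS_pos": (23.51, 5.13),
        "PANSS_neg": (22.55, 6.01),
        "PANSS_gen": (41.16, 8.05),
    }
    for name, (mean, sd) in panss.items():
        model[name] = {
            "mean": mean,
            "sd": sd,
            "group_shift": 0.0,
            "loadings": {},
            "cov_loadings": {},
            "noise_sd": sd,
            "patients_only": True,
            "shared_factor": 0.774,  # inter-scale correlation ~0.6
        }
    return model


def default_covariate_dists() -> dict:
    return {
        "age": {"mean": 20.9, "sd": 5.6, "min": 14.0},
        "sex": {"p_male": 49.0 / 120.0},  # coded 1 = male, 0 = female
        "education": {"mean": 11.1, "sd": 2.8, "min": 5.0},
        "tiv": {"mean": 1566.0, "sd": 137.0, "min": 1100.0},  # cm^3
    }


@dataclass
class CohortConfig:
    """Cohort sizes, group effects, covariate and score models."""

    n_patients: int = 56
    n_controls: int = 64
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    # multiplicative group effects (1 = null)
    psmd_effect: float = PSMD_PATIENT / PSMD_CONTROL
    lambda_effect: float = LAMBDA_PATIENT / LAMBDA_CONTROL
    eg_effect: float = EG_PATIENT / EG_CONTROL
    # latent metric population parameters (controls)
    psmd_base: float = PSMD_CONTROL
    psmd_subject_cv: float = 0.07
    eg_base: float = EG_CONTROL
    eg_subject_cv: float = 1.82 / 12.76
    lambda_base: float = LAMBDA_CONTROL
    lambda_subject_cv: float = 0.05 / 1.18
    # spatial scale of the MD heterogeneity field (exposed knob)
    perturb_corr_mm: float = 4.0
    # per-subject, per-tract caliber variability (lognormal CV)
    radius_jitter_cv: float = 0.12
    covariate_dists: dict = field(default_factory=default_covariate_dists)
    score_model: dict = field(default_factory=default_score_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("cohort counts must be >= 0")
        for name in ("psmd_effect", "lambda_effect", "eg_effect"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.perturb_corr_mm <= 0:
            raise ValueError("perturb_corr_mm must be positive")
        for score, spec in self.score_model.items():
            for m in spec.get("loadings", {}):
                if m not in _LATENT_METRICS:
                    raise ValueError(
                        f"score {score!r} references unknown metric {m!r}"
                    )
            for c in spec.get("cov_loadings", {}):
                if c not in _COVARIATES:
                    raise ValueError(
                        f"score {score!r} references unknown covariate {c!r}"
                    )
            if spec.get("noise_sd", 0.0) < 0:
                raise ValueError("score noise_sd must be >= 0")


@dataclass
class CohortData:
    subjects: list[SubjectData]
    table: pd.DataFrame
    parcellation: ScalarVolume | None
    node_points: np.ndarray | None = None


def _draw_covariates(rng: np.random.Generator, dists: dict) -> dict[str, float]:
    age = max(rng.normal(dists["age"]["mean"], dists["age"]["sd"]), dists["age"]["min"])
    sex = float(rng.random() < dists["sex"]["p_male"])
    edu = max(
        rng.normal(dists["education"]["mean"], dists["education"]["sd"]),
        dists["education"]["min"],
    )
    tiv = max(rng.normal(dists["tiv"]["mean"], dists["tiv"]["sd"]), dists["tiv"]["min"])
    return {"age": age, "sex": sex, "education": edu, "tiv": tiv}


def _latent_metrics(rng: np.random.Generator, cfg: CohortConfig, patient: bool) -> dict:
    psmd = cfg.psmd_base * math.exp(rng.normal(0.0, cfg.psmd_subject_cv))
    eg = cfg.eg_base * (1.0 + rng.normal(0.0, cfg.eg_subject_cv))
    lam = cfg.lambda_base * (1.0 + rng.normal(0.0, cfg.lambda_subject_cv))
    if patient:
        psmd *= cfg.psmd_effect
        eg *= cfg.eg_effect
        lam *= cfg.lambda_effect
    return {"psmd": psmd, "eg": max(eg, 0.1), "lambda": max(lam, 0.5)}


def _score_z_scales(cfg: CohortConfig) -> dict:
    """Population mean/SD used to standardize latent metrics in scores."""
    return {
        "psmd": (cfg.psmd_base, cfg.psmd_base * cfg.psmd_subject_cv),
        "eg": (cfg.eg_base, cfg.eg_base * cfg.eg_subject_cv),
        "lambda": (cfg.lambda_base, cfg.lambda_base * cfg.lambda_subject_cv),
    }


_COV_SCALES = {"age": (20.9, 5.6), "sex": (0.41, 0.49), "education": (11.1, 2.8),
               "tiv": (1566.0, 137.0)}


def _draw_scores(
    rng: np.random.Generator,
    cfg: CohortConfig,
    latent: dict,
    covariates: dict,
    patient: bool,
) -> dict[str, float]:
    zs = _score_z_scales(cfg)
    out: dict[str, float] = {}
    shared = rng.normal()  # common factor for PANSS inter-scale correlation
    for name, spec in cfg.score_model.items():
        if spec.get("patients_only") and not patient:
            out[name] = float("nan")
            # burn the same number of draws so controls/patients stay aligned
            rng.normal()
            continue
        val = spec["mean"]
        if patient:
            val += spec.get("group_shift", 0.0)
        for m, coef in spec.get("loadings", {}).items():
            mu, sd = zs[m]
            val += coef * (latent[m] - mu) / sd
        for c, coef in spec.get("cov_loadings", {}).items():
            mu, sd = _COV_SCALES[c]
            val += coef * (covariates[c] - mu) / sd
        a = spec.get("shared_factor", 0.0)
        noise = rng.normal(0.0, spec["noise_sd"])
        if a:
            val += a * shared * spec["sd"] + math.sqrt(max(1 - a**2, 0.0)) * noise
        else:
            val += noise
        out[name] = float(val)
    if patient and all(k in out for k in ("PANSS_pos", "PANSS_neg", "PANSS_gen")):
        out["PANSS_total"] = out["PANSS_pos"] + out["PANSS_neg"] + out["PANSS_gen"]
    else:
        out["PANSS_total"] = float("nan")
    return out


def _heterogeneity_field(
    rng: np.random.Generator, raster: _Raster, corr_mm: float, step_mm: float,
    width: float
) -> list[np.ndarray]:
    """Smooth zero-mean arclength fields whose skeleton-level q95-q5 is `width`.

    Each tract carries a random-phase harmonic field along its arclength,
    wavelength ``4 * corr_mm``.  The bounded (arcsine-like) marginal makes
    the 5th/95th percentiles insensitive to how densely the skeleton samples
    the tract, so the peak width measured downstream matches the latent
    value without further adjustment.  Normalization (zero mean, exact
    width) is computed over one sample per centerline voxel — the set a
    thin skeleton measures.
    """
    wavelength = 4.0 * corr_mm
    fields = []
    for n in raster.dense_counts:
        s = np.arange(n) * step_mm
        phase = rng.uniform(0.0, 2.0 * np.pi)
        fields.append(np.sin(2.0 * np.pi * s / wavelength + phase))
    seen = np.concatenate(
        [fields[t][idx] for t, idx in enumerate(raster.centerline_arc_idx)]
    )
    if seen.size < 2:
        raise RuntimeError("tracts cover too few voxels for a heterogeneity field")
    mean = seen.mean()
    w0 = np.percentile(seen, 95) - np.percentile(seen, 5)
    if w0 <= 0:
        raise RuntimeError("degenerate heterogeneity field")
    scale = width / w0
    return [(f - mean) * scale for f in fields]


def generate_cohort(config: CohortConfig, make_volumes: bool = True) -> CohortData:
    """Generate a cohort of subjects plus the cohort table.

    With ``make_volumes=False`` only the latent metric columns, covariates
    and scores are produced (fast path for statistical simulations); the
    subject list is then empty and no parcellation is built.
    """
    n_total = config.n_patients + config.n_controls
    if n_total == 0:
        raise ValueError("cohort must contain at least one subject")

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(n_total + 1)
    rows = []
    subjects: list[SubjectData] = []

    parcellation = None
    node_points = None
    if make_volumes:
        endpoints_mm = np.array(
            [t.centerline[k] for t in config.phantom.tracts for k in (0, -1)]
        )
        node_points = np.unique(
            np.floor(endpoints_mm / np.asarray(config.phantom.voxel_size)).astype(int),
            axis=0,
        )
        node_points = np.clip(
            node_points, 0, np.asarray(config.phantom.grid_shape) - 1
        )
        parcellation = generate_parcellation(
            config.phantom.grid_shape,
            len(node_points),
            seed=config.seed,
            voxel_size=config.phantom.voxel_size,
            seed_points=node_points,
        )

    step_mm = float(min(config.phantom.voxel_size)) / 2.0
    for i in range(n_total):
        patient = i < config.n_patients
        group = "patient" if patient else "control"
        sid = f"sub-{i:03d}"
        rng = np.random.default_rng(child_seeds[i])
        covariates = _draw_covariates(rng, config.covariate_dists)
        latent = _latent_metrics(rng, config, patient)
        scores = _draw_scores(rng, config, latent, covariates, patient)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                **covariates,
                "gen_psmd": latent["psmd"],
                "gen_eg": latent["eg"],
                "gen_lambda": latent["lambda"],
                **scores,
            }
        )
        if make_volumes:
            # subject geometry: per-tract caliber jitter; patients suffer
            # focal tract damage (severe thinning) with probability
            # 1 - eg_effect per tract.  A uniform caliber change would cancel
            # in the weight normalization; focal heterogeneity is what moves
            # weighted efficiency, mirroring disease-like network damage.
            factors = np.exp(rng.normal(0.0, config.radius_jitter_cv,
                                        size=len(config.phantom.tracts)))
            factors = np.clip(factors, 0.5, 1.5)
            damaged = rng.random(len(factors)) < (1.0 - config.eg_effect)
            if patient:
                factors = np.where(damaged, factors * 0.35, factors)
            tracts = [
                TractSpec(
                    t.centerline, t.radius * f, t.fa_peak,
                    (t.fa_profile[0], t.fa_profile[1] * f)
                    if t.fa_profile[0] == "gaussian" else t.fa_profile,
                    t.md_core,
                )
                for t, f in zip(config.phantom.tracts, factors)
            ]
            subj_cfg = PhantomConfig(
                config.phantom.grid_shape, config.phantom.voxel_size, tracts,
                config.phantom.csf_regions, config.phantom.noise_sd_fa,
                config.phantom.noise_sd_md, config.phantom.background_md,
                config.phantom.seed,
            )
            ras = _Raster(subj_cfg)
            fields = _heterogeneity_field(
                rng, ras, config.perturb_corr_mm, step_mm, latent["psmd"]
            )
            md_offset = ras.offset_volume(fields)
            subj = generate_phantom(
                subj_cfg,
                md_offset=md_offset,
                rng=rng,
                _raster=ras,
                subject_id=sid,
                group=group,
            )
            subj.covariates = covariates
            subj.scores = scores
            subjects.append(subj)

    table = pd.DataFrame(rows)
    return CohortData(subjects, table, parcellation, node_points)


def exclusion_from_csf(csf_mask: np.ndarray, dilate: int = 1) -> np.ndarray:
    """Ventricle-style exclusion mask: CSF regions dilated by ``dilate`` voxels."""
    if dilate <= 0:
        return csf_mask.astype(bool)
    return binary_dilation(csf_mask.astype(bool), iterations=dilate)
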