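"""Peak-width and average statistics over masked skeleton values.

PSMD and its siblings (PSFA/PSAD/PSRD) are the differences between the 95th
and 5th percentiles of the skeletonized, masked scalar values; the
skeletonized averages are plain means over the same voxels.  Quantiles use
linear interpolation (the "type 7" convention); the choice is recorded in
output metadata by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import AnalysisMask, Skeleton, SkeletonSample, apply_analysis_mask
from .volumes import MAP_NAMES

#: metric-name -> (source map, output scale note)
PEAK_WIDTH_NAMES = {"FA": "PSFA", "MD": "PSMD", "AD": "PSAD", "RD": "PSRD"}
AVERAGE_NAMES = {"FA": "avg_FA", "MD": "avg_MD", "AD": "avg_AD", "RD": "avg_RD"}


@dataclass
class DiffusionMetrics:
    """Per-subject peak-width and skeletonized-average diffusion metrics.

    Diffusivity-derived values (PSMD/PSAD/PSRD, avg_MD/AD/RD) are stored in
    mm^2/s; FA-derived ones are unitless.  ``n_voxels`` counts the masked
    skeleton voxels entering every statistic.
    """

    subject_id: str
    PSMD: float
    PSFA: float
    PSAD: float
    PSRD: float
    avg_MD: float
    avg_FA: float
    avg_AD: float
    avg_RD: float
    n_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "PSMD": self.PSMD, "PSFA": self.PSFA, "PSAD": self.PSAD,
            "PSRD": self.PSRD, "avg_MD": self.avg_MD, "avg_FA": self.avg_FA,
            "avg_AD": self.avg_AD, "avg_RD": self.avg_RD,
            "n_voxels": self.n_voxels,
        }


def peak_width(values: np.ndarray, lo_pct: float = 5.0, hi_pct: float = 95.0) -> float:
    """quantile(hi) - quantile(lo) with linear-interpolation quantiles.

    Translation-invariant and scale-equivariant; >= 0 always.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if not 0.0 <= lo_pct < hi_pct <= 100.0:
        raise ValueError(f"need 0 <= lo < hi <= 100, got ({lo_pct}, {hi_pct})")
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        raise ValueError(f"input contains {n_nan} NaN values")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    if values.size < 2:
        raise ValueError(f"need at least 2 values, got {values.size}")
    hi, lo = np.percentile(values, [hi_pct, lo_pct])
    return float(hi - lo)


def skeleton_average(values: np.ndarray) -> float:
    """Arithmetic mean of the masked skeleton values."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    return float(values.mean())


def compute_subject_metrics(
    samples: dict[str, SkeletonSample],
    skeleton: Skeleton,
    mask: AnalysisMask,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> DiffusionMetrics:
    """Peak widths and skeletonized averages of all four maps under one mask."""
    masked = {
        name: apply_analysis_mask(samples[name], skeleton, mask=mask)
        for name in MAP_NAMES
    }
    sid = samples["MD"].subject_id
    widths = {name: peak_width(masked[name], lo_pct, hi_pct) for name in MAP_NAMES}
    avgs = {name: skeleton_average(masked[name]) for name in MAP_NAMES}
    return DiffusionMetrics(
        subject_id=sid,
        PSMD=widths["MD"], PSFA=widths["FA"], PSAD=widths["AD"], PSRD=widths["RD"],
        avg_MD=avgs["MD"], avg_FA=avgs["FA"], avg_AD=avgs["AD"], avg_RD=avgs["RD"],
        n_voxels=int(mask.keep.sum()),
    )
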