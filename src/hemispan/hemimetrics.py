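"""Voxel-level hemispheric metrics: Autonomy Index (AI) and CFH.

AI measures functional specialization.  For voxel ``v`` with whole-brain
functional connectivity (Pearson correlation of time series),

    AI(v) = Ni / Hi - Nc / Hc

where ``Ni``/``Nc`` count significantly connected voxels in the
ipsilateral / contralateral hemisphere and ``Hi``/``Hc`` are the
hemisphere voxel totals.  The self-voxel is excluded from both ``Ni`` and
``Hi`` so that the ratio stays well defined and symmetric.

CFH (connectivity between functionally homotopic voxels) measures
interhemispheric coordination: for each voxel the *functionally* homotopic
voxel is the contralateral voxel with the highest functional connectivity,
and CFH is the correlation with it.  Because connectivity is itself the
Pearson correlation, CFH equals the maximum contralateral correlation; the
argmax partner is retained.

"Significantly connected" is not pinned down by common usage, so the AI
threshold is configurable: by default the positive critical Pearson r for
two-tailed p < 0.05 at the series length; an absolute-r variant counts
strong negative correlations as connected too.

Raw maps are normalized across the whole brain before group comparison:
CFH values pass through the Fisher r-to-z transform (variance
stabilization for correlations), then both metrics are z-scored over the
mask (mean 0, SD 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .volume import LEFT, RIGHT, BoldVolume4D

_FISHER_CLIP = 1.0 - 1e-12


@dataclass
class MetricMap:
    """Per-voxel scalar map (AI or CFH).

    ``values`` follows the voxel order of the :class:`BoldVolume4D` it was
    computed from.  ``normalized`` flags whether whole-brain normalization
    has been applied; raw AI and CFH values lie in [-1, 1].
    """

    values: np.ndarray
    metric: str
    normalized: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in ("AI", "CFH"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if not self.normalized and self.values.size:
            lo, hi = np.nanmin(self.values), np.nanmax(self.values)
            if lo < -1 - 1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"raw {self.metric} values outside [-1, 1]")


def _standardized(series: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean and unit norm, so Z @ Z.T is the correlation."""
    z = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-variance time series at voxel row(s) {bad[:5].tolist()}")
    return z / norms[:, None]


def critical_r(n_timepoints: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson r for a series of given length."""
    df = n_timepoints - 2
    if df <= 0:
        raise ValueError("need at least 3 timepoints")
    tc = stats.t.isf(alpha / 2.0, df)
    return float(tc / np.sqrt(df + tc**2))


def fc_vector(vol: BoldVolume4D, voxel: int) -> np.ndarray:
    """Whole-brain functional connectivity of one voxel (self-entry = 1)."""
    z = _standardized(vol.series)
    r = z @ z[voxel]
    r[voxel] = 1.0
    return np.clip(r, -1.0, 1.0)


def compute_ai(
    vol: BoldVolume4D,
    sig_threshold: float | None = None,
    alpha: float = 0.05,
    use_absolute: bool = False,
    exclude_self: bool = True,
    chunk: int = 512,
) -> MetricMap:
    """Autonomy Index map.

    Parameters
    ----------
    sig_threshold : float, optional
        Correlation above which a pair counts as "significantly connected".
        Defaults to the positive critical r for two-tailed p < ``alpha`` at
        the series length.
    use_absolute : bool
        Count ``|r| > threshold`` instead of ``r > threshold``.
    """
    if sig_threshold is None:
        sig_threshold = critical_r(vol.n_timepoints, alpha)
    if not 0.0 < sig_threshold < 1.0:
        raise ValueError("sig_threshold must lie in (0, 1)")
    left = vol.hemilabel == LEFT
    right = vol.hemilabel == RIGHT
    if not left.any() or not right.any():
        raise ValueError("both hemispheres must be nonempty")

    z = _standardized(vol.series)
    n = vol.n_voxels
    n_left, n_right = int(left.sum()), int(right.sum())
    same_count = np.where(left, n_left, n_right).astype(float)
    ai = np.empty(n)
    left_f = left.astype(float)
    right_f = right.astype(float)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        r = z[sl] @ z.T
        conn = (np.abs(r) if use_absolute else r) > sig_threshold
        diag = (np.arange(sl.stop - sl.start), np.arange(start, sl.stop))
        # self-correlation is exactly 1: counted only when the self-pair
        # convention keeps it (exclude_self=False)
        conn[diag] = not exclude_self
        with_left = conn @ left_f
        with_right = conn @ right_f
        is_left = left[sl]
        ni = np.where(is_left, with_left, with_right)
        nc = np.where(is_left, with_right, with_left)
        hi = same_count[sl] - (1.0 if exclude_self else 0.0)
        hc = np.where(is_left, n_right, n_left).astype(float)
        ai[sl] = ni / hi - nc / hc
    return MetricMap(
        values=ai,
        metric="AI",
        params={
            "sig_threshold": float(sig_threshold),
            "use_absolute": bool(use_absolute),
            "exclude_self": bool(exclude_self),
        },
    )


def compute_cfh(vol: BoldVolume4D) -> tuple[MetricMap, np.ndarray]:
    """CFH map plus the per-voxel functionally homotopic partner index.

    Ties in the contralateral maximum break to the smallest voxel index.
    """
    left_idx = vol.hemisphere_indices(LEFT)
    right_idx = vol.hemisphere_indices(RIGHT)
    if left_idx.size == 0 or right_idx.size == 0:
        raise ValueError("both hemispheres must be nonempty")
    z = _standardized(vol.series)
    cross = np.clip(z[left_idx] @ z[right_idx].T, -1.0, 1.0)
    cfh = np.empty(vol.n_voxels)
    partner = np.empty(vol.n_voxels, dtype=int)
    # np.argmax returns the first maximum; hemisphere indices ascend, so the
    # first maximum is the smallest voxel index.
    cfh[left_idx] = cross.max(axis=1)
    partner[left_idx] = right_idx[np.argmax(cross, axis=1)]
    cfh[right_idx] = cross.max(axis=0)
    partner[right_idx] = left_idx[np.argmax(cross, axis=0)]
    return MetricMap(values=cfh, metric="CFH", params={}), partner


def normalize_map(m: MetricMap) -> MetricMap:
    """Whole-brain normalization: Fisher r-to-z for CFH, then z-scoring.

    The output has mean 0 and SD 1 over the mask.  AI is not a correlation,
    so it is z-scored without the Fisher step.
    """
    if m.normalized:
        raise ValueError("map is already normalized")
    if np.ptp(m.values) == 0:
        raise ValueError("constant map cannot be normalized")
    v = m.values
    if m.metric == "CFH":
        v = np.arctanh(np.clip(v, -_FISHER_CLIP, _FISHER_CLIP))
    sd = v.std()
    if sd == 0:
        raise ValueError("constant map cannot be normalized")
    out = (v - v.mean()) / sd
    return replace(
        m,
        values=out,
        normalized=True,
        params={**m.params, "normalization": "fisher_z+zscore" if m.metric == "CFH" else "zscore"},
    )
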