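"""Group-level statistics: covariate-adjusted voxel-wise t maps with
Gaussian-random-field (GRF) cluster correction, a permutation oracle, and
the demographic / clinical tests (Shapiro-Wilk dispatch, chi-square,
post hoc power, Spearman correlations).

The voxel-wise model is ordinary least squares of the (normalized) metric
on [intercept, group, age, sex, education]; the group t statistic is the
group coefficient over its standard error.  Cluster-level inference uses
random-field theory: smoothness (FWHM per axis) is estimated from the
variance of normalized residual spatial derivatives, the search volume is
expressed in resels, and a cluster of extent k at height threshold u gets

    P = 1 - exp(-E[m] * exp(-beta * k^(2/D)))

with E[m] the expected cluster count from the D-dimensional Euler
characteristic density and beta calibrated from the expected cluster size.
Two-tailed control runs the positive and negative excursion sets as two
one-tailed analyses at half the nominal levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "GroupDesign",
    "Cluster",
    "TStatResult",
    "glm_t_map",
    "estimate_smoothness",
    "grf_cluster_correct",
    "permutation_cluster_correct",
    "chi_square_2x2",
    "power_two_sample_t",
    "compare_groups",
    "spearman_corr",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass
class GroupDesign:
    """Binary group labels plus optional per-subject covariates."""

    group: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        uniq = np.unique(self.group)
        if len(uniq) != 2:
            raise ValueError("group must contain exactly two labels, both nonempty")
        self.group = (self.group == uniq.max()).astype(float)
        for name, v in self.covariates.items():
            v = np.asarray(v, dtype=float)
            if len(v) != len(self.group):
                raise ValueError(f"covariate {name!r} length mismatch")
            if np.isnan(v).any():
                raise ValueError(f"covariate {name!r} has missing values")
            self.covariates[name] = v

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(self.group)), self.group]
        names = ["intercept", "group"]
        for name, v in self.covariates.items():
            cols.append(v)
            names.append(name)
        return np.column_stack(cols), names


@dataclass
class Cluster:
    label: int
    sign: int
    peak_t: float
    peak_coord: tuple[int, int, int]
    extent_voxels: int
    cluster_p: float


@dataclass
class TStatResult:
    """Voxel-wise t map with smoothness and (after correction) clusters."""

    t_map: np.ndarray
    df: int
    mask: np.ndarray
    fwhm: np.ndarray | None = None
    clusters: list[Cluster] = field(default_factory=list)
    residuals: np.ndarray | None = field(default=None, repr=False)

    def t_volume(self) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.t_map
        return out


def glm_t_map(maps: np.ndarray, design: GroupDesign, mask: np.ndarray) -> TStatResult:
    """Voxel-wise two-sample t map with covariate adjustment.

    Parameters
    ----------
    maps : ndarray, shape (n_subjects, n_voxels)
        Per-subject metric values over the shared mask (C-order scan).
    """
    maps = np.asarray(maps, dtype=float)
    X, names = design.matrix()
    n, p = X.shape
    if maps.shape[0] != n:
        raise ValueError("row count of maps must match design")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    pinv = np.linalg.pinv(X)
    beta = pinv @ maps
    resid = maps - X @ beta
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    g = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[g, g])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[g] / se, 0.0)
    return TStatResult(t_map=t, df=df, mask=np.asarray(mask, bool), residuals=resid)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            bad.append(names[j])
    return bad


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis FWHM (voxel units) from normalized residual derivatives.

    Residual images are scaled to unit sum of squares per voxel; the mean
    squared spatial derivative v along each axis estimates the roughness of
    a unit-variance field.  Under a Gaussian autocorrelation,
    lambda = -2 ln(1 - v/2), and FWHM = sqrt(4 ln 2 / lambda).  Unsmoothed
    white noise gives v ~ 2 and an FWHM near one voxel or below.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual images")
    mask = np.asarray(mask, bool)
    ss = np.sqrt((residuals**2).sum(axis=0))
    if np.any(ss == 0):
        raise ValueError("constant (zero) residuals: smoothness undefined")
    U = residuals / ss
    n_img = U.shape[0]
    vol = np.zeros((n_img,) + mask.shape)
    vol[:, mask] = U
    inmask = mask
    fwhm = np.empty(3)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        pair = inmask[tuple(sl_lo)] & inmask[tuple(sl_hi)]
        if not pair.any():
            fwhm[ax] = np.inf
            continue
        d = vol[(slice(None),) + tuple(sl_hi)] - vol[(slice(None),) + tuple(sl_lo)]
        v = (d[:, pair] ** 2).sum(axis=0).mean()
        if v <= 0:
            raise ValueError("zero derivative variance: constant residual field")
        lam = -2.0 * np.log(max(1.0 - v / 2.0, 1e-12))
        fwhm[ax] = np.sqrt(_LN2_4 / lam)
    return fwhm


def _rft_cluster_p(
    extent: int,
    n_voxels: int,
    fwhm: np.ndarray,
    z_thresh: float,
    dim: int = 3,
) -> float:
    """RFT cluster-level p for one excursion set at Gaussianized height z.

    FWHM is floored at one voxel: a sampled field carries no sub-voxel
    smoothness information, and continuous RFT degenerates below it.
    """
    resel_size = float(np.prod(np.clip(fwhm, 1.0, None)))
    resels = n_voxels / resel_size
    u = z_thresh
    # 3D EC density of a unit Gaussian field
    rho3 = (_LN2_4 ** 1.5) / ((2 * np.pi) ** 2) * (u**2 - 1) * np.exp(-(u**2) / 2)
    em = max(resels * rho3, 1e-300)
    en = n_voxels * stats.norm.sf(u)  # expected suprathreshold voxels
    if en <= 0:
        return 1.0
    nbar = max(en / em, 1e-300)
    from scipy.special import gamma as gamma_fn

    beta = (gamma_fn(dim / 2 + 1) / nbar) ** (2.0 / dim)
    p_ge_k = np.exp(-beta * extent ** (2.0 / dim))
    return float(1.0 - np.exp(-em * p_ge_k))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def _excursion_clusters(
    t_vol: np.ndarray, mask: np.ndarray, t_thresh: float, connectivity: int
) -> list[tuple[int, float, tuple[int, int, int], int]]:
    """(sign, peak_t, peak_coord, extent) for both tails at |t| > t_thresh."""
    out = []
    struct = _structure(connectivity)
    for sign in (1, -1):
        exc = (sign * t_vol > t_thresh) & mask
        lab, n_lab = ndimage.label(exc, structure=struct)
        for li in range(1, n_lab + 1):
            coords = np.argwhere(lab == li)
            vals = t_vol[tuple(coords.T)]
            peak = int(np.argmax(sign * vals))
            out.append(
                (sign, float(vals[peak]), tuple(int(c) for c in coords[peak]), len(coords))
            )
    return out


def grf_cluster_correct(
    res: TStatResult,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    two_tailed: bool = True,
    connectivity: int = 26,
) -> TStatResult:
    """Attach GRF-surviving clusters to a t map.

    ``voxel_p`` and ``cluster_p`` are the two-tailed nominal levels; each
    tail is analyzed one-tailed at half the level.
    """
    if res.fwhm is None:
        if res.residuals is None:
            raise ValueError("smoothness unavailable: provide fwhm or residuals")
        res.fwhm = estimate_smoothness(res.residuals, res.mask)
    tail_voxel_p = voxel_p / 2 if two_tailed else voxel_p
    tail_cluster_p = cluster_p / 2 if two_tailed else cluster_p
    t_thresh = stats.t.isf(tail_voxel_p, res.df)
    z_thresh = stats.norm.isf(tail_voxel_p)  # Gaussianized height
    t_vol = res.t_volume()
    n_voxels = int(res.mask.sum())
    clusters = []
    for i, (sign, peak_t, peak_coord, extent) in enumerate(
        _excursion_clusters(t_vol, res.mask, t_thresh, connectivity)
    ):
        p = _rft_cluster_p(extent, n_voxels, res.fwhm, z_thresh)
        if p < tail_cluster_p:
            clusters.append(
                Cluster(
                    label=len(clusters) + 1,
                    sign=sign,
                    peak_t=peak_t,
                    peak_coord=peak_coord,
                    extent_voxels=extent,
                    cluster_p=p,
                )
            )
    res.clusters = sorted(clusters, key=lambda c: -abs(c.peak_t))
    return res


def permutation_cluster_correct(
    maps: np.ndarray,
    design: GroupDesign,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> list[Cluster]:
    """Max-cluster-extent permutation analogue of the GRF correction.

    Group labels are relabeled ``n_perm`` times; the null is the maximum
    cluster extent over both tails.  Serves as the model-free oracle for
    the parametric correction.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if n_perm < 1.0 / cluster_p:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve cluster_p={cluster_p}", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    res = glm_t_map(maps, design, mask)
    t_thresh = stats.t.isf(voxel_p / 2, res.df)
    observed = _excursion_clusters(res.t_volume(), res.mask, t_thresh, connectivity)
    null_max = np.zeros(n_perm)
    group0 = design.group.copy()
    for b in range(n_perm):
        perm = rng.permutation(len(group0))
        d = GroupDesign(group=group0[perm], covariates={
            k: v for k, v in design.covariates.items()
        })
        r = glm_t_map(maps, d, mask)
        cl = _excursion_clusters(r.t_volume(), r.mask, t_thresh, connectivity)
        null_max[b] = max((c[3] for c in cl), default=0)
    clusters = []
    for sign, peak_t, peak_coord, extent in observed:
        p = (1.0 + np.sum(null_max >= extent)) / (1.0 + n_perm)
        if p < cluster_p:
            clusters.append(
                Cluster(
                    label=len(clusters) + 1,
                    sign=sign,
                    peak_t=peak_t,
                    peak_coord=peak_coord,
                    extent_voxels=extent,
                    cluster_p=float(p),
                )
            )
    return sorted(clusters, key=lambda c: -abs(c.peak_t))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    a, b = tab[0]
    c, d = tab[1]
    n = tab.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("all margins must be positive")
    stat = n * (a * d - b * c) ** 2 / np.prod(margins)
    return float(stat), float(stats.chi2.sf(stat, 1))


def power_two_sample_t(
    d: float, alpha: float = 0.05, n1: int = 42, n2: int = 45, two_tailed: bool = True
) -> float:
    """Power of the independent-samples t test at effect size Cohen's d."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    if two_tailed:
        tc = stats.t.isf(alpha / 2, df)
        power = stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc)
    else:
        tc = stats.t.isf(alpha, df)
        power = stats.nct.sf(tc, df, nc)
    return float(power)


def compare_groups(
    x, y, method: str = "shapiro_then_auto"
) -> tuple[float, float, str]:
    """Two-group comparison with optional normality-based dispatch.

    ``shapiro_then_auto`` runs Shapiro-Wilk on both samples at 0.05 and
    uses the t test when both pass, Mann-Whitney U otherwise; the branch
    taken is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 observations")
    if method == "shapiro_then_auto":
        for s in (x, y):
            if np.ptp(s) == 0:
                raise ValueError("constant sample: Shapiro-Wilk undefined")
        normal = (
            stats.shapiro(x).pvalue > 0.05 and stats.shapiro(y).pvalue > 0.05
        )
        method = "t" if normal else "mann_whitney"
    if method == "t":
        if np.ptp(np.concatenate([x, y])) == 0:  # identical constants
            return 0.0, 1.0, "t"
        res = stats.ttest_ind(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant samples
            stat, p = 0.0, 1.0
        return stat, p, "t"
    if method == "mann_whitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), "mann_whitney"
    raise ValueError(f"unknown method {method!r}")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rho with two-tailed p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
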