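"""Expression preprocessing and PLS transcriptome-neuroimaging association.

The preprocessing chain mirrors the standard microarray-to-parcellation
workflow: probes below background in more than half of the samples are
dropped; one representative probe per gene is kept (the probe whose
regional profile agrees best, on average, with the gene's other probes);
tissue samples are assigned to the nearest parcel within a Euclidean
distance cap; expression is normalized with a scaled robust sigmoid
(median/IQR sigmoid followed by unit-interval rescaling).

The association stage regresses a regional response map (group-difference
t values) on the regions x genes expression matrix with partial least
squares.  Only the first component is used: with a univariate response the
PLS1 weight vector is the normalized covariance X'y, the regional scores
are X w, and the explained variance equals the squared Pearson correlation
of scores with the response.  Significance against spatial
autocorrelation uses a spin permutation null (random 3D rotations of
region centroids projected on a sphere, greedy nearest reassignment);
per-gene inference uses bootstrap resampling of regions, Z = loading /
bootstrap SE, and two-tailed normal p values under Benjamini-Hochberg FDR,
split into positive and negative gene sets by weight sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProbeTable",
    "PLSResult",
    "SpinNull",
    "filter_probes",
    "select_representative_probe",
    "assign_samples",
    "srs_normalize",
    "pls1_fit",
    "build_spin_null",
    "spin_test",
    "bootstrap_gene_z",
    "fdr_gene_sets",
]


@dataclass
class ProbeTable:
    """Probe-level expression with above-background flags.

    ``expression``: probes x samples; ``flags``: same shape, True where the
    measurement exceeded background noise; ``probe_gene``: probe_id -> gene
    symbol (exactly one gene per probe).
    """

    expression: pd.DataFrame
    probe_gene: pd.Series
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.flags.index) or not (
            self.expression.columns.equals(self.flags.columns)
        ):
            raise ValueError("flags must align with expression")
        if not self.expression.index.equals(self.probe_gene.index):
            raise ValueError("every probe needs exactly one gene symbol")


@dataclass
class PLSResult:
    scores: np.ndarray
    weights: pd.Series
    explained_variance: float
    spin_p: float | None = None
    gene_z: pd.Series | None = None
    plus_set: list[str] = field(default_factory=list)
    minus_set: list[str] = field(default_factory=list)
    z_cutoffs: tuple[float | None, float | None] = (None, None)


@dataclass
class SpinNull:
    """Spatial permutation null: one region bijection per rotation."""

    perms: np.ndarray  # (n_rotations, n_regions) int
    centroids: np.ndarray
    method: str = "sphere_rotation"

    def __post_init__(self) -> None:
        n = self.perms.shape[1]
        ref = np.arange(n)
        for row in self.perms:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("each spin must be a bijection over regions")

    @property
    def n_rotations(self) -> int:
        return self.perms.shape[0]


def filter_probes(t: ProbeTable) -> ProbeTable:
    """Drop probes below background in more than 50% of samples."""
    frac = t.flags.to_numpy().mean(axis=1)
    keep = frac >= 0.5  # exactly-50% probes survive
    if not keep.any():
        raise ValueError("no probes survive the background filter")
    idx = t.expression.index[keep]
    return ProbeTable(
        expression=t.expression.loc[idx],
        probe_gene=t.probe_gene.loc[idx],
        flags=t.flags.loc[idx],
    )


def select_representative_probe(
    t: ProbeTable, sample_region: pd.Series
) -> tuple[ProbeTable, pd.Series]:
    """One probe per gene by maximum inter-probe regional consistency.

    ``sample_region`` maps sample id -> region label (NaN / <=0 means
    unassigned).  For multi-probe genes the winner maximizes the mean
    Pearson correlation of its regional mean profile with the profiles of
    the gene's other probes; ties break to the lexicographically smallest
    probe id.  Returns the reduced table and a gene -> probe mapping.
    """
    assigned = sample_region.dropna()
    assigned = assigned[assigned > 0]
    profiles = (
        t.expression[assigned.index]
        .T.groupby(assigned)
        .mean()
        .T
    )  # probes x regions
    chosen: dict[str, str] = {}
    for gene, probes in t.probe_gene.groupby(t.probe_gene):
        ids = sorted(probes.index)
        if len(ids) == 1:
            chosen[gene] = ids[0]
            continue
        prof = profiles.loc[ids].to_numpy()
        with np.errstate(invalid="ignore"):
            cmat = np.corrcoef(prof)
        cmat = np.nan_to_num(cmat, nan=0.0)
        np.fill_diagonal(cmat, np.nan)
        score = np.nanmean(cmat, axis=1)
        best = int(np.argmax(score))  # first max = smallest probe id (sorted)
        chosen[gene] = ids[best]
    probe_ids = [chosen[g] for g in sorted(chosen)]
    reduced = ProbeTable(
        expression=t.expression.loc[probe_ids],
        probe_gene=t.probe_gene.loc[probe_ids],
        flags=t.flags.loc[probe_ids],
    )
    return reduced, pd.Series({g: chosen[g] for g in sorted(chosen)}, name="probe_id")


def assign_samples(
    sample_coords: np.ndarray,
    atlas_labels: np.ndarray,
    affine: np.ndarray,
    max_dist: float = 2.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Assign world-mm sample coordinates to parcel labels.

    A sample inside a labelled voxel takes that label; otherwise the label
    of the nearest labelled voxel center within ``max_dist`` mm
    (equidistant candidates resolve to the smallest label); otherwise 0
    (unassigned).
    """
    import nibabel as nib

    sample_coords = np.atleast_2d(np.asarray(sample_coords, dtype=float))
    atlas_labels = np.asarray(atlas_labels)
    inv = np.linalg.inv(affine)
    vox = nib.affines.apply_affine(inv, sample_coords)
    vox_round = np.round(vox).astype(int)
    labelled = np.argwhere(atlas_labels > 0)
    if labelled.size == 0:
        raise ValueError("atlas contains no labelled voxels")
    world_lab = nib.affines.apply_affine(affine, labelled)
    lab_vals = atlas_labels[tuple(labelled.T)]
    tree = cKDTree(world_lab)
    out = np.zeros(len(sample_coords), dtype=int)
    for i, (w, v) in enumerate(zip(sample_coords, vox_round)):
        if np.all((v >= 0) & (v < atlas_labels.shape)) and atlas_labels[tuple(v)] > 0:
            out[i] = int(atlas_labels[tuple(v)])
            continue
        d, j = tree.query(w)
        if d <= max_dist:
            near = tree.query_ball_point(w, d + tol)
            out[i] = int(min(lab_vals[k] for k in near))
    return out


def srs_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: median/IQR sigmoid, then min-max to [0, 1]."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct values")
    med = np.median(x)
    iqr = np.percentile(x, 75) - np.percentile(x, 25)
    if iqr == 0:
        raise ValueError("zero IQR: robust sigmoid undefined")
    s = 1.0 / (1.0 + np.exp(-(x - med) / iqr))
    return (s - s.min()) / (s.max() - s.min())


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def pls1_fit(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, standardize: bool = True
) -> PLSResult:
    """First PLS component of a univariate-response regression.

    Weights are the normalized covariance direction X'y; scores are X w;
    explained variance is corr(scores, y)^2; the sign convention fixes
    corr(scores, y) >= 0.
    """
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"g{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xa.shape[0] < 3:
        raise ValueError("need at least 3 regions")
    if Xa.shape[0] != len(y):
        raise ValueError("region mismatch between X and y")
    Xs = _standardize_columns(Xa) if standardize else Xa
    yc = y - y.mean()
    w = Xs.T @ yc
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("response uncorrelated with every gene: PLS1 undefined")
    w = w / nrm
    scores = Xs @ w
    r = np.corrcoef(scores, y)[0, 1]
    if r < 0:
        w, scores, r = -w, -scores, -r
    return PLSResult(
        scores=scores,
        weights=pd.Series(w, index=genes, name="pls1_weight"),
        explained_variance=float(r**2),
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform 3D rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def build_spin_null(
    centroids: np.ndarray,
    n: int = 5000,
    seed: int = 0,
    rotations: np.ndarray | None = None,
) -> SpinNull:
    """Spin permutations of region centroids.

    Centroids are projected radially onto a unit sphere about their mean;
    for each iteration a uniformly random rotation is applied and each
    region is greedily reassigned to the nearest rotated centroid without
    replacement.  Degenerate (coplanar) centroid sets fall back to plain
    label permutation with a warning.
    """
    centroids = np.asarray(centroids, dtype=float)
    R = len(centroids)
    if R < 4:
        raise ValueError("need at least 4 regions for a spin null")
    v = centroids - centroids.mean(axis=0)
    if np.linalg.matrix_rank(v) < 3:
        warnings.warn(
            "coplanar centroids: falling back to label permutation", stacklevel=2
        )
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(R) for _ in range(n)])
        return SpinNull(perms=perms, centroids=centroids, method="label_permutation")
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    perms = np.empty((n, R), dtype=int)
    for it in range(n):
        Q = _random_rotation(rng) if rotations is None else rotations[it]
        rotated = u @ Q.T
        D = np.linalg.norm(u[:, None, :] - rotated[None, :, :], axis=2)
        perm = _greedy_assign(D)
        perms[it] = perm
    return SpinNull(perms=perms, centroids=centroids)


def _greedy_assign(D: np.ndarray) -> np.ndarray:
    """Greedy min-distance bijection: perm[i] = rotated index taken by region i.

    Equivalent to repeatedly taking the global minimum of the masked
    distance matrix; implemented by scanning pairs in ascending distance.
    """
    D = D.copy()
    R = D.shape[0]
    perm = np.full(R, -1, dtype=int)
    for _ in range(R):
        i, j = np.unravel_index(np.argmin(D), D.shape)
        perm[i] = j
        D[i, :] = np.inf
        D[:, j] = np.inf
    return perm


def spin_test(
    statistic_fn,
    observed: float,
    null: SpinNull,
    regional_map: np.ndarray,
    alternative: str = "greater",
) -> float:
    """Permutation p of a regional statistic against the spin null.

    ``statistic_fn`` receives the spun map (``map[perm]``) and must be
    deterministic.  One-tailed "exceeds chance": p = (1 + #{null >= obs})
    / (1 + n); the two-tailed variant doubles the smaller tail.
    """
    regional_map = np.asarray(regional_map, dtype=float)
    null_stats = np.array([statistic_fn(regional_map[p]) for p in null.perms])
    n = len(null_stats)
    p_hi = (1.0 + np.sum(null_stats >= observed)) / (1.0 + n)
    if alternative == "greater":
        return float(p_hi)
    if alternative == "two-sided":
        p_lo = (1.0 + np.sum(null_stats <= observed)) / (1.0 + n)
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))
    raise ValueError(f"unknown alternative {alternative!r}")


def bootstrap_gene_z(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene Z = PLS1 loading / bootstrap SE.

    Regions are resampled with replacement; each bootstrap loading vector
    is sign-aligned to the original (flipped when their correlation is
    negative) before the per-gene SD is taken, removing the sign
    indeterminacy of the component.

    The bootstrap operates on the *unnormalized* covariance loadings
    X'y (standardized predictors, centered response): renormalizing the
    weight vector inside every resample deflates the per-gene bootstrap SE
    by up to sqrt(2) under weak signal (the resampled norm absorbs part of
    the fluctuation), which would inflate null Z scores.  Z values share
    the sign pattern of the (sign-fixed) PLS1 weights, so the downstream
    sign split is unaffected.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    base = pls1_fit(X, y)
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    R = Xa.shape[0]
    rng = np.random.default_rng(seed)

    def raw_loading(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
        return _standardize_columns(Xb).T @ (yb - yb.mean())

    w0 = raw_loading(Xa, y)
    # match the sign convention of pls1_fit (corr(scores, y) >= 0)
    if float(w0 @ base.weights.to_numpy()) < 0:
        w0 = -w0
    W = np.empty((n_boot, Xa.shape[1]))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, R, size=R)
            if len(np.unique(idx)) < 3 or np.ptp(y[idx]) == 0:
                continue  # fewer than 3 distinct regions: redraw
            break
        wb = raw_loading(Xa[idx], y[idx])
        if float(wb @ w0) < 0:
            wb = -wb
        W[b] = wb
    se = W.std(axis=0)
    se = np.where(se == 0, np.inf, se)
    z = w0 / se
    genes = base.weights.index
    return pd.Series(z, index=genes, name="gene_z")


def fdr_gene_sets(
    Z: pd.Series, q: float = 0.05
) -> tuple[list[str], list[str], tuple[float | None, float | None]]:
    """BH-FDR significant genes split by weight sign.

    Two-tailed normal p values on Z; returns (plus_set, minus_set,
    (positive cutoff, negative cutoff)) where the cutoffs are the smallest
    |Z| among significant genes of each sign (None when a set is empty).
    """
    z = np.asarray(Z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("Z values must be finite")
    p = 2.0 * stats.norm.sf(np.abs(z))
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    names = np.asarray(Z.index)
    plus = [str(g) for g in names[reject & (z > 0)]]
    minus = [str(g) for g in names[reject & (z < 0)]]
    z_plus = float(z[reject & (z > 0)].min()) if plus else None
    z_minus = float(z[reject & (z < 0)].max()) if minus else None
    return plus, minus, (z_plus, z_minus)
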