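"""Synthetic cohorts, expression tables and receptor maps.

The generator plants exactly the statistical structure the downstream
analysis assumes, so every stage is testable without any data download:

* **Homotopic coupling.**  Each mirror pair of voxels shares a latent time
  series with loading sqrt(rho), giving an expected Pearson correlation of
  ``rho`` between mirrored voxels (closed form, no tuning).
* **CFH effects.**  In a flagged region the patient-group pair loading is
  raised from ``rho`` to ``rho + shift``.
* **AI effects.**  A region-wide latent is added to one hemisphere only in
  patients, raising within-hemisphere connectivity (Ni) without touching
  cross-hemisphere connectivity (Nc).
* **Clinical table.**  Vision and disease duration are log-normal, so
  normality tests reject and nonparametric branches are exercised.
* **Expression / receptor tables.**  A chosen number of gene columns has a
  prescribed expected Pearson correlation with a target regional map;
  receptor maps get a prescribed expected *Spearman* correlation via
  rank blending (blend weight ``2*sin(pi*rho/6)``, the bivariate-normal
  rank-correlation inversion).

Defaults mirror the emulated study: 42 patients vs 45 controls, a
16x16x12 grid (midline on the first axis) with 8 parcels per hemisphere,
150 timepoints, baseline homotopic correlation 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import LEFT, BoldVolume4D, save_label_volume, save_volume

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "make_parcellation",
    "make_cohort",
    "make_expression_table",
    "make_receptor_tables",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator (defaults are the study conditions)."""

    grid_shape: tuple[int, int, int] = (16, 16, 12)
    n_timepoints: int = 150
    n_patients: int = 42
    n_controls: int = 45
    baseline_homotopic_rho: float = 0.5
    effect_regions: tuple[tuple[int, str, float], ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] % 2:
            raise ValueError("first grid axis must be even (two equal hemispheres)")
        if not 0.0 <= self.baseline_homotopic_rho < 1.0:
            raise ValueError("baseline_homotopic_rho must lie in [0, 1)")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 timepoints")
        for label, metric, size in self.effect_regions:
            if metric not in ("AI", "CFH"):
                raise ValueError(f"effect metric must be AI or CFH, got {metric!r}")
            if metric == "CFH" and not 0 <= size < 1 - self.baseline_homotopic_rho:
                raise ValueError("CFH shift must keep rho + shift below 1")
            if metric == "AI" and not 0 <= size < 1 - self.baseline_homotopic_rho:
                raise ValueError("AI loading must keep total variance share below 1")


@dataclass
class SyntheticCohort:
    """One generated cohort: volumes, clinical table, parcellation, truth."""

    volumes: list[BoldVolume4D]
    subject_table: pd.DataFrame
    parcellation: np.ndarray
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def patients(self) -> np.ndarray:
        return (self.subject_table["group"] == "patient").to_numpy()

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write volumes (.nii), parcellation, subject table and truth record."""
        outdir = Path(outdir)
        (outdir / "volumes").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, vol in zip(self.subject_table["id"], self.volumes):
            p = outdir / "volumes" / f"{sid}_bold.nii"
            data = np.zeros(vol.mask.shape + (vol.n_timepoints,), dtype=np.float32)
            data[tuple(vol.voxel_coords.T)] = vol.series
            save_volume(p, data, vol.affine)
            paths[f"bold:{sid}"] = p
        p = outdir / "parcellation.nii"
        save_label_volume(p, self.parcellation)
        paths["parcellation"] = p
        mask = np.ones(self.parcellation.shape, dtype=np.int16)
        p = outdir / "mask.nii"
        save_label_volume(p, mask)
        paths["mask"] = p
        p = outdir / "subjects.tsv"
        self.subject_table.to_csv(p, sep="\t", index=False)
        paths["subjects"] = p
        p = outdir / "truth.json"
        p.write_text(json.dumps(self.truth, indent=2))
        paths["truth"] = p
        return paths


def make_parcellation(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Mirror-symmetric parcellation: 8 left parcels (1-8), right = left + 8.

    The left hemisphere (lower first-axis half) is split 2x2x2 along the
    three axes; the right-hemisphere mirror of left parcel ``k`` carries
    label ``k + 8``, in the style of paired anatomical atlas labels.
    """
    sx, sy, sz = grid_shape
    half = sx // 2
    labels = np.zeros(grid_shape, dtype=np.int16)
    i, j, k = np.meshgrid(
        np.arange(sx), np.arange(sy), np.arange(sz), indexing="ij"
    )
    block = (
        (np.minimum(i, sx - 1 - i) >= half // 2).astype(int) * 4
        + (j >= sy // 2).astype(int) * 2
        + (k >= sz // 2).astype(int)
    )
    labels = np.where(i < half, block + 1, block + 9).astype(np.int16)
    return labels


def make_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort with planted homotopic / autonomy effects."""
    rng = np.random.default_rng(config.seed)
    parc = make_parcellation(config.grid_shape)
    labels_present = set(int(v) for v in np.unique(parc) if v > 0)
    for label, metric, size in config.effect_regions:
        if int(label) not in labels_present:
            raise ValueError(f"effect region label {label} absent from parcellation")

    mask = np.ones(config.grid_shape, dtype=bool)
    from .volume import hemisphere_split

    kept, hemilabel, mirror_index, coords = hemisphere_split(mask)
    n_vox, T = len(coords), config.n_timepoints
    left_rows = np.flatnonzero(hemilabel == LEFT)
    # every left voxel has an in-mask mirror on the full grid
    pair_right = mirror_index[left_rows]
    parc_flat = parc[tuple(coords.T)].astype(int)

    half = config.grid_shape[0] // 2
    mirror_label = {}
    for label in sorted(labels_present):
        mirror_label[label] = label + 8 if label <= 8 else label - 8

    rho_base = config.baseline_homotopic_rho
    cfh_shift_pair = np.zeros(len(left_rows))
    ai_regions: list[tuple[int, float]] = []
    for label, metric, size in config.effect_regions:
        if metric == "CFH":
            # the shift is a pair property: flag pairs whose either member
            # lies in the named region
            hit = (parc_flat[left_rows] == label) | (parc_flat[pair_right] == label)
            cfh_shift_pair[hit] = np.maximum(cfh_shift_pair[hit], size)
        else:
            ai_regions.append((int(label), float(size)))

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    volumes: list[BoldVolume4D] = []
    for group in groups:
        is_pat = group == "patient"
        rho_pair = rho_base + (cfh_shift_pair if is_pat else 0.0)
        shared = rng.standard_normal((len(left_rows), T))
        noise = rng.standard_normal((n_vox, T))
        gamma = np.zeros(n_vox)
        region_latents = {}
        for label, size in ai_regions:
            region_latents[label] = rng.standard_normal(T)
            if is_pat:
                gamma[parc_flat == label] = size
        series = np.empty((n_vox, T))
        rho_vox = np.empty(n_vox)
        rho_vox[left_rows] = rho_pair
        rho_vox[pair_right] = rho_pair
        shared_vox = np.empty((n_vox, T))
        shared_vox[left_rows] = shared
        shared_vox[pair_right] = shared
        resid = 1.0 - rho_vox - gamma
        if np.any(resid < 0):
            raise ValueError("planted effect sizes exceed unit variance budget")
        series = (
            np.sqrt(rho_vox)[:, None] * shared_vox
            + np.sqrt(resid)[:, None] * noise
        )
        for label, size in ai_regions:
            in_reg = parc_flat == label
            if is_pat and in_reg.any():
                series[in_reg] += np.sqrt(size) * region_latents[label]
        series *= config.noise_sd
        volumes.append(
            BoldVolume4D(
                series=series,
                mask=kept,
                hemilabel=hemilabel,
                mirror_index=mirror_index,
                voxel_coords=coords,
            )
        )

    subject_table = _make_subject_table(groups, rng)
    truth = {
        "baseline_homotopic_rho": rho_base,
        "effects": [
            {
                "label": int(label),
                "metric": metric,
                "size": float(size),
                "mirror_label": mirror_label[int(label)],
            }
            for label, metric, size in config.effect_regions
        ],
        "n_parcels": len(labels_present),
        "grid_shape": list(config.grid_shape),
    }
    return SyntheticCohort(
        volumes=volumes,
        subject_table=subject_table,
        parcellation=parc,
        truth=truth,
        config=config,
    )


def _make_subject_table(groups: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Clinical table; vision and duration are log-normal (non-normal by design)."""
    n = len(groups)
    rows = []
    for i, group in enumerate(groups):
        is_pat = group == "patient"
        rows.append(
            {
                "id": f"sub-{i + 1:03d}",
                "group": group,
                "age": float(np.clip(np.round(rng.normal(54, 10)), 25, 80)),
                "sex": int(rng.random() < 0.45),  # 1 = male
                "education": float(np.clip(np.round(rng.normal(12, 3)), 6, 20)),
                # decimal visual acuity ~ median 0.04 for patients; HC >= 1.0
                "vision": float(rng.lognormal(np.log(0.04), 1.0)) if is_pat else np.nan,
                # days since detachment, median ~ 11
                "duration": float(rng.lognormal(np.log(11.0), 1.0)) if is_pat else np.nan,
            }
        )
    return pd.DataFrame(rows)


def make_expression_table(
    n_regions: int,
    n_genes: int,
    target_map: np.ndarray,
    n_coupled: int,
    coupling_r: float,
    seed: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Regions x genes expression table with planted coupled genes.

    Each of ``n_coupled`` gene columns has expected Pearson correlation
    ``coupling_r`` with ``target_map``; the rest are independent noise.
    Returns the table and the list of truly coupled gene names.
    """
    target_map = np.asarray(target_map, dtype=float)
    if len(target_map) != n_regions:
        raise ValueError(
            f"target_map has {len(target_map)} entries, expected {n_regions}"
        )
    if n_coupled > n_genes:
        raise ValueError("n_coupled cannot exceed n_genes")
    if abs(coupling_r) > 1:
        raise ValueError("|coupling_r| must be at most 1")
    rng = np.random.default_rng(seed)
    z = (target_map - target_map.mean()) / target_map.std()
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    coupled_cols = rng.choice(n_genes, size=n_coupled, replace=False)
    coupled_cols.sort()
    X = rng.standard_normal((n_regions, n_genes))
    X[:, coupled_cols] = (
        coupling_r * z[:, None]
        + np.sqrt(1.0 - coupling_r**2) * X[:, coupled_cols]
    )
    # gene-specific affine placement, expression-like scale
    offset = rng.uniform(4.0, 10.0, size=n_genes)
    scale = rng.uniform(0.5, 2.0, size=n_genes)
    X = offset + scale * X
    regions = [f"region_{i + 1}" for i in range(n_regions)]
    table = pd.DataFrame(X, index=regions, columns=genes)
    return table, [genes[c] for c in coupled_cols]


def make_receptor_tables(
    n_regions: int,
    target_map: np.ndarray,
    target_rhos: list[float],
    seed: int,
) -> pd.DataFrame:
    """Regions x maps density table with prescribed expected Spearman rhos.

    Map ``k`` is a blend of the z-scored ranks of ``target_map`` with noise;
    the blend weight ``w = 2 sin(pi * rho / 6)`` inverts the
    bivariate-normal Spearman/Pearson relation so the expected sample
    Spearman correlation is approximately ``target_rhos[k]``.  At rho = +/-1
    the map is an exact monotone transform (sample Spearman = +/-1).
    """
    from scipy.stats import rankdata

    target_map = np.asarray(target_map, dtype=float)
    if len(target_map) != n_regions:
        raise ValueError("target_map length must equal n_regions")
    for r in target_rhos:
        if abs(r) > 1:
            raise ValueError("each target rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    ranks = rankdata(target_map)
    zr = (ranks - ranks.mean()) / ranks.std()
    cols = {}
    for k, rho in enumerate(target_rhos):
        w = 2.0 * np.sin(np.pi * rho / 6.0)
        eps = rng.standard_normal(n_regions)
        y = w * zr + np.sqrt(max(0.0, 1.0 - w**2)) * eps
        cols[f"MAP{k + 1:02d}"] = 10.0 + 2.0 * y  # tracer-like arbitrary units
    regions = [f"region_{i + 1}" for i in range(n_regions)]
    return pd.DataFrame(cols, index=regions)
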