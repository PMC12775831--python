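"""End-to-end orchestration: simulate -> metrics -> group -> transcriptomics
-> receptors -> classify, with standard-format I/O and a reproducibility
manifest.

Every stage reads its inputs from, and writes its artifacts into, a run
directory, so stages can be re-run individually from the CLI.  Each run
produces ``manifest.json`` mapping every artifact to its SHA-256 digest;
identical configuration and seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    discriminate,
    groupstats,
    hemimetrics,
    molecular_maps,
    synthdata,
    transcriptomics,
)
from .volume import BoldVolume4D, load_volume, save_label_volume, save_volume

logger = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "group", "transcriptomics", "receptors", "classify")


@dataclass
class RunConfig:
    """All pipeline knobs in one document (JSON/YAML loadable)."""

    out_dir: str = "hemispan_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulation
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    n_timepoints: int = 150
    n_patients: int = 42
    n_controls: int = 45
    baseline_homotopic_rho: float = 0.5
    effect_regions: tuple[tuple[int, str, float], ...] = (
        (9, "AI", 0.25),
        (14, "CFH", 0.3),
    )
    n_genes: int = 200
    n_coupled_genes: int = 10
    coupling_r: float = 0.8
    n_receptor_maps: int = 10
    receptor_rhos: tuple[float, ...] = (0.6, 0.6, 0.6, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    # thresholds (printed analysis constants)
    ai_alpha: float = 0.05
    map_smoothing_fwhm: float = 2.0  # voxels; GRF needs >=~2-voxel smoothness
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    spin_iterations: int = 5000
    bootstrap_iterations: int = 10000
    fdr_q: float = 0.05
    bonferroni_alpha: float = 0.001
    svm_C_grid: tuple[float, ...] = discriminate.DEFAULT_C_GRID
    svm_gamma_grid: tuple[float, ...] = discriminate.DEFAULT_GAMMA_GRID

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not 0 < self.voxel_p < 1 or not 0 < self.cluster_p < 1:
            raise ValueError("p thresholds must lie in (0, 1)")
        if len(self.receptor_rhos) != self.n_receptor_maps:
            raise ValueError("receptor_rhos length must equal n_receptor_maps")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        for key in ("grid_shape", "stages", "receptor_rhos", "svm_C_grid", "svm_gamma_grid"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "effect_regions" in kwargs:
            kwargs["effect_regions"] = tuple(
                (int(a), str(b), float(c)) for a, b, c in kwargs["effect_regions"]
            )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _np_default(o):
    import numpy as _np

    if isinstance(o, _np.integer):
        return int(o)
    if isinstance(o, _np.floating):
        return float(o)
    if isinstance(o, _np.ndarray):
        return o.tolist()
    return str(o)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path: Path, params: dict, seed: int, inputs: dict[str, str]) -> None:
    doc = {"params": params, "seed": seed, "inputs": inputs}
    Path(str(path) + ".json").write_text(json.dumps(doc, indent=2, default=_np_default))


def _require(rundir: Path, *names: str) -> None:
    missing = [n for n in names if not (rundir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing required input(s) before computation: {missing}"
        )


def _load_bold(rundir: Path, sid: str) -> BoldVolume4D:
    data, affine = load_volume(rundir / "volumes" / f"{sid}_bold.nii")
    mask, _ = load_volume(rundir / "mask.nii")
    return BoldVolume4D.from_array(np.asarray(data, float), mask.astype(bool), affine=affine)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    rundir = Path(cfg.out_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        fn = globals()[f"stage_{stage}"]
        logger.info("running stage %s", stage)
        try:
            produced = fn(cfg, rundir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for p in produced:
            artifacts[str(Path(p).relative_to(rundir))] = _sha256(Path(p))
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "artifacts": dict(sorted(artifacts.items())),
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_np_default))
    return manifest


def stage_simulate(cfg: RunConfig, rundir: Path) -> list[Path]:
    sim = synthdata.SimulationConfig(
        grid_shape=cfg.grid_shape,
        n_timepoints=cfg.n_timepoints,
        n_patients=cfg.n_patients,
        n_controls=cfg.n_controls,
        baseline_homotopic_rho=cfg.baseline_homotopic_rho,
        effect_regions=cfg.effect_regions,
        seed=cfg.seed,
    )
    cohort = synthdata.make_cohort(sim)
    paths = cohort.save(rundir)

    # left-hemisphere regional target map for expression coupling: planted
    # group difference profile (region indicator smoothed by nothing) over
    # left parcels; expression couples to the left-region CFH truth profile
    left_labels = sorted(l for l in np.unique(cohort.parcellation) if 0 < l <= 8)
    target = np.zeros(len(left_labels))
    for eff in cohort.truth["effects"]:
        for lab in (eff["label"], eff["mirror_label"]):
            if lab in left_labels:
                target[left_labels.index(lab)] = eff["size"]
    rng = np.random.default_rng(cfg.seed + 1)
    target = target + rng.normal(0, 0.1, size=len(target))  # non-degenerate profile
    expr, truth_genes = synthdata.make_expression_table(
        n_regions=len(left_labels),
        n_genes=cfg.n_genes,
        target_map=target,
        n_coupled=cfg.n_coupled_genes,
        coupling_r=cfg.coupling_r,
        seed=cfg.seed + 2,
    )
    expr.index = [f"region_{l}" for l in left_labels]
    p = rundir / "expression.tsv"
    expr.to_csv(p, sep="\t")
    paths["expression"] = p

    all_labels = sorted(l for l in np.unique(cohort.parcellation) if l > 0)
    target_all = np.zeros(len(all_labels))
    for eff in cohort.truth["effects"]:
        for lab in (eff["label"], eff["mirror_label"]):
            target_all[all_labels.index(lab)] = eff["size"]
    target_all = target_all + rng.normal(0, 0.1, size=len(target_all))
    rec = synthdata.make_receptor_tables(
        n_regions=len(all_labels),
        target_map=target_all,
        target_rhos=list(cfg.receptor_rhos),
        seed=cfg.seed + 3,
    )
    rec.index = [f"region_{l}" for l in all_labels]
    p = rundir / "receptors.tsv"
    rec.to_csv(p, sep="\t")
    paths["receptors"] = p

    truth = cohort.truth | {
        "coupled_genes": truth_genes,
        "expression_target_map": target.tolist(),
        "receptor_target_map": target_all.tolist(),
    }
    (rundir / "truth.json").write_text(json.dumps(truth, indent=2, default=_np_default))
    _sidecar(rundir / "subjects.tsv", {"simulation": dataclasses.asdict(sim)}, cfg.seed, {})
    out = list(paths.values()) + [rundir / "subjects.tsv.json"]
    return out


def stage_metrics(cfg: RunConfig, rundir: Path) -> list[Path]:
    _require(rundir, "subjects.tsv", "mask.nii", "parcellation.nii", "volumes")
    subjects = pd.read_csv(rundir / "subjects.tsv", sep="\t")
    for metric in ("ai", "cfh"):
        (rundir / metric).mkdir(exist_ok=True)
    produced = []
    for sid in subjects["id"]:
        vol = _load_bold(rundir, sid)
        ai = hemimetrics.normalize_map(hemimetrics.compute_ai(vol, alpha=cfg.ai_alpha))
        cfh_raw, partner = hemimetrics.compute_cfh(vol)
        cfh = hemimetrics.normalize_map(cfh_raw)
        for metric, mmap in (("ai", ai), ("cfh", cfh)):
            p = rundir / metric / f"{sid}.nii"
            save_volume(p, vol.values_to_volume(mmap.values, fill=0.0), vol.affine)
            _sidecar(
                p,
                {"metric": mmap.metric, "normalized": mmap.normalized, **mmap.params},
                cfg.seed,
                {f"bold:{sid}": _sha256(rundir / "volumes" / f"{sid}_bold.nii")},
            )
            produced += [p, Path(str(p) + ".json")]
        p = rundir / "cfh" / f"{sid}_partner.nii"
        save_label_volume(p, vol.values_to_volume(partner.astype(float), fill=-1.0), vol.affine)
        produced.append(p)
    return produced


def _load_maps(
    rundir: Path,
    metric: str,
    subjects: pd.DataFrame,
    mask: np.ndarray,
    smoothing_fwhm: float = 0.0,
):
    from scipy.ndimage import gaussian_filter

    sigma = smoothing_fwhm / np.sqrt(8.0 * np.log(2.0))
    maps = []
    for sid in subjects["id"]:
        data, _ = load_volume(rundir / metric / f"{sid}.nii")
        data = np.asarray(data, float)
        if sigma > 0:
            data = gaussian_filter(data, sigma)
        maps.append(data[mask])
    return np.asarray(maps)


def stage_group(cfg: RunConfig, rundir: Path) -> list[Path]:
    _require(rundir, "subjects.tsv", "mask.nii", "ai", "cfh")
    subjects = pd.read_csv(rundir / "subjects.tsv", sep="\t")
    mask, affine = load_volume(rundir / "mask.nii")
    mask = mask.astype(bool)
    design = groupstats.GroupDesign(
        group=(subjects["group"] == "patient").to_numpy().astype(float),
        covariates={
            "age": subjects["age"].to_numpy(),
            "sex": subjects["sex"].to_numpy(),
            "education": subjects["education"].to_numpy(),
        },
    )
    produced = []
    for metric in ("ai", "cfh"):
        maps = _load_maps(rundir, metric, subjects, mask, cfg.map_smoothing_fwhm)
        res = groupstats.glm_t_map(maps, design, mask)
        res = groupstats.grf_cluster_correct(
            res, voxel_p=cfg.voxel_p, cluster_p=cfg.cluster_p
        )
        p = rundir / f"tmap_{metric}.nii"
        save_volume(p, res.t_volume(), affine)
        produced.append(p)
        clusters = [
            {
                "label": c.label,
                "sign": c.sign,
                "peak_t": c.peak_t,
                "peak_voxel": list(c.peak_coord),
                "peak_world_mm": list(
                    (affine @ np.r_[c.peak_coord, 1.0])[:3].astype(float)
                ),
                "extent_voxels": c.extent_voxels,
                "cluster_p": c.cluster_p,
            }
            for c in res.clusters
        ]
        p = rundir / f"clusters_{metric}.json"
        p.write_text(
            json.dumps(
                {
                    "df": res.df,
                    "fwhm_voxels": list(map(float, res.fwhm)),
                    "voxel_p": cfg.voxel_p,
                    "cluster_p": cfg.cluster_p,
                    "clusters": clusters,
                },
                indent=2,
                default=_np_default,
            )
        )
        produced.append(p)

    # demographic / clinical table
    pat = subjects[subjects["group"] == "patient"]
    con = subjects[subjects["group"] == "control"]
    rows = []
    for var in ("age", "education"):
        stat, pval, used = groupstats.compare_groups(pat[var], con[var])
        rows.append({"variable": var, "statistic": stat, "p": pval, "test": used})
    men_pat = int(pat["sex"].sum())
    men_con = int(con["sex"].sum())
    tab = [[men_pat, len(pat) - men_pat], [men_con, len(con) - men_con]]
    stat, pval = groupstats.chi_square_2x2(tab)
    rows.append({"variable": "sex", "statistic": stat, "p": pval, "test": "chi_square"})
    power = groupstats.power_two_sample_t(0.5, 0.05, len(pat), len(con))
    rows.append(
        {"variable": "posthoc_power_d0.5", "statistic": power, "p": np.nan, "test": "noncentral_t"}
    )
    demo = pd.DataFrame(rows)
    p = rundir / "demographics.tsv"
    demo.to_csv(p, sep="\t", index=False)
    produced.append(p)
    return produced


def _parcel_centroids(parc: np.ndarray, affine: np.ndarray, labels: list[int]) -> np.ndarray:
    import nibabel as nib

    cents = []
    for lab in labels:
        coords = np.argwhere(parc == lab)
        cents.append(nib.affines.apply_affine(affine, coords.mean(axis=0)))
    return np.asarray(cents)


def stage_transcriptomics(cfg: RunConfig, rundir: Path) -> list[Path]:
    _require(rundir, "tmap_cfh.nii", "parcellation.nii", "expression.tsv")
    tmap, affine = load_volume(rundir / "tmap_cfh.nii")
    parc, _ = load_volume(rundir / "parcellation.nii")
    parc = parc.astype(int)
    expr = pd.read_csv(rundir / "expression.tsv", sep="\t", index_col=0)
    left_labels = [int(s.split("_")[1]) for s in expr.index]
    regional = molecular_maps.regional_average(np.asarray(tmap, float), parc)
    y = regional.loc[left_labels].to_numpy()

    fit = transcriptomics.pls1_fit(expr, y)
    cents = _parcel_centroids(parc, affine, left_labels)
    null = transcriptomics.build_spin_null(
        cents, n=cfg.spin_iterations, seed=cfg.seed + 10
    )

    def stat(y_spun: np.ndarray) -> float:
        return transcriptomics.pls1_fit(expr, y_spun).explained_variance

    fit.spin_p = transcriptomics.spin_test(stat, fit.explained_variance, null, y)
    fit.gene_z = transcriptomics.bootstrap_gene_z(
        expr, y, n_boot=cfg.bootstrap_iterations, seed=cfg.seed + 11
    )
    fit.plus_set, fit.minus_set, fit.z_cutoffs = transcriptomics.fdr_gene_sets(
        fit.gene_z, q=cfg.fdr_q
    )
    p1 = rundir / "pls_result.json"
    p1.write_text(
        json.dumps(
            {
                "explained_variance": fit.explained_variance,
                "spin_p": fit.spin_p,
                "n_spin": cfg.spin_iterations,
                "n_boot": cfg.bootstrap_iterations,
                "plus_set": fit.plus_set,
                "minus_set": fit.minus_set,
                "z_cutoffs": list(fit.z_cutoffs),
                "regions": left_labels,
            },
            indent=2,
            default=_np_default,
        )
    )
    genes = pd.DataFrame({"weight": fit.weights, "z": fit.gene_z})
    p2 = rundir / "pls_genes.tsv"
    genes.to_csv(p2, sep="\t")
    p3 = rundir / "pls_scores.tsv"
    pd.DataFrame({"region": left_labels, "score": fit.scores, "t": y}).to_csv(
        p3, sep="\t", index=False
    )
    return [p1, p2, p3]


def stage_receptors(cfg: RunConfig, rundir: Path) -> list[Path]:
    _require(rundir, "tmap_cfh.nii", "parcellation.nii", "receptors.tsv")
    tmap, affine = load_volume(rundir / "tmap_cfh.nii")
    parc, _ = load_volume(rundir / "parcellation.nii")
    parc = parc.astype(int)
    rec = pd.read_csv(rundir / "receptors.tsv", sep="\t", index_col=0)
    labels = [int(s.split("_")[1]) for s in rec.index]
    regional = molecular_maps.regional_average(np.asarray(tmap, float), parc)
    t = regional.loc[labels]
    cents = _parcel_centroids(parc, affine, labels)
    null = transcriptomics.build_spin_null(
        cents, n=cfg.spin_iterations, seed=cfg.seed + 20
    )
    report = molecular_maps.receptor_spatial_corr(
        t, rec, null, alpha=cfg.bonferroni_alpha, n_maps=rec.shape[1]
    )
    p1 = rundir / "receptor_report.tsv"
    report.table.to_csv(p1, sep="\t")
    p2 = rundir / "receptor_report.json"
    p2.write_text(
        json.dumps(
            {
                "alpha": report.alpha,
                "n_maps": report.n_maps,
                "bonferroni_mode": report.bonferroni_mode,
                "significant_maps": report.significant_maps,
            },
            indent=2,
            default=_np_default,
        )
    )
    return [p1, p2]


def stage_classify(cfg: RunConfig, rundir: Path) -> list[Path]:
    _require(rundir, "subjects.tsv", "parcellation.nii", "truth.json", "ai", "cfh")
    subjects = pd.read_csv(rundir / "subjects.tsv", sep="\t")
    parc, _ = load_volume(rundir / "parcellation.nii")
    parc = parc.astype(int)
    truth = json.loads((rundir / "truth.json").read_text())
    effects = truth["effects"]
    if not effects:
        raise ValueError("no effect regions recorded: nothing to classify on")
    names, cols = [], []
    for eff in effects:
        metric = eff["metric"].lower()
        lab = eff["label"]
        vals = []
        for sid in subjects["id"]:
            data, _ = load_volume(rundir / metric / f"{sid}.nii")
            vals.append(np.asarray(data, float)[parc == lab].mean())
        names.append(f"{eff['metric']}_region{lab}")
        cols.append(vals)
    X = np.column_stack(cols)
    y = (subjects["group"] == "patient").to_numpy().astype(int)
    ft = discriminate.FeatureTable(X, y, names)
    report = discriminate.loocv_grid_svm(
        ft, cfg.svm_C_grid, cfg.svm_gamma_grid, per_feature=True
    )
    ranking = discriminate.rank_features_by_shap(report, labels=y)
    p1 = rundir / "classifier_report.json"
    p1.write_text(
        json.dumps(
            {
                "best_C": report.best_C,
                "best_gamma": report.best_gamma,
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "precision": report.precision,
                "auc": report.auc,
                "baseline_value": report.baseline_value,
                "per_feature": report.per_feature,
                "shap_ranking": ranking.to_dict(orient="records"),
            },
            indent=2,
            default=_np_default,
        )
    )
    p2 = rundir / "features.tsv"
    pd.DataFrame(X, columns=names).assign(label=y).to_csv(p2, sep="\t", index=False)
    p3 = rundir / "roc.tsv"
    report.roc.to_csv(p3, sep="\t", index=False)
    p4 = rundir / "shap_values.tsv"
    pd.DataFrame(report.shap_values, columns=names).to_csv(p4, sep="\t", index=False)
    return [p1, p2, p3, p4]
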