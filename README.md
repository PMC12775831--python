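# hemispan

Analysis pipeline for **hemispheric specialization** and
**interhemispheric coordination** in resting-state brain volumes, aimed
at researchers studying how focal sensory loss (for example retinal
detachment) reorganizes large-scale brain function.  The package covers
the full analysis chain — voxel-level metrics, covariate-adjusted group
statistics with cluster correction, transcriptome–neuroimaging
association, neurotransmitter-receptor spatial correlation, and
interpretable SVM classification — and ships a synthetic-data generator
so that every stage is testable end-to-end without access to patient
data.

## The metrics

For each in-mask voxel *v* with whole-brain functional connectivity
(Pearson correlation of BOLD time series):

* **Autonomy Index (AI)** — functional specialization:

  `AI(v) = Ni/Hi − Nc/Hc`

  where `Ni`/`Nc` count significantly connected voxels in the
  ipsilateral/contralateral hemisphere and `Hi`/`Hc` are the hemisphere
  voxel totals.  "Significantly connected" defaults to the positive
  critical Pearson *r* for two-tailed *p* < 0.05 at the series length.

* **CFH (Connectivity between Functionally Homotopic voxels)** —
  interhemispheric coordination: the maximum correlation between *v* and
  any voxel of the opposite hemisphere; the argmax voxel is the
  *functionally* homotopic partner (distinct from the geometric mirror).

Raw maps are normalized across the brain (Fisher r-to-z for CFH, then
z-scoring) before group comparison.  Group differences use voxel-wise
OLS of the metric on `[intercept, group, age, sex, education]` with
Gaussian-random-field cluster correction (voxel *p* < 0.001, cluster
*p* < 0.05, two-tailed) plus a permutation oracle.  Downstream stages:
PLS1 regression of regional *t* values on a regions × genes expression
matrix with spin-permutation significance and bootstrap gene *Z* scores
under BH-FDR; Spearman correlation of regional *t* maps against
receptor-density batteries under spin nulls with Bonferroni control; and
RBF-SVM classification (grid search, leave-one-out cross-validation)
with exact Shapley attribution.

## Worked example

Plant a homotopic-coupling increase (+0.3 on a baseline correlation of
0.4) in parcel 14 of a 16×16×12 synthetic cohort, compute CFH maps, and
localize the group difference:

```python
import numpy as np
from hemispan import synthdata, hemimetrics, groupstats

cfg = synthdata.SimulationConfig(
    grid_shape=(16, 16, 12), n_timepoints=150,
    n_patients=12, n_controls=12,
    baseline_homotopic_rho=0.4,
    effect_regions=((14, "CFH", 0.3),),
    seed=0,
)
cohort = synthdata.make_cohort(cfg)

maps = []
for vol in cohort.volumes:
    raw, partner = hemimetrics.compute_cfh(vol)
    maps.append(hemimetrics.normalize_map(raw).values)

design = groupstats.GroupDesign(group=cohort.patients.astype(float))
res = groupstats.glm_t_map(np.array(maps), design, cohort.volumes[0].mask)
peak = int(np.argmax(res.t_map))
peak_label = cohort.parcellation[tuple(cohort.volumes[0].voxel_coords[peak])]
print(f"peak t = {res.t_map[peak]:.2f} (df={res.df}) in parcel {peak_label}")
print(f"power(d=0.5, 42 vs 45) = {groupstats.power_two_sample_t(0.5, 0.05, 42, 45):.4f}")
```

Output:

```
peak t = 15.43 (df=22) in parcel 6
power(d=0.5, 42 vs 45) = 0.6346
```

The peak *t* lands in parcel 6, the left-hemisphere mirror of the
planted right-hemisphere parcel 14 (the shared latent raises both
members of each mirror pair).  The power line is the exact post hoc
power of a two-tailed independent-samples *t* test at Cohen's *d* = 0.5
for groups of 42 and 45.

## Command line

```bash
hemispan all --seed 1 --out runs/demo          # full chain
hemispan simulate --config cfg.json --out runs/demo
```

Subcommands `simulate`, `metrics`, `group`, `transcriptomics`,
`receptors`, `classify`, `all`; each stage reads and writes a run
directory (NIfTI volumes and maps, TSV tables, JSON reports) and the run
ends with a `manifest.json` of SHA-256 digests — identical configuration
and seed reproduce identical manifests.

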