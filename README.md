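# langlat

Multitask, multimodal phenotyping of language brain lateralization from
fMRI task asymmetries and resting-state connectivity of the SENT_CORE
sentence-processing network.

## The problem

Most people process sentences with a left-lateralized fronto-temporal
network, but a minority — mostly left-handers — lateralize rightward or
dissociate, hosting different language components (production, listening,
reading) in different hemispheres. Classifying these phenotypes from a
single production task misses much of the structure; combining several
task-induced asymmetries with the network's resting-state organization
separates a strongly typical, a mildly typical and an atypical phenotype
and reveals a high rate of *crossed* (dissociated) lateralization in the
atypical group.

`langlat` implements that analysis as a reusable library for researchers
working with ROI-level fMRI summaries:

* **Task asymmetries** — volumetric-mean left-minus-right BOLD contrast
  over the 18 homotopic SENT_CORE pairs and the 3 SENT_HUBS pairs
  (F3t, STS3, STS4), per task:
  `asym = Σᵢ wᵢ (Lᵢ − Rᵢ) / Σᵢ wᵢ` with `wᵢ` the pair volume.
* **Resting-state metrics** — after confound regression and a zero-phase
  least-squares FIR bandpass (0.01–0.1 Hz), per-hemisphere degree
  centrality `Rs_DC(roi) = Σ_{j≠roi, ipsilateral} max(r_roi,j, 0)`
  (averaged over the 18 hROIs of a hemisphere) and the mean
  interhemispheric homotopic correlation
  `Rs_mIHHC = tanh( mean_i atanh(r_{iL,iR}) )`.
* **Phenotype classification** — Ward minimum-variance clustering of the
  nine standardized variables, the number of clusters chosen by a majority
  vote of twelve internal validity indices, clusters labelled
  TYP_STRONG / TYP_MILD / ATYP from their mean task asymmetries.
* **Dissociation rule** — a participant is CROSSED when, within SENT_CORE
  or SENT_HUBS, the three task asymmetries point in opposite directions
  beyond a ±0.05 band; otherwise CONGRUENT.
* **Group statistics** — repeated-measures MANOVA (Pillai's trace,
  Type-III), Tukey HSD post hocs, Pearson chi-square proportion tests,
  covariate residualization, promax-rotated PCA of an 11-test cognitive
  battery, and the TYP/ATYP × CROSSED/CONGRUENT anatomy comparison.
* **Synthetic cohort** — a first-class generator that emulates the
  287-participant study cohort (150 left-handers, 140 women; groups of
  125/132/30 with 2/9/12 crossed members), calibrated so that the
  group-level means and spreads of every clustering variable reproduce the
  published tables; used by the tests and the acceptance script.

## Worked example

```python
import langlat
from langlat import synthetic as syn

atlas = langlat.default_atlas()            # 18 SENT_CORE pairs, 3 hubs
cfg = langlat.default_config(seed=42)
cohort = syn.generate_cohort(cfg)
contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)
profiles = langlat.asymmetry_profiles(contrasts, atlas)
rest = syn.generate_rest_timeseries(cohort, atlas, cfg)
metrics = langlat.connectivity_metrics(rest, atlas)
result = langlat.classify_cohort(profiles, metrics, seed=42, label_k=3)
print(result["labels"].group.value_counts())
print(result["labels"].dissociation.value_counts())
```

prints (seed 42):

```
TYP_MILD      144
TYP_STRONG    116
ATYP           27
CONGRUENT    264
CROSSED       23
```

i.e. the three-cluster cut recovers the planted phenotype structure up to
boundary uncertainty between the two typical groups, and the dissociation
rule finds exactly the 23 planted crossed individuals (12 of the 30
atypicals — a 40% dissociation rate against ~2–7% in the typical groups).
Group means of the computed features at the same seed: SENT_CORE PROD
asymmetry 0.53 / 0.30 / −0.09, mean Rs_DC 8.96 / 8.16 / 9.90 and
Rs_mIHHC 0.57 / 0.57 / 0.61 for TYP_STRONG / TYP_MILD / ATYP.

The `examples/` directory has one short script per capability (cohort
simulation, task asymmetries, resting-state metrics, clustering and
dissociations, group statistics, classification concordance). A thin CLI
drives the same stages end to end:

```bash
langlat run --seed 1 --out-dir out/        # simulate -> ... -> compare
langlat simulate --seed 1 --out-dir out/   # single stage
```

Every stage writes tab-delimited text plus a machine-readable
`report.json` (seed, config hash, row counts, selected k, group sizes,
dissociation counts).

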