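"""Group-level statistics: repeated-measures MANOVA, chi-square, Tukey HSD,
anatomy comparison and promax-rotated PCA of the cognitive battery."""

import langlat
from langlat import synthetic as syn
from langlat.group_stats import (
    anatomy_comparison,
    pca_promax,
    proportion_test,
    repeated_manova,
    residualize,
    tukey_hsd,
)

atlas = langlat.default_atlas()
cfg = langlat.default_config(seed=42)
cohort = syn.generate_cohort(cfg)
contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)
profiles = langlat.asymmetry_profiles(contrasts, atlas)

# task-by-group interaction on |asymmetry| (repeated-measures MANOVA)
dep = profiles[["ABS_CORE_PROD", "ABS_CORE_LISN", "ABS_CORE_READ"]]
em = repeated_manova(dep, cohort[["latent_group", "handedness"]])
print("repeated-measures MANOVA on |SENT_CORE asymmetry|:")
print(em.round(4).to_string(index=False))
# The task x group interaction is overwhelmingly significant: asymmetry
# strength differs between tasks for typicals but not for atypicals.

# handedness by group (Pearson chi-square, no continuity correction)
import pandas as pd
table = pd.crosstab(cohort.latent_group, cohort.handedness)
chi2, df, p = proportion_test(table.to_numpy())
print(f"\nleft-hander share differs between groups: "
      f"chi2({df}) = {chi2:.1f}, p = {p:.2g}")

# anatomy: organization (TYP vs ATYP) x dissociation
anatomy = syn.generate_anatomy(cohort, cfg)
labels = cohort.rename(columns={
    "latent_group": "group", "latent_dissociation": "dissociation"})
effects, pairs = anatomy_comparison(
    anatomy,
    labels[["participant_id", "group", "dissociation"]],
    cohort[["participant_id", "age", "sex", "total_intracranial_volume",
            "handedness"]],
)
org = effects.set_index(["variable", "effect"]).loc[
    ("tissue_asymmetry", "organization")]
print(f"\nGM/WM asymmetry, organization effect: "
      f"F = {org.F:.2f}, p = {org.p:.3g}")
gm_asym = (anatomy.gm_left - anatomy.gm_right).groupby(
    cohort.latent_group.map(lambda g: "ATYP" if g == "ATYP" else "TYP").values
).mean()
print("mean GM asymmetry (cc):", gm_asym.round(2).to_dict(),
      " (planted: smaller leftward asymmetry in ATYP)")

# cognition: 11 test scores -> covariate residuals -> PCA with promax
cog = syn.generate_cognitive_scores(cohort, cfg)
resid = residualize(
    cog.drop(columns="participant_id"),
    cohort[["sex", "handedness", "age", "education",
            "total_intracranial_volume"]],
)
pca = pca_promax(resid)
print(f"\nPCA of the cognitive battery: {pca.n_components} components "
      f"({pca.variance_explained.sum():.0f}% of variance)")
print("strongest promax loadings per component:")
for comp in pca.loadings.columns:
    top = pca.loadings[comp].abs().nlargest(3)
    print(f"  {comp}: " + ", ".join(f"{t} ({pca.loadings.loc[t, comp]:+.2f})"
                                    for t in top.index))
# Components align with the planted structure: a spatial factor (rotation,
# maze, Raven), a memory factor (word/pseudoword learning), a verbal factor
# (fluency, spans) and a phonological factor (rhyming).

print("\nTukey HSD on the memory component:")
mem = pca.scores.iloc[:, int(pca.loadings.loc["word_learning"].abs().argmax())]
print(tukey_hsd(mem, cohort.latent_group).round(4).to_string(index=False))
# ATYP scores lower on verbal memory than the typical groups.
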