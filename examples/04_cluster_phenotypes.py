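"""Cluster participants into lateralization phenotypes and find dissociations.

The nine standardized variables (six task asymmetries + Rs_DC sum, Rs_DC
asymmetry, Rs_mIHHC) enter Ward agglomeration; internal validity indices
vote on the number of clusters; clusters are labelled from their mean task
asymmetries; and each participant is checked for crossed lateralization
(opposite supra-0.05 asymmetries across tasks).
"""

import langlat
from langlat import synthetic as syn

atlas = langlat.default_atlas()
cfg = langlat.default_config(seed=42)
cohort = syn.generate_cohort(cfg)
contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)
profiles = langlat.asymmetry_profiles(contrasts, atlas)
rest = syn.generate_rest_timeseries(cohort, atlas, cfg)
metrics = langlat.connectivity_metrics(rest, atlas)

result = langlat.classify_cohort(profiles, metrics, seed=42, label_k=3)
print(f"validity-index vote: k = {result['k']}")
print("votes per index:", result["votes"])
# On this synthetic geometry most global indices prefer the dominant
# 2-cluster cut (ATYP vs the rest); the canonical 3-group labelling is
# taken at label_k = 3.

labels = result["labels"]
print("\nthree-group labelling:")
print(labels.group.value_counts().to_string())
print("\ndissociation status:")
print(labels.dissociation.value_counts().to_string())

truth = labels.merge(cohort, on="participant_id")
agree = (truth.dissociation == truth.latent_dissociation).mean()
print(f"\ndissociation rule recovers the planted status for "
      f"{100 * agree:.1f}% of participants")
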