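"""Compute volumetric-mean network asymmetries from hROI task contrasts.

Each participant's left-minus-right BOLD contrast is averaged over the 18
SENT_CORE pairs (and the 3 SENT_HUBS pairs) with pair-volume weights, for
the three sentence-minus-word-list tasks (PROD, LISN, READ).  Positive
values mean leftward (typical) lateralization.
"""

import langlat
from langlat import synthetic as syn

atlas = langlat.default_atlas()
cfg = langlat.default_config(seed=42)
cohort = syn.generate_cohort(cfg)
contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)

profiles = langlat.asymmetry_profiles(contrasts, atlas)
merged = profiles.merge(cohort, on="participant_id")

print("group means of the six signed asymmetries:")
cols = ["CORE_PROD", "CORE_LISN", "CORE_READ",
        "HUBS_PROD", "HUBS_LISN", "HUBS_READ"]
print(merged.groupby("latent_group")[cols].mean().round(3).to_string())
# TYP_STRONG shows strong leftward asymmetry in all tasks (~0.56 for
# SENT_CORE PROD), TYP_MILD moderate leftward (~0.30), and ATYP rightward
# (negative) mean asymmetry — the calibrated group structure.

one = profiles.iloc[0]
print(f"\nsingle participant {one.participant_id}: "
      f"SENT_CORE PROD asymmetry = {one.CORE_PROD:+.3f} "
      f"({'leftward' if one.CORE_PROD > 0 else 'rightward'})")
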