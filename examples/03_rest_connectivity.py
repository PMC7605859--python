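"""Resting-state connectivity metrics of the SENT_CORE network.

ROI time series are cleaned (confound regression + 0.01-0.1 Hz zero-phase
FIR bandpass), correlated, and summarized as per-hemisphere degree
centrality (Rs_DC: sum of positive ipsilateral correlations, averaged over
the 18 hROIs) and the mean interhemispheric homotopic correlation
(Rs_mIHHC, averaged on the Fisher-z scale).
"""

import langlat
from langlat import synthetic as syn

atlas = langlat.default_atlas()
cfg = langlat.default_config(seed=42)
cohort = syn.generate_cohort(cfg)
rest = syn.generate_rest_timeseries(cohort, atlas, cfg)

one = rest["sub-0001"]
print(f"one resting run: {one.n_timepoints} timepoints x "
      f"{one.data.shape[1]} hROIs, TR = {one.tr} s")

metrics = langlat.connectivity_metrics(rest, atlas, band=(0.01, 0.1))
merged = metrics.merge(cohort, on="participant_id")
print("\ngroup means of the resting-state variables:")
print(
    merged.groupby("latent_group")[["rs_dc_mean", "rs_dc_asym", "mihhc_r"]]
    .mean().round(3).to_string()
)
# ATYP shows the highest mean degree centrality (~9.5, bilateral network)
# and the strongest homotopic correlation (~0.61), with no leftward Rs_DC
# asymmetry; both TYP groups are leftward-asymmetric (~+0.5).
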