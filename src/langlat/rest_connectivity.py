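"""Resting-state SENT_CORE connectivity metrics.

From an ROI-mean BOLD time-series matrix (timepoints x 36 hROIs) the module
computes, after nuisance regression and bandpass filtering:

* ``Rs_DC`` — degree centrality of each hROI, the sum of its *positive*
  Pearson correlations with the other hROIs of the same hemisphere
  (17 partners, so Rs_DC is bounded by [0, 17]); averaged over the 18
  hROIs of a hemisphere to give per-hemisphere values, their sum,
  asymmetry (left minus right) and mean.
* ``Rs_mIHHC`` — mean interhemispheric homotopic correlation: the Fisher
  z-transformed correlations between the 18 homotopic pairs are averaged
  on the z scale and back-transformed (tanh) for reporting on the r scale.

Cleaning follows the conventional order: confound regression (always with
intercept and linear trend) first, then a zero-phase least-squares
linear-phase FIR bandpass (default 0.01-0.1 Hz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import Atlas

__all__ = [
    "RestSeries",
    "design_bandpass",
    "clean_timeseries",
    "correlation_matrix",
    "rs_dc",
    "mihhc",
    "connectivity_metrics",
    "METRIC_COLUMNS",
]

log = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "participant_id",
    "rs_dc_left",
    "rs_dc_right",
    "rs_dc_sum",
    "rs_dc_asym",
    "rs_dc_mean",
    "mihhc_z",
    "mihhc_r",
)


@dataclass
class RestSeries:
    """ROI-mean BOLD time series for one participant.

    ``data`` columns must be the atlas column labels (``<pair>_L`` for all
    pairs, then ``<pair>_R``); ``tr`` is the repetition time in seconds.
    """

    participant_id: str
    data: pd.DataFrame
    tr: float = 2.0

    @property
    def n_timepoints(self) -> int:
        return len(self.data)

    def validate(self, atlas: Atlas, min_timepoints: int = 100) -> "RestSeries":
        expected = atlas.column_labels()
        if list(self.data.columns) != expected:
            raise ValueError(
                f"series {self.participant_id}: columns do not match atlas "
                f"(expected {len(expected)} labels {expected[:2]}...)"
            )
        if self.n_timepoints < min_timepoints:
            raise ValueError(
                f"series {self.participant_id}: only {self.n_timepoints} "
                f"timepoints (< {min_timepoints})"
            )
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError(f"series {self.participant_id}: non-finite values")
        return self


def design_bandpass(
    low_hz: float, high_hz: float, tr: float, numtaps: int | None = None
) -> np.ndarray:
    """Least-squares linear-phase FIR bandpass taps.

    The filter order defaults to about four cycles of the low cutoff
    (numtaps ~= 4 / (low_hz * tr), rounded up to odd) so that the slow edge
    of the passband is resolved.  Transition bands are half the low cutoff
    below it and 20% of the high cutoff above it.
    """
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must lie within (0, Nyquist={nyquist:g})"
        )
    if numtaps is None:
        numtaps = int(round(4.0 / (low_hz * tr)))
    if numtaps % 2 == 0:
        numtaps += 1
    lo_edge = low_hz / 2.0
    hi_edge = min(high_hz * 1.2, (high_hz + nyquist) / 2.0)
    # transition bands enter the least-squares fit as explicit ramps:
    # leaving them as don't-care regions lets the LS solution grow large
    # gain spikes there, which would dominate the filtered variance
    bands = [
        0.0, lo_edge,
        lo_edge, low_hz,
        low_hz, high_hz,
        high_hz, hi_edge,
        hi_edge, nyquist,
    ]
    desired = [0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=1.0 / tr)


def _confound_design(n: int, confounds: np.ndarray | None) -> np.ndarray:
    """Intercept + linear trend + user confounds, redundant columns dropped."""
    trend = np.linspace(-1.0, 1.0, n)
    cols = [np.ones(n), trend]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if len(confounds) != n:
            raise ValueError("confound matrix length does not match the series")
        cols.extend(confounds.T)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} redundant confound column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
    return X


def clean_timeseries(
    series: RestSeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
) -> RestSeries:
    """Confound-regress then bandpass a resting series (same shape out).

    Confound regression (ordinary least squares with intercept and linear
    trend always included) precedes filtering.  ``band=None`` skips the
    filter.  The FIR filter is applied forward-backward (zero phase), so the
    effective amplitude response is the squared magnitude of the design.
    """
    Y = series.data.to_numpy(dtype=float)
    n = len(Y)
    X = _confound_design(n, confounds)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if band is not None:
        taps = design_bandpass(band[0], band[1], series.tr)
        padlen = min(3 * len(taps), n - 1)
        resid = signal.filtfilt(taps, [1.0], resid, axis=0, padlen=padlen)
    cleaned = pd.DataFrame(resid, columns=series.data.columns, index=series.data.index)
    return RestSeries(series.participant_id, cleaned, tr=series.tr)


def correlation_matrix(series: RestSeries) -> pd.DataFrame:
    """Pearson correlation matrix across the series columns."""
    Y = series.data.to_numpy(dtype=float)
    sd = Y.std(axis=0)
    if np.any(sd == 0):
        dead = [c for c, s in zip(series.data.columns, sd) if s == 0]
        raise ValueError(
            f"series {series.participant_id}: zero-variance column(s) {dead}"
        )
    corr = np.corrcoef(Y, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    cols = list(series.data.columns)
    return pd.DataFrame(corr, index=cols, columns=cols)


def _hemi_labels(atlas: Atlas, hemisphere: str) -> list[str]:
    suffix = {"left": "L", "right": "R"}[hemisphere]
    return [f"{p}_{suffix}" for p in atlas.pair_names]


def rs_dc(
    corr: pd.DataFrame,
    atlas: Atlas,
    hemisphere: str,
    partners: str = "ipsilateral",
) -> tuple[pd.Series, float]:
    """Per-hROI degree centrality and its hemisphere mean.

    DC of an hROI is the sum of positive correlations with its partner
    hROIs — by default the other hROIs of the same hemisphere (the reading
    consistent with "intra-hemispheric" degree centrality); ``partners="all"``
    includes contralateral hROIs as well.
    """
    labels = _hemi_labels(atlas, hemisphere)
    if partners == "ipsilateral":
        partner_labels = labels
    elif partners == "all":
        partner_labels = atlas.column_labels()
    else:
        raise ValueError(f"partners must be 'ipsilateral' or 'all', got {partners!r}")
    block = corr.loc[labels, partner_labels].to_numpy(dtype=float).copy()
    for i, lab in enumerate(labels):
        block[i, partner_labels.index(lab)] = 0.0  # exclude self-correlation
    dc = np.maximum(block, 0.0).sum(axis=1)
    per_roi = pd.Series(dc, index=labels)
    return per_roi, float(dc.mean())


def mihhc(corr: pd.DataFrame, atlas: Atlas) -> tuple[float, float]:
    """Mean interhemispheric homotopic correlation (Fisher-z mean, r value)."""
    rs = np.array(
        [corr.loc[f"{p}_L", f"{p}_R"] for p in atlas.pair_names], dtype=float
    )
    if np.any(np.abs(rs) >= 1.0):
        bad = [p for p, r in zip(atlas.pair_names, rs) if abs(r) >= 1.0]
        raise ValueError(f"homotopic correlation of +/-1 for pair(s) {bad}")
    z = float(np.arctanh(rs).mean())
    return z, float(np.tanh(z))


def connectivity_metrics(
    series_map: dict[str, RestSeries],
    atlas: Atlas,
    band: tuple[float, float] | None = (0.01, 0.1),
    confounds: dict[str, np.ndarray] | None = None,
    dc_partners: str = "ipsilateral",
) -> pd.DataFrame:
    """Clean every series and compute the full metric table.

    Returns one row per participant with columns ``rs_dc_left, rs_dc_right,
    rs_dc_sum, rs_dc_asym, rs_dc_mean, mihhc_z, mihhc_r``.
    """
    rows = []
    for pid, series in series_map.items():
        series.validate(atlas)
        conf = confounds.get(pid) if confounds else None
        cleaned = clean_timeseries(series, confounds=conf, band=band)
        corr = correlation_matrix(cleaned)
        _, dc_left = rs_dc(corr, atlas, "left", partners=dc_partners)
        _, dc_right = rs_dc(corr, atlas, "right", partners=dc_partners)
        z, r = mihhc(corr, atlas)
        rows.append(
            {
                "participant_id": pid,
                "rs_dc_left": dc_left,
                "rs_dc_right": dc_right,
                "rs_dc_sum": dc_left + dc_right,
                "rs_dc_asym": dc_left - dc_right,
                "rs_dc_mean": (dc_left + dc_right) / 2.0,
                "mihhc_z": z,
                "mihhc_r": r,
            }
        )
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
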