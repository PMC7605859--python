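"""Synthetic cohort generator.

Emulates a 287-participant cohort (150 left-handers, 140 women) with three
latent language-organization phenotypes — TYP_STRONG (n=125), TYP_MILD
(n=132) and ATYP (n=30) — and a planted minority of CROSSED (dissociated)
individuals (2 / 9 / 12 per group, 17 of the 23 left-handed).  All default
calibration constants are the published group-level tables of the study the
pipeline reproduces:

* task-asymmetry targets per group x task x region set (network means/sds),
* resting-state degree-centrality and homotopic-correlation levels,
* grey/white-matter and corpus-callosum anatomy per organization x
  dissociation cell,
* an 11-test cognitive battery with a 4-factor latent structure.

The generator is quota-exact (group sizes, handedness, sex and dissociation
counts are fixed counts, not Bernoulli draws) and fully deterministic given
``CohortConfig.seed``; every sub-generator draws from an independent child
stream of that seed.

Task contrasts are built so that the volumetric-mean network asymmetry
recomputed from the per-hROI values reproduces each participant's drawn
target exactly: pair differences solve the weighted-mean constraint in
closed form and the added per-hROI noise has zero volume-weighted sum within
each region subset.  CROSSED participants receive truncated-normal targets
planted beyond the 0.05 band in the documented subtype patterns, and the
CONGRUENT cell means are analytically re-centred so that every group-level
table cell remains the mixture mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .atlas import Atlas
from .classifier import GROUPS
from .rest_connectivity import RestSeries
from .task_asymmetry import ROI_SETS, TASKS

__all__ = [
    "CohortConfig",
    "RestTemplate",
    "default_config",
    "generate_cohort",
    "calibrate_rest_template",
    "generate_rest_timeseries",
    "generate_task_contrasts",
    "generate_cognitive_scores",
    "generate_anatomy",
    "generate_external_labels",
    "TABLE_TASK_PARAMS",
    "TABLE_REST_PARAMS",
    "COGNITIVE_TESTS",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or infeasible cohort configuration."""


# --------------------------------------------------------------------------
# Published calibration constants
# --------------------------------------------------------------------------

#: group -> (roi_set, task) -> (mean, sd) of the signed network asymmetry.
TABLE_TASK_PARAMS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "TYP_STRONG": {
        ("CORE", "PROD"): (0.557, 0.17),
        ("CORE", "LISN"): (0.299, 0.13),
        ("CORE", "READ"): (0.351, 0.18),
        ("HUBS", "PROD"): (0.80, 0.23),
        ("HUBS", "LISN"): (0.42, 0.19),
        ("HUBS", "READ"): (0.51, 0.29),
    },
    "TYP_MILD": {
        ("CORE", "PROD"): (0.296, 0.12),
        ("CORE", "LISN"): (0.167, 0.09),
        ("CORE", "READ"): (0.217, 0.14),
        ("HUBS", "PROD"): (0.391, 0.18),
        ("HUBS", "LISN"): (0.210, 0.15),
        ("HUBS", "READ"): (0.287, 0.23),
    },
    "ATYP": {
        ("CORE", "PROD"): (-0.114, 0.19),
        ("CORE", "LISN"): (-0.155, 0.17),
        ("CORE", "READ"): (-0.177, 0.15),
        ("HUBS", "PROD"): (-0.119, 0.30),
        ("HUBS", "LISN"): (-0.291, 0.28),
        ("HUBS", "READ"): (-0.358, 0.30),
    },
}

#: group -> (target mean left Rs_DC, right Rs_DC, homotopic correlation).
#: Left/right levels derive from the published mean Rs_DC and its asymmetry.
TABLE_REST_PARAMS: dict[str, tuple[float, float, float]] = {
    "TYP_STRONG": (8.920, 8.420, 0.571),
    "TYP_MILD": (8.188, 7.710, 0.578),
    "ATYP": (9.3765, 9.5435, 0.610),
}

#: group -> published between-participant sds of (mean Rs_DC, Rs_DC
#: asymmetry, Rs_mIHHC); the participant-level jitter is calibrated so the
#: generated sds meet these at the network level.
TABLE_REST_SDS: dict[str, tuple[float, float, float]] = {
    "TYP_STRONG": (1.42, 0.77, 0.07),
    "TYP_MILD": (1.24, 0.64, 0.07),
    "ATYP": (1.60, 0.78, 0.06),
}

#: Approximate sampling contribution (finite 240-timepoint, bandpassed run)
#: to the per-participant sd of (mean Rs_DC, Rs_DC asym, Rs_mIHHC); removed
#: from the published sds before sizing the correlation-level jitter.
_REST_SAMPLING_SD = (0.30, 0.42, 0.015)

COGNITIVE_TESTS = (
    "word_learning",
    "pseudoword_learning",
    "verbal_fluency",
    "reading_span",
    "listening_span",
    "vocabulary",
    "rhyming",
    "mental_rotation",
    "corsi_blocks",
    "maze",
    "raven_matrices",
)

#: test -> group -> (mean, sd), groups in GROUPS order.
TABLE_COGNITION: dict[str, tuple[tuple[float, float], ...]] = {
    "word_learning": ((65.98, 7.57), (65.07, 7.51), (64.73, 7.57)),
    "pseudoword_learning": ((36.52, 10.44), (34.64, 11.16), (34.47, 9.68)),
    "verbal_fluency": ((48.19, 9.82), (46.55, 10.01), (47.63, 8.85)),
    "reading_span": ((4.07, 1.08), (3.91, 1.11), (4.25, 1.11)),
    "listening_span": ((4.85, 1.06), (4.57, 1.14), (4.63, 1.21)),
    "vocabulary": ((28.39, 3.78), (27.80, 3.74), (28.07, 4.42)),
    "rhyming": ((68.38, 4.56), (67.17, 6.11), (65.93, 5.62)),
    "mental_rotation": ((11.08, 4.27), (10.70, 4.60), (10.17, 4.63)),
    "corsi_blocks": ((5.99, 1.06), (5.72, 1.04), (5.73, 0.94)),
    "maze": ((6.68, 2.66), (6.09, 2.32), (4.42, 2.39)),
    "raven_matrices": ((111.78, 9.70), (109.82, 10.47), (106.00, 9.48)),
}

FACTORS = ("SPA", "PHONO", "MEM", "VERB")

#: 11 x 4 loading pattern (tests in COGNITIVE_TESTS order).
DEFAULT_LOADINGS = np.array(
    [
        # SPA  PHONO  MEM   VERB
        [0.00, 0.00, 0.77, 0.00],  # word learning
        [0.00, 0.48, 0.49, 0.00],  # pseudoword learning
        [0.00, 0.00, 0.00, 0.64],  # verbal fluency
        [0.00, 0.00, 0.00, 0.34],  # reading span
        [0.00, 0.00, 0.00, 0.31],  # listening span
        [0.00, 0.36, 0.00, 0.31],  # vocabulary
        [0.00, 0.72, 0.00, 0.00],  # rhyming
        [0.62, 0.00, 0.00, 0.00],  # mental rotation
        [0.39, 0.00, 0.00, 0.00],  # corsi blocks
        [0.60, 0.00, 0.00, 0.00],  # maze
        [0.68, 0.00, 0.00, 0.00],  # raven matrices
    ]
)

#: factor -> per-group latent mean shift (estimated component means).
DEFAULT_FACTOR_SHIFTS: dict[str, tuple[float, float, float]] = {
    "SPA": (0.29, -0.19, -0.41),
    "PHONO": (0.0, 0.0, 0.0),
    "MEM": (0.05, 0.19, -0.57),
    "VERB": (0.0, 0.0, 0.0),
}

#: (organization, dissociation) -> anatomy cell parameters, volumes in cc.
TABLE_ANATOMY: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("TYP", "CONGRUENT"): {
        "gm_base": (321.32, 32.0),
        "gm_asym": (11.35, 4.00),
        "wm_base": (215.03, 25.5),
        "wm_asym": (3.33, 2.19),
        "cc": (5.31, 0.85),
    },
    ("TYP", "CROSSED"): {
        "gm_base": (331.66, 47.5),
        "gm_asym": (11.87, 4.50),
        "wm_base": (219.87, 35.5),
        "wm_asym": (4.11, 1.74),
        "cc": (5.21, 0.67),
    },
    ("ATYP", "CONGRUENT"): {
        "gm_base": (332.60, 34.0),
        "gm_asym": (9.65, 5.03),
        "wm_base": (221.33, 25.5),
        "wm_asym": (2.22, 2.41),
        "cc": (5.45, 0.90),
    },
    ("ATYP", "CROSSED"): {
        "gm_base": (311.89, 15.5),
        "gm_asym": (10.82, 3.82),
        "wm_base": (207.50, 14.5),
        "wm_asym": (2.23, 2.03),
        "cc": (5.48, 0.74),
    },
}

# named child-seed streams of the master seed
_STREAMS = {
    "cohort": 0,
    "contrasts": 1,
    "rest": 2,
    "cognition": 3,
    "anatomy": 4,
    "external": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """All tunable knobs of the synthetic cohort, with published defaults."""

    seed: int = 0
    n_total: int = 287
    group_sizes: dict = field(
        default_factory=lambda: {"TYP_STRONG": 125, "TYP_MILD": 132, "ATYP": 30}
    )
    left_handers: dict = field(
        default_factory=lambda: {"TYP_STRONG": 58, "TYP_MILD": 67, "ATYP": 25}
    )
    females: dict = field(
        default_factory=lambda: {"TYP_STRONG": 48, "TYP_MILD": 77, "ATYP": 15}
    )
    crossed: dict = field(
        default_factory=lambda: {"TYP_STRONG": 2, "TYP_MILD": 9, "ATYP": 12}
    )
    crossed_left_handers: dict = field(
        default_factory=lambda: {"TYP_STRONG": 1, "TYP_MILD": 6, "ATYP": 10}
    )
    atyp_reverse_crossed: int = 3  # of the 12 crossed ATYP: rightward PROD

    # demographics
    age_mean: float = 25.8
    age_sd: float = 6.5
    education_mean: float = 15.6
    education_sd: float = 2.3
    edinburgh_left: tuple = (-63.2, 39.9)
    edinburgh_right: tuple = (90.0, 12.0)
    tiv_mean: float = 1350.0
    tiv_sd: float = 110.0
    tiv_male_shift: float = 100.0

    # task contrasts
    task_asym_params: dict = field(
        default_factory=lambda: {
            g: dict(cells) for g, cells in TABLE_TASK_PARAMS.items()
        }
    )
    # Within-group residual correlations of the six asymmetry targets.  The
    # published sds are within-cluster residual spreads: the shared
    # lateralization trait is absorbed by the group means, so the residuals
    # are modeled independent by default.  Positive values re-introduce a
    # common within-cluster trait across tasks / region sets.
    task_corr: float = 0.0  # cross-task correlation of residual targets
    roi_set_corr: float = 0.0  # core-hub residual correlation within a task
    roi_noise_sd: float = 0.15  # per-hROI difference noise (zero weighted sum)
    base_mean: float = 1.0  # mean per-pair activation level
    base_sd: float = 0.3
    threshold: float = 0.05  # dissociation band used for planting/rejection

    # resting state
    rest_params: dict = field(
        default_factory=lambda: {g: v for g, v in TABLE_REST_PARAMS.items()}
    )
    n_timepoints: int = 240
    tr: float = 2.0
    heterotopic_ratio: float = 0.8
    #: group -> target between-participant sds (mean DC, DC asym, mihhc);
    #: converted internally to correlation-level jitter sds.
    rest_sds: dict = field(
        default_factory=lambda: {g: v for g, v in TABLE_REST_SDS.items()}
    )

    # cognition
    loading_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_LOADINGS.copy()
    )
    factor_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_SHIFTS)
    )
    # Multiplier on the uniqueness (residual) sd of each test score.  The
    # canonical unit-variance split (1 - communality) puts the weakest
    # printed component right at the detection edge of an 11-variable PCA at
    # n = 287; a slightly tighter uniqueness keeps the planted 4-component
    # structure recoverable, which the calibration requires.  Table-level
    # score scales are unaffected (scores are rescaled afterwards).
    cognition_noise: float = 0.9
    covariate_betas: dict = field(
        default_factory=lambda: {
            "age": -0.01,  # per year (centred), in z units
            "education": 0.04,
            "female": 0.05,
            "left_handed": 0.0,
        }
    )

    def validate(self) -> "CohortConfig":
        if sorted(self.group_sizes) != sorted(GROUPS):
            raise ConfigError(f"group_sizes must cover {GROUPS}")
        if sum(self.group_sizes.values()) != self.n_total:
            raise ConfigError("group sizes must sum to n_total")
        for name, quota in (
            ("left_handers", self.left_handers),
            ("females", self.females),
            ("crossed", self.crossed),
        ):
            for g in GROUPS:
                if not 0 <= quota[g] <= self.group_sizes[g]:
                    raise ConfigError(f"{name}[{g}]={quota[g]} infeasible")
        for g in GROUPS:
            if not 0 <= self.crossed_left_handers[g] <= min(
                self.crossed[g], self.left_handers[g]
            ):
                raise ConfigError(f"crossed_left_handers[{g}] infeasible")
        if not 0 <= self.atyp_reverse_crossed <= self.crossed["ATYP"]:
            raise ConfigError("atyp_reverse_crossed infeasible")
        n_pairs = 18
        for g, (dcl, dcr, ihc) in self.rest_params.items():
            if not (0 <= dcl <= n_pairs - 1 and 0 <= dcr <= n_pairs - 1):
                raise ConfigError(f"rest DC target out of [0, {n_pairs - 1}] for {g}")
            if not abs(ihc) < 1:
                raise ConfigError(f"|mihhc| must be < 1 for {g}")
        if np.asarray(self.loading_matrix).shape != (11, 4):
            raise ConfigError("loading matrix must be 11 x 4")
        if self.n_timepoints < 100:
            raise ConfigError("n_timepoints must be >= 100")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loading_matrix"] = np.asarray(self.loading_matrix).tolist()
        d["task_asym_params"] = {
            g: {f"{rs}_{t}": list(v) for (rs, t), v in cells.items()}
            for g, cells in self.task_asym_params.items()
        }
        d["rest_params"] = {g: list(v) for g, v in self.rest_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "loading_matrix" in d:
            d["loading_matrix"] = np.asarray(d["loading_matrix"], dtype=float)
        if "task_asym_params" in d:
            d["task_asym_params"] = {
                g: {
                    tuple(key.split("_", 1)): tuple(v)
                    for key, v in cells.items()
                }
                for g, cells in d["task_asym_params"].items()
            }
        if "rest_params" in d:
            d["rest_params"] = {g: tuple(v) for g, v in d["rest_params"].items()}
        if "edinburgh_left" in d:
            d["edinburgh_left"] = tuple(d["edinburgh_left"])
        if "edinburgh_right" in d:
            d["edinburgh_right"] = tuple(d["edinburgh_right"])
        return cls(**d).validate()


def default_config(seed: int = 0) -> CohortConfig:
    """The published-cohort calibration with a chosen master seed."""
    return CohortConfig(seed=seed).validate()


# --------------------------------------------------------------------------
# Participants
# --------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Participant table with exact quota counts and latent truth columns."""
    config.validate()
    rng = _rng(config.seed, "cohort")
    rows = []
    counter = 0
    for g in GROUPS:
        n = config.group_sizes[g]
        n_lh = config.left_handers[g]
        n_f = config.females[g]
        n_cross = config.crossed[g]
        n_cross_lh = config.crossed_left_handers[g]

        hand = np.array(["L"] * n_lh + ["R"] * (n - n_lh))
        sex = np.full(n, "M")
        sex[rng.choice(n, size=n_f, replace=False)] = "F"
        crossed = np.zeros(n, dtype=bool)
        lh_idx = np.arange(n_lh)
        rh_idx = np.arange(n_lh, n)
        crossed[rng.choice(lh_idx, size=n_cross_lh, replace=False)] = True
        crossed[rng.choice(rh_idx, size=n_cross - n_cross_lh, replace=False)] = True

        subtype = np.full(n, "", dtype=object)
        cross_idx = np.where(crossed)[0]
        if g == "ATYP":
            rev = rng.choice(
                cross_idx, size=config.atyp_reverse_crossed, replace=False
            )
            subtype[cross_idx] = "prod_left"
            subtype[rev] = "prod_right"
        elif g == "TYP_MILD":
            subtype[cross_idx] = "flip_read"
        else:
            subtype[cross_idx] = "flip_lisn"

        edinburgh = np.where(
            hand == "L",
            rng.normal(*config.edinburgh_left, size=n),
            rng.normal(*config.edinburgh_right, size=n),
        ).clip(-100, 100)
        age = rng.normal(config.age_mean, config.age_sd, size=n).clip(18, None)
        education = rng.normal(
            config.education_mean, config.education_sd, size=n
        ).clip(8, None)
        tiv = rng.normal(config.tiv_mean, config.tiv_sd, size=n) + np.where(
            sex == "M", config.tiv_male_shift, 0.0
        )

        for i in range(n):
            counter += 1
            rows.append(
                {
                    "participant_id": f"sub-{counter:04d}",
                    "latent_group": g,
                    "handedness": hand[i],
                    "sex": sex[i],
                    "edinburgh": round(float(edinburgh[i]), 1),
                    "age": round(float(age[i]), 1),
                    "education": round(float(education[i]), 1),
                    "total_intracranial_volume": round(float(tiv[i]), 1),
                    "latent_dissociation": "CROSSED" if crossed[i] else "CONGRUENT",
                    "crossed_subtype": subtype[i],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Task-contrast targets
# --------------------------------------------------------------------------

CELLS = tuple((rs, t) for rs in ROI_SETS for t in TASKS)

_TruncSpec = tuple  # ("norm", mu, sd) | ("trunc", lo, hi, mu, sd)


def _spec_mean(spec: _TruncSpec) -> float:
    if spec[0] == "norm":
        return spec[1]
    _, lo, hi, mu, sd = spec
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.mean(a, b, loc=mu, scale=sd))


def _spec_draw(spec: _TruncSpec, rng: np.random.Generator) -> float:
    if spec[0] == "norm":
        return float(rng.normal(spec[1], spec[2]))
    _, lo, hi, mu, sd = spec
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def _crossed_specs(group: str, subtype: str, params, margin: float) -> dict:
    """Per-cell target distributions for a planted CROSSED subtype."""
    inf = np.inf
    specs: dict[tuple[str, str], _TruncSpec] = {}
    if group == "ATYP":
        if subtype == "prod_left":
            specs[("CORE", "PROD")] = ("trunc", margin, inf, 0.20, 0.10)
            specs[("HUBS", "PROD")] = ("trunc", margin, inf, 0.25, 0.12)
            for rs in ROI_SETS:
                for t in ("LISN", "READ"):
                    mu, sd = params[(rs, t)]
                    specs[(rs, t)] = ("trunc", -inf, -margin, mu, sd)
        else:  # prod_right: the reverse, rarer pattern
            for rs in ROI_SETS:
                mu, sd = params[(rs, "PROD")]
                specs[(rs, "PROD")] = ("trunc", -inf, -margin, mu, sd)
            specs[("CORE", "LISN")] = ("trunc", margin, inf, 0.15, 0.08)
            specs[("CORE", "READ")] = ("trunc", margin, inf, 0.15, 0.08)
            specs[("HUBS", "LISN")] = ("trunc", margin, inf, 0.20, 0.10)
            specs[("HUBS", "READ")] = ("trunc", margin, inf, 0.20, 0.10)
    else:
        flip = "READ" if subtype == "flip_read" else "LISN"
        weak = (-0.10, 0.04) if group == "TYP_MILD" else (-0.08, 0.03)
        band = margin - 0.011  # stay inside the neutral band
        for (rs, t) in CELLS:
            mu, sd = params[(rs, t)]
            if t == flip:
                if rs == "HUBS":
                    specs[(rs, t)] = ("trunc", -inf, -margin, weak[0], weak[1])
                else:
                    specs[(rs, t)] = ("trunc", -band, band, 0.0, 0.05)
            else:
                specs[(rs, t)] = ("trunc", margin, inf, mu, sd)
    return specs


def _congruent_means(group: str, config: CohortConfig) -> dict:
    """Re-centred CONGRUENT cell means so the mixture hits the table means."""
    params = config.task_asym_params[group]
    n = config.group_sizes[group]
    margin = config.threshold + 0.01
    subtype_counts: dict[str, int] = {}
    if group == "ATYP":
        subtype_counts["prod_left"] = config.crossed[group] - config.atyp_reverse_crossed
        subtype_counts["prod_right"] = config.atyp_reverse_crossed
    elif config.crossed[group]:
        subtype_counts["flip_read" if group == "TYP_MILD" else "flip_lisn"] = (
            config.crossed[group]
        )
    subtype_counts = {st: c for st, c in subtype_counts.items() if c > 0}
    n_cong = n - sum(subtype_counts.values())
    means = {}
    for cell in CELLS:
        mu_table, _ = params[cell]
        planted = sum(
            cnt * _spec_mean(_crossed_specs(group, st, params, margin)[cell])
            for st, cnt in subtype_counts.items()
        )
        means[cell] = (n * mu_table - planted) / n_cong
    return means


def _corr6(task_corr: float, roi_corr: float) -> np.ndarray:
    t = np.full((3, 3), task_corr)
    np.fill_diagonal(t, 1.0)
    s = np.array([[1.0, roi_corr], [roi_corr, 1.0]])
    return np.kron(s, t)


def _draw_congruent_targets(
    mu: np.ndarray,
    sd: np.ndarray,
    chol: np.ndarray,
    rng: np.random.Generator,
    threshold: float,
    rule: str = "both_poles",
    max_tries: int = 200,
) -> np.ndarray:
    """Correlated targets for a CONGRUENT member, rejected if crossed."""
    from .classifier import _is_crossed

    for _ in range(max_tries):
        z = chol @ rng.standard_normal(6)
        vals = mu + sd * z
        by_set = {"CORE": vals[:3], "HUBS": vals[3:]}
        if not _is_crossed(by_set, threshold, rule):
            return vals
    # fallback: clamp the minority-direction values into the neutral band
    dominant = np.sign(vals.sum()) or 1.0
    clamp = (threshold - 0.001) * (-dominant)
    offending = np.sign(vals) == -dominant
    beyond = np.abs(vals) >= threshold
    vals[offending & beyond] = clamp
    return vals


def draw_asymmetry_targets(
    cohort: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Per-participant target network asymmetries for all 6 cells."""
    rng = _rng(config.seed, "contrasts")
    chol = np.linalg.cholesky(_corr6(config.task_corr, config.roi_set_corr))
    margin = config.threshold + 0.01
    cong_means = {g: _congruent_means(g, config) for g in GROUPS}
    records = []
    for _, person in cohort.iterrows():
        g = person["latent_group"]
        params = config.task_asym_params[g]
        if person["latent_dissociation"] == "CROSSED":
            specs = _crossed_specs(g, person["crossed_subtype"], params, margin)
            vals = np.array([_spec_draw(specs[c], rng) for c in CELLS])
        else:
            mu = np.array([cong_means[g][c] for c in CELLS])
            sd = np.array([params[c][1] for c in CELLS])
            vals = _draw_congruent_targets(
                mu, sd, chol, rng, config.threshold
            )
        rec = {"participant_id": person["participant_id"]}
        rec.update({f"{rs}_{t}": v for (rs, t), v in zip(CELLS, vals)})
        records.append(rec)
    return pd.DataFrame(records)


def generate_task_contrasts(
    cohort: pd.DataFrame,
    atlas: Atlas,
    config: CohortConfig,
    return_targets: bool = False,
):
    """hROI-level BOLD contrast table whose network asymmetries equal the
    drawn per-participant targets exactly."""
    config.validate()
    targets = draw_asymmetry_targets(cohort, config)
    rng = _rng(config.seed, "contrasts").spawn(1)[0]

    pairs = list(atlas.pair_names)
    w = np.array([atlas.pair_volume(p) for p in pairs])
    hub = np.array([p in atlas.hub_names for p in pairs])
    w_tot, w_hub, w_non = w.sum(), w[hub].sum(), w[~hub].sum()

    n_pairs = len(pairs)
    frames = []
    for _, trow in targets.iterrows():
        pid = trow["participant_id"]
        for task in TASKS:
            a_core = trow[f"CORE_{task}"]
            a_hubs = trow[f"HUBS_{task}"]
            d = np.empty(n_pairs)
            d[hub] = a_hubs
            d[~hub] = (a_core * w_tot - a_hubs * w_hub) / w_non
            noise = rng.normal(0.0, config.roi_noise_sd, size=n_pairs)
            for mask in (hub, ~hub):  # zero volume-weighted sum per subset
                noise[mask] -= np.dot(w[mask], noise[mask]) / w[mask].sum()
            d = d + noise
            base = rng.normal(config.base_mean, config.base_sd, size=n_pairs)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "task": task,
                        "pair_name": pairs * 2,
                        "hemisphere": ["L"] * n_pairs + ["R"] * n_pairs,
                        "bold": np.concatenate([base + d / 2.0, base - d / 2.0]),
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    if return_targets:
        return table, targets
    return table


# --------------------------------------------------------------------------
# Resting state
# --------------------------------------------------------------------------


@dataclass
class RestTemplate:
    """Block-correlation template for one phenotype group."""

    within_left_r: float
    within_right_r: float
    homotopic_r: float
    heterotopic_r: float
    n_timepoints: int = 240
    tr: float = 2.0
    n_pairs: int = 18

    def matrix(self) -> np.ndarray:
        return _block_matrix(
            self.within_left_r,
            self.within_right_r,
            self.homotopic_r,
            self.heterotopic_r,
            self.n_pairs,
        )


def _block_matrix(wl: float, wr: float, hom: float, het: float, n_pairs: int) -> np.ndarray:
    n = 2 * n_pairs
    m = np.empty((n, n))
    m[:n_pairs, :n_pairs] = wl
    m[n_pairs:, n_pairs:] = wr
    m[:n_pairs, n_pairs:] = het
    m[n_pairs:, :n_pairs] = het
    idx = np.arange(n_pairs)
    m[idx, idx + n_pairs] = hom
    m[idx + n_pairs, idx] = hom
    np.fill_diagonal(m, 1.0)
    return m


def _nearest_psd(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by rescaling to unit diagonal."""
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= floor:
        return m
    repaired = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _expected_metrics(m: np.ndarray, n_pairs: int) -> tuple[float, float, float]:
    """Expected (dc_left, dc_right, mihhc_r) of a template matrix."""
    left = m[:n_pairs, :n_pairs]
    right = m[n_pairs:, n_pairs:]
    off = ~np.eye(n_pairs, dtype=bool)
    dc_l = np.maximum(left[off].reshape(n_pairs, n_pairs - 1), 0).sum(axis=1).mean()
    dc_r = np.maximum(right[off].reshape(n_pairs, n_pairs - 1), 0).sum(axis=1).mean()
    hom = np.diag(m[:n_pairs, n_pairs:])
    mih = float(np.tanh(np.arctanh(hom).mean()))
    return float(dc_l), float(dc_r), mih


def calibrate_rest_template(
    target_mean_dc_left: float,
    target_mean_dc_right: float,
    target_mihhc: float,
    n_timepoints: int = 240,
    tr: float = 2.0,
    heterotopic_ratio: float = 0.8,
    n_pairs: int = 18,
) -> RestTemplate:
    """Invert the degree-centrality definition for a uniform-block template.

    With a uniform positive within-hemisphere correlation r among the
    ``n_pairs`` ipsilateral hROIs, each hROI's DC is (n_pairs - 1) * r, so
    r = target / (n_pairs - 1).  The homotopic correlation equals the target
    mIHHC directly; heterotopic entries default to 0.8 x homotopic (they do
    not enter any metric and only matter for positive semi-definiteness).
    """
    lim = n_pairs - 1
    if not (0 <= target_mean_dc_left <= lim and 0 <= target_mean_dc_right <= lim):
        raise ValueError(f"target mean DC must be within [0, {lim}]")
    if not abs(target_mihhc) < 1:
        raise ValueError("|target_mihhc| must be < 1")
    tpl = RestTemplate(
        within_left_r=target_mean_dc_left / lim,
        within_right_r=target_mean_dc_right / lim,
        homotopic_r=target_mihhc,
        heterotopic_r=heterotopic_ratio * target_mihhc,
        n_timepoints=n_timepoints,
        tr=tr,
        n_pairs=n_pairs,
    )
    m = tpl.matrix()
    # positive semi-definite is acceptable as-is (e.g. within_r = 1.0);
    # repair only a genuinely indefinite template
    if np.linalg.eigvalsh(m).min() >= -1e-10:
        return tpl
    repaired = _nearest_psd(m)
    if repaired is not m:
        got = _expected_metrics(repaired, n_pairs)
        want = (target_mean_dc_left, target_mean_dc_right, target_mihhc)
        if max(abs(g - t) for g, t in zip(got, want)) > 0.05:
            raise ValueError(
                f"PSD repair moved template metrics beyond 0.05: {got} vs {want}"
            )
        log.warning("rest template repaired to nearest PSD")
    return tpl


def group_rest_templates(config: CohortConfig) -> dict[str, RestTemplate]:
    return {
        g: calibrate_rest_template(
            *config.rest_params[g],
            n_timepoints=config.n_timepoints,
            tr=config.tr,
            heterotopic_ratio=config.heterotopic_ratio,
        )
        for g in GROUPS
    }


def generate_rest_timeseries(
    cohort: pd.DataFrame,
    atlas: Atlas,
    config: CohortConfig,
    templates: dict[str, RestTemplate] | None = None,
) -> dict[str, RestSeries]:
    """Zero-mean Gaussian ROI series per participant from the group template.

    Participant-level jitter perturbs the template's correlation levels
    through a common within-hemisphere shift, a left/right differential
    shift, and a homotopic shift, with sds calibrated so that the generated
    between-participant spreads of mean Rs_DC, Rs_DC asymmetry and Rs_mIHHC
    meet the published group sds (``config.rest_sds``) after accounting for
    the finite-run sampling noise.
    """
    config.validate()
    if templates is None:
        templates = group_rest_templates(config)
    rng = _rng(config.seed, "rest")
    columns = atlas.column_labels()
    n_pairs = atlas.n_pairs
    lim = n_pairs - 1
    jitter_sds = {}
    for g, (sd_mean, sd_asym, sd_ihc) in config.rest_sds.items():
        s0, s1, s2 = _REST_SAMPLING_SD
        jitter_sds[g] = (
            np.sqrt(max(sd_mean**2 - s0**2, 0.0)) / lim,  # common shift
            np.sqrt(max(sd_asym**2 - s1**2, 0.0)) / (2 * lim),  # differential
            np.sqrt(max(sd_ihc**2 - s2**2, 0.0)),  # homotopic
        )
    out: dict[str, RestSeries] = {}
    for _, person in cohort.iterrows():
        tpl = templates[person["latent_group"]]
        sd_c, sd_a, sd_h = jitter_sds[person["latent_group"]]
        raw = rng.standard_normal(3)
        jitter = np.array([sd_c, sd_a, sd_h]) * raw
        # shrink the jitter (not the template) until the matrix stays PSD,
        # so the clipping cannot bias the group-level expectations
        for _ in range(20):
            d_c, d_a, d_hom = jitter
            wl = float(np.clip(tpl.within_left_r + d_c + d_a, 0.0, 0.95))
            wr = float(np.clip(tpl.within_right_r + d_c - d_a, 0.0, 0.95))
            hom = float(np.clip(tpl.homotopic_r + d_hom, -0.95, 0.95))
            m = _block_matrix(wl, wr, hom, config.heterotopic_ratio * hom, n_pairs)
            if np.linalg.eigvalsh(m).min() >= 1e-8:
                break
            jitter *= 0.7
            log.debug(
                "jitter for %s re-clipped to keep the template PSD",
                person["participant_id"],
            )
        else:
            m = tpl.matrix()
        chol = np.linalg.cholesky(m + 1e-10 * np.eye(len(m)))
        series = rng.standard_normal((config.n_timepoints, 2 * n_pairs)) @ chol.T
        out[person["participant_id"]] = RestSeries(
            person["participant_id"],
            pd.DataFrame(series, columns=columns),
            tr=config.tr,
        )
    return out


# --------------------------------------------------------------------------
# Cognition
# --------------------------------------------------------------------------


def generate_cognitive_scores(
    cohort: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """11 battery scores per participant from a 4-factor latent model.

    score_t = pooled_mean_t + z_t * pooled_sd_t with
    z = covariate effects + loadings @ factors + uniqueness noise, the
    factor means shifted per latent group (``factor_shifts``).
    """
    config.validate()
    rng = _rng(config.seed, "cognition")
    lam = np.asarray(config.loading_matrix, dtype=float)
    n = len(cohort)
    gidx = cohort["latent_group"].map({g: i for i, g in enumerate(GROUPS)}).to_numpy()
    shifts = np.column_stack(
        [np.asarray(config.factor_shifts[f])[gidx] for f in FACTORS]
    )
    factors = shifts + rng.standard_normal((n, 4))
    uniq_sd = np.sqrt(np.clip(1.0 - (lam**2).sum(axis=1), 0.0, None))
    noise = rng.standard_normal((n, 11)) * uniq_sd * config.cognition_noise

    betas = config.covariate_betas
    age_c = cohort["age"].to_numpy() - config.age_mean
    edu_c = cohort["education"].to_numpy() - config.education_mean
    female = (cohort["sex"] == "F").to_numpy(float)
    lh = (cohort["handedness"] == "L").to_numpy(float)
    cov = (
        betas["age"] * age_c
        + betas["education"] * edu_c
        + betas["female"] * female
        + betas["left_handed"] * lh
    )
    z = cov[:, None] + factors @ lam.T + noise

    sizes = np.array([config.group_sizes[g] for g in GROUPS], dtype=float)
    out = {"participant_id": cohort["participant_id"].to_numpy()}
    for j, test in enumerate(COGNITIVE_TESTS):
        cells = TABLE_COGNITION[test]
        pooled_mean = float(np.dot(sizes, [c[0] for c in cells]) / sizes.sum())
        pooled_sd = float(np.dot(sizes, [c[1] for c in cells]) / sizes.sum())
        out[test] = pooled_mean + z[:, j] * pooled_sd
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Anatomy
# --------------------------------------------------------------------------


def generate_anatomy(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """GM/WM hemispheric volumes and corpus-callosum volume (cc) per cell.

    left = base + asym/2 and right = base - asym/2, so left - right equals
    the drawn asymmetry exactly.
    """
    config.validate()
    rng = _rng(config.seed, "anatomy")
    rows = []
    for _, person in cohort.iterrows():
        org = "ATYP" if person["latent_group"] == "ATYP" else "TYP"
        cell = TABLE_ANATOMY[(org, person["latent_dissociation"])]
        gm_base = rng.normal(*cell["gm_base"])
        gm_asym = rng.normal(*cell["gm_asym"])
        wm_base = rng.normal(*cell["wm_base"])
        wm_asym = rng.normal(*cell["wm_asym"])
        cc = rng.normal(*cell["cc"])
        rows.append(
            {
                "participant_id": person["participant_id"],
                "gm_left": gm_base + gm_asym / 2.0,
                "gm_right": gm_base - gm_asym / 2.0,
                "wm_left": wm_base + wm_asym / 2.0,
                "wm_right": wm_base - wm_asym / 2.0,
                "cc_volume": cc,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic external classifications
# --------------------------------------------------------------------------


def generate_external_labels(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Synthetic prior-classification labels (GMM on HFLI; per-hemisphere SVM).

    These emulate the published cross-classification counts: 9 strong-
    atypicals (all in ATYP), 37 ambilaterals (15 in ATYP, 16 TYP_MILD,
    6 TYP_STRONG), right-hemisphere dominance for 17 ATYP members (7 of them
    codominant) plus 5 others, everyone else left-dominant.  HFLI values are
    drawn uniformly inside each GMM category's range.  Purely synthetic —
    the GMM/SVM classifiers themselves are not reimplemented.
    """
    rng = _rng(config.seed, "external")
    df = cohort[["participant_id", "latent_group", "handedness"]].copy()
    n = len(df)
    gmm = np.full(n, "TYP", dtype=object)
    svm_left = np.full(n, "DOM", dtype=object)
    svm_right = np.full(n, "NONDOM", dtype=object)

    atyp = np.where(df["latent_group"] == "ATYP")[0]
    atyp_lh = np.where((df["latent_group"] == "ATYP") & (df["handedness"] == "L"))[0]
    sa = rng.choice(atyp_lh, size=min(9, len(atyp_lh)), replace=False)
    gmm[sa] = "SA"
    remaining_atyp = np.setdiff1d(atyp, sa)
    amb_atyp = rng.choice(remaining_atyp, size=min(15, len(remaining_atyp)), replace=False)
    gmm[amb_atyp] = "AMB"
    for group, n_amb in (("TYP_MILD", 16), ("TYP_STRONG", 6)):
        idx = np.where(df["latent_group"] == group)[0]
        gmm[rng.choice(idx, size=n_amb, replace=False)] = "AMB"

    rdom_atyp = rng.choice(atyp, size=min(17, len(atyp)), replace=False)
    svm_right[rdom_atyp] = "DOM"
    codom_atyp = rng.choice(rdom_atyp, size=min(7, len(rdom_atyp)), replace=False)
    svm_left[np.setdiff1d(rdom_atyp, codom_atyp)] = "NONDOM"
    others = np.concatenate(
        [
            rng.choice(np.where(df["latent_group"] == "TYP_MILD")[0], 4, replace=False),
            rng.choice(np.where(df["latent_group"] == "TYP_STRONG")[0], 1, replace=False),
        ]
    )
    svm_right[others] = "DOM"  # codominant

    hfli = np.empty(n)
    hfli[gmm == "SA"] = rng.uniform(-95, -52, size=(gmm == "SA").sum())
    hfli[gmm == "AMB"] = rng.uniform(-49, 49, size=(gmm == "AMB").sum())
    hfli[gmm == "TYP"] = rng.uniform(52, 95, size=(gmm == "TYP").sum())

    return pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "gmm_label": gmm,
            "svm_left": svm_left,
            "svm_right": svm_right,
            "hfli": np.round(hfli, 1),
        }
    )
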