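import logging

import numpy as np
import pandas as pd
import pytest

import langlat
from langlat import synthetic as syn
from langlat.atlas import Atlas, HRoi
from langlat.classifier import assign_groups, build_features, select_k, ward_tree
from sklearn.metrics import adjusted_rand_score

logging.disable(logging.WARNING)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def atlas():
    return langlat.default_atlas()


def make_toy_atlas(volumes=None, hubs=("p1",)):
    """A 3-pair atlas for hand-checkable computations."""
    volumes = volumes or {
        ("p1", "L"): 1000.0, ("p1", "R"): 1000.0,
        ("p2", "L"): 500.0, ("p2", "R"): 500.0,
        ("p3", "L"): 500.0, ("p3", "R"): 500.0,
    }
    entries = [
        HRoi(p, h, volumes[(p, h)], p in hubs)
        for p in ("p1", "p2", "p3")
        for h in ("L", "R")
    ]
    return Atlas(entries, name="toy")


@pytest.fixture()
def toy_atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def default_cohort(atlas):
    """One default synthetic cohort with contrasts, profiles and metrics."""
    cfg = langlat.default_config(seed=1)
    cohort = syn.generate_cohort(cfg)
    contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)
    profiles = langlat.asymmetry_profiles(contrasts, atlas)
    rest = syn.generate_rest_timeseries(cohort, atlas, cfg)
    metrics = langlat.connectivity_metrics(rest, atlas)
    return {
        "config": cfg,
        "cohort": cohort,
        "contrasts": contrasts,
        "profiles": profiles,
        "metrics": metrics,
    }


@pytest.fixture(scope="session")
def ten_seed_runs(atlas):
    """Classification results of ten default cohorts (seeds 0..9).

    Shared by the calibration-recovery, cluster-number and planted-partition
    tests so the cohorts are generated once.
    """
    runs = []
    for seed in range(10):
        cfg = langlat.default_config(seed=seed)
        cohort = syn.generate_cohort(cfg)
        contrasts = syn.generate_task_contrasts(cohort, atlas, cfg)
        profiles = langlat.asymmetry_profiles(contrasts, atlas)
        rest = syn.generate_rest_timeseries(cohort, atlas, cfg)
        metrics = langlat.connectivity_metrics(rest, atlas)
        raw = build_features(profiles, metrics)
        std = raw.standardize()
        tree = ward_tree(std)
        k, votes = select_k(std, tree, seed=seed)
        groups = assign_groups(raw, tree, 3)
        merged = groups.merge(cohort, on="participant_id")
        ari = adjusted_rand_score(merged["latent_group"], merged["group"])
        cells = (
            profiles.merge(cohort, on="participant_id")
            .merge(metrics, on="participant_id")
            .groupby("latent_group")[
                [
                    "CORE_PROD", "CORE_LISN", "CORE_READ",
                    "HUBS_PROD", "HUBS_LISN", "HUBS_READ",
                    "rs_dc_mean", "rs_dc_asym", "mihhc_r",
                ]
            ]
            .mean()
        )
        runs.append(
            {"seed": seed, "k": k, "votes": votes, "ari": ari, "cells": cells}
        )
    return runs
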