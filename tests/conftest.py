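"""Shared fixtures: small synthetic cohorts extracted once per session."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import eegstress as es
from eegstress.pipeline import PipelineConfig, extract_cohort_features

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

logging.getLogger("eegstress").setLevel(logging.ERROR)

EFFECT_SEED = 7
NULL_SEED = 11
COHORT_SIZE = 6


@pytest.fixture(scope="session")
def effect_cohort():
    """Six subjects with the default condition effects, fully extracted.

    Returns (config, records, tables_by_subject, labels_by_subject)."""
    cfg = PipelineConfig(synth=es.SynthConfig(n_subjects=COHORT_SIZE, seed=EFFECT_SEED))
    records = es.generate_cohort(cfg.synth)
    tables, labels = extract_cohort_features(records, cfg)
    return cfg, records, tables, labels


@pytest.fixture(scope="session")
def null_cohort():
    """Six subjects with no condition effect (chance-level cohort)."""
    cfg = PipelineConfig(synth=es.null_config(n_subjects=COHORT_SIZE, seed=NULL_SEED))
    records = es.generate_cohort(cfg.synth)
    tables, labels = extract_cohort_features(records, cfg)
    return cfg, records, tables, labels


@pytest.fixture(scope="session")
def pooled_effect(effect_cohort):
    """Pooled per-domain tables and label vector of the effect cohort."""
    _, _, tables, labels = effect_cohort
    pooled = {
        d: pd.concat([t[d] for t in tables], ignore_index=True)
        for d in ("time", "freq", "plv")
    }
    return pooled, np.concatenate(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data: np.ndarray, fs: float = 256.0, labels=None, channels=None):
    """Convenience EpochSet builder for hand-made arrays."""
    n_ep, n_ch, spe = data.shape
    if labels is None:
        labels = tuple(["rest"] * (n_ep // 2) + ["stress"] * (n_ep - n_ep // 2))
    if channels is None:
        channels = tuple(f"C{i}" for i in range(n_ch))
    return es.EpochSet(
        data, fs, 1000.0 * spe / fs, tuple(labels), tuple(channels),
        tuple(range(0, n_ep * spe, spe)),
    )
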