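import numpy as np
import pandas as pd
import pytest

from polyarray import synthetic as syn
from polyarray import signal_model as sm


@pytest.fixture(scope="session")
def array_experiment():
    cfg = syn.ArrayScenarioConfig(n_samples=96, n_probesets=300, seed=11)
    table, truth = syn.generate_array_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def array_results(array_experiment):
    _, table, _ = array_experiment
    calls, results, step_log = sm.two_step_genotyping(table)
    return calls, results, step_log


@pytest.fixture(scope="session")
def call_matrix(array_results):
    calls, _, _ = array_results
    return sm.calls_to_matrix(calls)


@pytest.fixture(scope="session")
def panel_two_groups():
    cfg = syn.PanelScenarioConfig(
        n_groups=2, samples_per_group=(12, 12), n_loci=500, fst=0.3, seed=23
    )
    return syn.generate_population_panel(cfg)


@pytest.fixture(scope="session")
def ril_population():
    cfg = syn.RilScenarioConfig(
        n_individuals=300,
        n_chromosomes=2,
        markers_per_chromosome=(40, 40),
        chromosome_length_cM=(120.0, 120.0),
        distortion_loci=((0, 60.0, 0.8),),
        missing_rate=0.02,
        seed=31,
    )
    return syn.generate_ril_f6(cfg)


@pytest.fixture(scope="session")
def variant_set():
    records, gt, truth = syn.generate_variant_records(
        n_loci=2000,
        n_lines=8,
        class_mix={"CLASS1": 0.5, "CLASS2": 0.2, "CLASS3": 0.2, "CLASS4": 0.1},
        tstv_target=2.0,
        multi_hit_rate=0.05,
        seed=41,
    )
    return records, gt, truth


def make_model(labels, contrast_means, contrast_vars=None, size_means=None,
               size_vars=None, counts=None, weights=None, penalty=0.0):
    """Hand-built ProbesetModel for metric unit tests."""
    k = len(labels)
    cm = np.asarray(contrast_means, dtype=float)
    cv = np.asarray(contrast_vars if contrast_vars is not None else [0.01] * k, float)
    sm_ = np.asarray(size_means if size_means is not None else [12.0] * k, float)
    sv = np.asarray(size_vars if size_vars is not None else [0.02] * k, float)
    n = np.asarray(counts if counts is not None else [30.0] * k, float)
    w = np.asarray(weights if weights is not None else n / n.sum(), float)
    return sm.ProbesetModel(
        means=np.column_stack([cm, sm_]),
        variances=np.column_stack([cv, sv]),
        weights=w,
        labels=list(labels),
        inbred_penalty=penalty,
        n_points=int(n.sum()),
        counts=n,
    )
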