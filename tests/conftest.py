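"""Shared fixtures: a small synthetic cohort and a model trained on it.

The cohort is deliberately smaller than the study-scale demo (60 subjects on a
24x24x28 grid) so that module-level tests stay fast; the full-scale end-to-end
conditions are exercised in the acceptance tests.
"""

import numpy as np
import pytest

from relmap3d import io_preproc, synthetic
from relmap3d.network import NetworkSpec, TrainConfig, stratified_folds, train_fold

SMALL_GRID = (24, 24, 28)


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthetic.CohortSpec(
        n_control=30, n_mci=15, n_ad=15, grid_shape=SMALL_GRID, noise_sd=0.05, seed=7
    )
    volumes, records, atlas = synthetic.simulate_cohort(spec)
    return spec, volumes, records, atlas


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    spec, volumes, records, atlas = small_cohort
    model = io_preproc.fit_residualizer_on_controls(volumes, records)
    residuals = io_preproc.residualize_volumes(volumes, records, model)
    return [r.values for r in residuals]


STUDY_GRID = (40, 40, 48)


def train_study_fold(seed: int, keep_cohort: bool = False):
    """Train one CV fold at the study conditions (200 subjects, 40x40x48 grid,
    hippocampal attenuation 0.4, reference optimization protocol with the
    grid-independent flip augmentation)."""
    spec = synthetic.CohortSpec(n_control=100, n_mci=50, n_ad=50,
                                grid_shape=STUDY_GRID, seed=100 + seed)
    volumes, records, atlas = synthetic.simulate_cohort(spec)
    model = io_preproc.fit_residualizer_on_controls(volumes, records)
    residuals = io_preproc.residualize_volumes(volumes, records, model)
    X = [rv.values for rv in residuals]
    diagnoses = np.array([rec.diagnosis for rec in records])
    binary = (diagnoses != "CN").astype(int)
    folds = stratified_folds(diagnoses, k=10, seed=seed)
    te = folds == 0
    net = train_fold(
        [X[i] for i in np.where(~te)[0]], binary[~te],
        [X[i] for i in np.where(te)[0]], binary[te],
        NetworkSpec(input_shape=STUDY_GRID),
        TrainConfig(epochs=10, augment="flip", seed=seed),
    )
    best_acc = max(h["test_balanced_accuracy"] for h in net.history)
    cohort = (volumes, records, atlas, X) if keep_cohort else None
    return net, best_acc, cohort


@pytest.fixture(scope="session")
def study_models():
    """Five study-condition fold models; full cohort data kept for seed 0 only."""
    nets, accs, cohort0 = [], [], None
    for seed in range(5):
        net, acc, cohort = train_study_fold(seed, keep_cohort=(seed == 0))
        nets.append(net)
        accs.append(acc)
        if cohort is not None:
            cohort0 = cohort
    return {"nets": nets, "accs": accs, "cohort": cohort0}


@pytest.fixture(scope="session")
def trained_small_model(small_cohort, small_residuals):
    """One model trained on a single stratified split of the small cohort."""
    spec, volumes, records, atlas = small_cohort
    diagnoses = np.array([r.diagnosis for r in records])
    binary = (diagnoses != "CN").astype(int)
    folds = stratified_folds(diagnoses, k=4, seed=0)
    te = folds == 0
    net = train_fold(
        [small_residuals[i] for i in np.where(~te)[0]],
        binary[~te],
        [small_residuals[i] for i in np.where(te)[0]],
        binary[te],
        NetworkSpec(input_shape=SMALL_GRID),
        TrainConfig(epochs=30, augment="flip", seed=3),
    )
    return net, te
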