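"""Shared fixtures: small in-memory cohorts and evaluation-scale configs.

Session-scoped fixtures cache the expensive artifacts (the 30-per-group
separable cohort and its cross-validation runs) so the separability, null
and ablation checks share one set of trainings.
"""

from __future__ import annotations

import numpy as np
import pytest

from gazenest import evaluation, heatmap, nested_ae, synthetic

# Evaluation-scale problem sizes: 30 subjects per group (the cohort scale at
# which group separation is assessed) and a 40-epoch training budget — the
# joint loss needs a couple hundred optimizer steps before the classifier
# head's threshold calibrates, since the reconstruction terms dominate early.
EVAL_N_PER_GROUP = 30
EVAL_EPOCHS = 40
DELTA1_SEED = 11


@pytest.fixture(scope="session")
def eval_config() -> nested_ae.TrainConfig:
    return nested_ae.TrainConfig(epochs=EVAL_EPOCHS)


@pytest.fixture(scope="session")
def delta1_views() -> list[heatmap.SubjectViews]:
    """Separable cohort: full group contrast (delta=1), 30 per group."""
    cfg = synthetic.CohortConfig(n_per_group=EVAL_N_PER_GROUP, delta=1.0, seed=DELTA1_SEED)
    return synthetic.generate_views(cfg)


@pytest.fixture(scope="session")
def tiny_views() -> list[heatmap.SubjectViews]:
    """4 + 4 subjects, enough for fast structural checks with k=4 folds."""
    cfg = synthetic.CohortConfig(n_per_group=4, delta=1.0, seed=5)
    return synthetic.generate_views(cfg)


@pytest.fixture(scope="session")
def full_model_reports(delta1_views, eval_config) -> dict[int, evaluation.MetricsReport]:
    """Four-fold CV of the full model on the separable cohort, five seeds."""
    factory = evaluation.make_nested_ae_factory(eval_config)
    return {
        seed: evaluation.cross_validate(
            delta1_views, factory, k=4, seed=seed, model_name="full_model"
        )
        for seed in range(5)
    }


@pytest.fixture(scope="session")
def encoders_only_reports(delta1_views, eval_config) -> dict[int, evaluation.MetricsReport]:
    """The encoders-only reduction under the same folds and seeds."""
    from dataclasses import replace

    cfg = replace(
        eval_config,
        use_inner_decoder=False,
        use_outer_decoder=False,
        use_fusion_layer=False,
    )
    factory = evaluation.make_nested_ae_factory(cfg)
    return {
        seed: evaluation.cross_validate(
            delta1_views, factory, k=4, seed=seed, model_name="encoders_only"
        )
        for seed in range(5)
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
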