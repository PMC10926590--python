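import numpy as np
import pytest

from disfc.fusioncore import ModelConfig
from disfc.synthdata import SynthConfig, generate_cohort
from disfc.trainer import TrainConfig


@pytest.fixture(scope="session")
def tiny_cfg() -> SynthConfig:
    """Desk-scale study conditions: small volumes, short SNP panel."""
    return SynthConfig(
        n_subjects=60, volume_shape=(8, 8, 8), n_snps=80,
        n_causal_snps=4, n_decoys_per_block=4, n_train_only_ad=4,
        interaction_strength=0.8, seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def default_scale_cohort():
    """A cohort at the generator's default scale (252 MCI + 45 AD extras)."""
    return generate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_model_cfg() -> ModelConfig:
    return ModelConfig(volume_shape=(8, 8, 8), n_snp_features=20)


@pytest.fixture(scope="session")
def fast_train_cfg() -> TrainConfig:
    return TrainConfig(epochs=5, warmup_epochs=2, seed=1)


@pytest.fixture(scope="session")
def trained_toy():
    """A model trained on strongly planted signals, for attribution tests.

    The clinical branch is kept small and well regularized so that its
    learned function rests on the planted product term rather than on
    memorized noise partitions; a held-out quarter of the cohort supports
    generalization-based attribution checks.
    """
    from disfc.trainer import prepare_split, train_fold

    cfg = SynthConfig(
        n_subjects=400, volume_shape=(8, 8, 8), n_snps=60,
        n_causal_snps=4, n_decoys_per_block=3, n_train_only_ad=0,
        interaction_strength=0.95, atrophy_fraction=0.5, noise_sd=0.05,
        missing_clinical_fraction=0.0, test_fraction=0.25, seed=31,
    )
    cohort = generate_cohort(cfg)
    tr = np.flatnonzero(cohort.roles == "cv")
    va = np.flatnonzero(cohort.roles == "test")
    model_cfg = ModelConfig(volume_shape=(8, 8, 8), n_snp_features=10,
                            branch_hidden_dim=12, l2_strength=1e-2,
                            dropout_fc=0.3)
    train_data, val_data, fitted_cfg = prepare_split(cohort, tr, va, model_cfg)
    model, history = train_fold(
        fitted_cfg, train_data,
        TrainConfig(epochs=30, warmup_epochs=8, seed=2))
    return {"model": model, "cohort": cohort, "cfg": cfg,
            "train_data": train_data, "val_data": val_data,
            "history": history}
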