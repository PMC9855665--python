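import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from molactive import active_ensemble as ae
from molactive import chem_data as cd
from molactive import dmpnn_model as dm
from molactive import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


DESK_CONFIG = dict(
    hidden_size=32, depth=2, ffn_depth=2, learning_rate=1e-3,
    batch_size=64, max_epochs=20, patience=5,
)


@pytest.fixture(scope="session")
def desk_config():
    return dm.DMPNNConfig(**DESK_CONFIG)


@pytest.fixture(scope="session")
def synthetic_task():
    """The study-condition synthetic task: n=1000, noise 0.1, imbalance 1.9."""
    return sd.generate_dataset(
        sd.GeneratorConfig(n=1000, imbalance_ratio=1.9, noise_rate=0.1, seed=101)
    )


@pytest.fixture(scope="session")
def small_task():
    """A faster task for single-model training checks: n=400, noise 0.05."""
    return sd.generate_dataset(
        sd.GeneratorConfig(n=400, imbalance_ratio=1.9, noise_rate=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def screening_fixture():
    """1000 records with 50 planted actives (imbalance 19) and light noise."""
    return sd.generate_dataset(
        sd.GeneratorConfig(n=1000, imbalance_ratio=19.0, noise_rate=0.02, seed=13)
    )


@pytest.fixture(scope="session")
def trained_small_model(small_task, desk_config):
    split = cd.split_dataset(len(small_task.records), 7)
    tr, va = split.folds[0]
    cfg = dm.DMPNNConfig(**{**DESK_CONFIG, "hidden_size": 64, "max_epochs": 30, "seed": 1})
    model = dm.train(
        [small_task.records[i] for i in tr],
        [small_task.records[i] for i in va],
        cfg,
    )
    return model, split


@pytest.fixture(scope="session")
def al_runs(synthetic_task, desk_config):
    """Active and passive pool-learning trajectories over 5 seeds.

    Shared by the data-efficiency, ensemble and pool-invariant checks so the
    expensive runs happen once per session.
    """
    records = synthetic_task.records
    runs = {}
    for seed in range(5):
        split = cd.split_dataset(len(records), 200 + seed)
        tr, va = split.folds[0]
        n_init = max(2, round(0.05 * len(tr)))
        sched = ae.make_schedule(len(tr) - n_init, initial_fraction=0.05)
        cfg = dm.DMPNNConfig(**{**DESK_CONFIG, "seed": seed})
        active = ae.run_active_learning(records, tr, va, cfg, sched, seed=seed)
        passive = ae.run_passive_learning(records, tr, va, cfg, sched, seed=seed)
        runs[seed] = {
            "split": split, "schedule": sched, "train": tr, "val": va,
            "active": active, "passive": passive,
        }
    return runs


@pytest.fixture(scope="session")
def tiny_params_config():
    """A small fixed network for exact-value comparisons."""
    cfg = dm.DMPNNConfig(hidden_size=4, depth=2, ffn_depth=2, seed=42)
    params = dm.init_params(cfg, np.random.default_rng(42))
    return params, cfg
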