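import numpy as np
import pytest

import gradval as gv


@pytest.fixture(scope="session")
def small_blobs():
    """50-sample separable 2-class table used across oracle tests."""
    return gv.make_blobs(50, d=6, separation=4.0, seed=3)


@pytest.fixture(scope="session")
def blob_experiment():
    """The standard corrupted-label setup: separable blobs, 20% of the
    source labels flipped, clean target set.  Computed once per session."""
    data = gv.make_blobs(1400, d=10, separation=4.0, seed=11)
    Xs, ys = data.X[:1000], data.y[:1000]
    Xt, yt = data.X[1000:], data.y[1000:]
    ys_corrupt, mask = gv.flip_labels(ys, 0.2, seed=5)
    return {"Xs": Xs, "ys_clean": ys, "ys": ys_corrupt, "mask": mask,
            "Xt": Xt, "yt": yt}


@pytest.fixture(scope="session")
def blob_dvgs_values(blob_experiment):
    """Gradient-similarity values for the corrupted blob source set, with
    the per-iteration record kept (reused by several tests)."""
    e = blob_experiment
    cfg = gv.ValuationConfig(
        learning_rate=0.05, n_iterations=1000, target_batch_size=50,
        base_seed=0, n_runs=3, record_per_iteration=True,
    )
    dv = gv.run_dvgs(lambda s: gv.make_mlp(10, 100, 2, seed=s),
                     (e["Xs"], e["ys"]), (e["Xt"], e["yt"]), cfg)
    return dv
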