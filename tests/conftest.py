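import pytest

from seedfold.motif_discovery import mask_for_search
from seedfold.pipeline import rank_windows
from seedfold.synthetic import SyntheticSpec, generate_windows


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """Windows + ground truth at generator defaults (seed 1)."""
    windows, truth = generate_windows(default_spec)
    return windows, truth


@pytest.fixture(scope="session")
def default_ranked(default_dataset):
    """Accessibility-ranked windows plus their unconstrained folds."""
    windows, _ = default_dataset
    return rank_windows(windows)


@pytest.fixture(scope="session")
def default_masked(default_ranked):
    ranked, folds = default_ranked
    return [mask_for_search(w, folds[w.window_id]) for w in ranked.windows]
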