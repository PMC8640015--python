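from __future__ import annotations

import numpy as np
import pytest

import hmm4d as h
from hmm4d.synthetic import DEFAULT_ROLES


@pytest.fixture(scope="session")
def roles() -> dict[int, str]:
    return dict(DEFAULT_ROLES)


@pytest.fixture(scope="session")
def demo_spec(roles) -> h.HmmSpec:
    """Plain temporal spec: default transition, 95%-correct square emission."""
    n = 4
    emission = np.full((n, n), 0.05 / (n - 1))
    np.fill_diagonal(emission, 0.95)
    return h.HmmSpec(
        n_classes=n,
        n_bins=1,
        transition=h.build_transition_default(n, roles),
        emission=emission,
        start=h.build_start_uniform(n),
    )


@pytest.fixture(scope="session")
def small_phantom() -> h.Phantom:
    """Reduced phantom for fast unit tests."""
    return h.generate_phantom(h.PhantomConfig(shape=(10, 24, 24, 24), seed=7))


@pytest.fixture(scope="session")
def default_phantom() -> h.Phantom:
    """The full default study conditions: 21 time steps over a 64^3 grid."""
    return h.generate_phantom(h.PhantomConfig())


@pytest.fixture(scope="session")
def phantom_specs(default_phantom, roles):
    """Confusion-derived specs for the default phantom, as the pipeline builds
    them: tally the segmenter's confusion against the truth, row-normalise,
    and (for the confidence-aware model) apply the same-title adjustment."""
    ph = default_phantom
    cm_sq = h.tally_confusion(ph.observed, None, ph.hidden, 4)
    cm_rect = h.tally_confusion(ph.observed, ph.confidence, ph.hidden, 4, 3)
    return {
        "hmm-t": h.make_spec("hmm-t", cm_sq, roles),
        "hmm-tc": h.make_spec("hmm-tc", cm_rect, roles),
        "hmm-t-naive": h.make_spec("hmm-t-naive", cm_sq),
        "hmm-t-naive-stable": h.make_spec("hmm-t-naive-stable", cm_sq),
    }
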