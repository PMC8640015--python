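"""Independent oracles used by the test suite.

The brute-force decoder enumerates every possible hidden path and maximizes
its probability directly — no dynamic programming — so it is an independent
check of the Viterbi implementation.  Log-probabilities are accumulated in
the same order as the decoder (start + emission, then transition, then
emission per step) so that any given path scores bit-identically in both
routes.  The oracle returns the full set of score-tied optimal paths: two
distinct paths can tie in total score yet compare unequal at an intermediate
dynamic-programming stage (the rounding of the final addition can collapse a
strict inequality into an exact tie), so the correctness contract checked
against the oracle is "the decoded path is optimal", while tie-break
determinism is checked separately by repeat-run equality.
"""

from __future__ import annotations

import itertools

import numpy as np

from hmm4d import HmmSpec
from hmm4d.decode import NoFeasiblePathError


def brute_force_optimal_paths(obs: np.ndarray, spec: HmmSpec) -> np.ndarray:
    """All score-maximizing hidden paths, by exhaustive enumeration.

    Returns a ``(n_tied, T)`` array; usually ``n_tied == 1``.
    """
    obs = np.asarray(obs, dtype=np.int64)
    T = obs.size
    n = spec.n_classes
    with np.errstate(divide="ignore"):
        log_t = np.log(spec.transition)
        log_e = np.log(spec.emission)
        log_s = np.log(spec.start)

    paths = np.array(list(itertools.product(range(n), repeat=T)), dtype=np.int64)
    scores = log_s[paths[:, 0]] + log_e[paths[:, 0], obs[0]]
    for t in range(1, T):
        # two separate adds to mirror the decoder's accumulation order
        scores = scores + log_t[paths[:, t - 1], paths[:, t]]
        scores = scores + log_e[paths[:, t], obs[t]]

    best = scores.max()
    if not np.isfinite(best):
        # locate the first fully blocked step for error parity checks
        raise NoFeasiblePathError(_first_blocked_step(obs, spec))
    return paths[scores == best]


def assert_is_optimal_path(path: np.ndarray, obs: np.ndarray, spec: HmmSpec) -> None:
    """Assert that ``path`` is one of the enumeration's optimal paths."""
    optimal = brute_force_optimal_paths(obs, spec)
    assert any(
        np.array_equal(path, cand) for cand in optimal
    ), f"decoded path {path} not among {len(optimal)} optimal path(s) {optimal}"


def _first_blocked_step(obs: np.ndarray, spec: HmmSpec) -> int:
    with np.errstate(divide="ignore"):
        log_t = np.log(spec.transition)
        log_e = np.log(spec.emission)
        log_s = np.log(spec.start)
    delta = log_s + log_e[:, obs[0]]
    if not np.any(np.isfinite(delta)):
        return 0
    for t in range(1, obs.size):
        delta = (delta[:, None] + log_t).max(axis=0) + log_e[:, obs[t]]
        if not np.any(np.isfinite(delta)):
            return t
    raise AssertionError("a feasible path exists")


def random_spec(
    rng: np.random.Generator,
    n_classes: int,
    n_bins: int = 1,
    zero_fraction: float = 0.0,
) -> HmmSpec:
    """Random valid spec, optionally with hard-zero transition entries."""
    m = n_classes * n_bins

    def _stochastic(rows: int, cols: int, zeros: float) -> np.ndarray:
        mat = rng.dirichlet(np.ones(cols), size=rows)
        if zeros > 0:
            mask = rng.random((rows, cols)) < zeros
            # never zero out a full row
            keep = rng.integers(0, cols, size=rows)
            mask[np.arange(rows), keep] = False
            mat = np.where(mask, 0.0, mat)
            mat = mat / mat.sum(axis=1, keepdims=True)
        return mat

    return HmmSpec(
        n_classes=n_classes,
        n_bins=n_bins,
        transition=_stochastic(n_classes, n_classes, zero_fraction),
        emission=_stochastic(n_classes, m, zero_fraction),
        start=rng.dirichlet(np.ones(n_classes)),
    )
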