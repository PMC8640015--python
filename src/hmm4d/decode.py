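"""Viterbi decoding of per-site observation sequences.

Every spatial site of an aligned 4D volume yields one observation sequence
over time (a :class:`ToxelSequence`); sites are decoded independently.  The
decoder returns the single most probable hidden-state path under the model's
transition, emission and starting probabilities.  All dynamic programming is
done in log space with ``-inf`` standing in for zero probabilities, so paths
through forbidden transitions are never selected while underflow cannot occur
even for long series.

Ties are broken deterministically toward the lowest class index, both in the
final-state selection and at every backtrack step; the decoded path is
therefore the optimal path that is lexicographically smallest when read from
the last time step backwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import HmmSpec

__all__ = [
    "ToxelSequence",
    "NoFeasiblePathError",
    "viterbi_decode",
    "viterbi_decode_batch",
    "shortcut_constant",
    "shortcut_table",
    "audit_shortcut",
]


class NoFeasiblePathError(ValueError):
    """Raised when every complete hidden path has zero probability."""

    def __init__(self, t: int):
        self.t = t
        super().__init__(
            f"no feasible hidden path: every partial path has zero probability "
            f"at time step {t}"
        )


@dataclass(frozen=True)
class ToxelSequence:
    """One spatial site's observation sequence over time."""

    observations: np.ndarray
    t0: int = 0

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=np.int64)
        if obs.ndim != 1 or obs.size < 1:
            raise ValueError("observations must be a non-empty 1-D sequence")
        if np.any(obs < 0):
            raise ValueError("observation indices must be non-negative")
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return self.observations.size


def _log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def viterbi_decode(seq: ToxelSequence | np.ndarray, spec: HmmSpec) -> np.ndarray:
    """Most probable hidden-class path for a single observation sequence.

    Maximizes ``P(X_0) O[X_0, E_0] * prod_t T[X_{t-1}, X_t] O[X_t, E_t]``.

    Raises
    ------
    NoFeasiblePathError
        If every complete path has zero probability; the error names the
        first fully blocked time step.
    """
    obs = seq.observations if isinstance(seq, ToxelSequence) else np.asarray(seq)
    if np.any(obs >= spec.n_observables):
        raise ValueError("observation index out of range for this spec")
    return viterbi_decode_batch(obs[None, :], spec)[0]


def viterbi_decode_batch(obs: np.ndarray, spec: HmmSpec) -> np.ndarray:
    """Viterbi decode many sequences at once.

    Parameters
    ----------
    obs
        ``(n_sites, T)`` integer array of observable indices.

    Returns
    -------
    ``(n_sites, T)`` integer array of hidden class indices.
    """
    obs = np.asarray(obs, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[1] < 1:
        raise ValueError("obs must be a (n_sites, T) array with T >= 1")
    n_sites, T = obs.shape
    log_t = _log(spec.transition)  # (N, N)
    log_e = _log(spec.emission)  # (N, M)
    log_s = _log(spec.start)  # (N,)
    n = spec.n_classes

    # delta[s, i]: best log-prob of any path ending in state i at current t
    delta = log_s[None, :] + log_e[:, obs[:, 0]].T  # (n_sites, N)
    _check_feasible(delta, 0)
    psi = np.empty((T, n_sites, n), dtype=np.int8 if n <= 127 else np.int64)
    for t in range(1, T):
        # cand[s, i, j] = delta[s, i] + log T[i, j]
        cand = delta[:, :, None] + log_t[None, :, :]
        best_prev = np.argmax(cand, axis=1)  # first (lowest) argmax
        delta = np.take_along_axis(cand, best_prev[:, None, :], axis=1)[:, 0, :]
        delta = delta + log_e[:, obs[:, t]].T
        psi[t] = best_prev
        _check_feasible(delta, t)

    path = np.empty((n_sites, T), dtype=np.int64)
    path[:, -1] = np.argmax(delta, axis=1)
    rows = np.arange(n_sites)
    for t in range(T - 1, 0, -1):
        path[:, t - 1] = psi[t][rows, path[:, t]]
    return path


def _check_feasible(delta: np.ndarray, t: int) -> None:
    blocked = ~np.any(np.isfinite(delta), axis=1)
    if np.any(blocked):
        raise NoFeasiblePathError(t)


# ---------------------------------------------------------------------------
# constant-observation shortcut
# ---------------------------------------------------------------------------

def shortcut_table(spec: HmmSpec) -> np.ndarray:
    """Per-observable hidden class used by the constant-observation shortcut.

    For each observable ``e`` this is the hidden class that emits ``e`` with
    the highest probability (the emission-column argmax; ties resolve to the
    lowest class index).
    """
    emission = spec.emission
    if np.any(~np.any(emission > 0, axis=0)):
        col = int(np.flatnonzero(~np.any(emission > 0, axis=0))[0])
        raise ValueError(f"emission column {col} is entirely zero")
    return np.argmax(emission, axis=0)


def shortcut_constant(observable: int, spec: HmmSpec, T: int) -> np.ndarray:
    """Decode a temporally constant sequence without running Viterbi.

    Sites whose observation never changes — the overwhelming majority in a
    large 4D dataset with localised temporal events — are assigned the class
    that emits their observable with the highest probability, repeated for
    all ``T`` steps.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= observable < spec.n_observables:
        raise ValueError(f"observable {observable} out of range")
    cls = int(shortcut_table(spec)[observable])
    return np.full(T, cls, dtype=np.int64)


def audit_shortcut(spec: HmmSpec, max_T: int = 6, warn: bool = True) -> dict[int, bool]:
    """Compare the shortcut against full Viterbi on constant sequences.

    The shortcut is an approximation: for each observable it checks, for
    every length up to ``max_T``, whether the shortcut class matches the
    Viterbi decode of the constant sequence.  Returns a mapping
    ``observable -> agrees`` and warns on any disagreement.
    """
    agreement: dict[int, bool] = {}
    for e in range(spec.n_observables):
        ok = True
        for T in range(1, max_T + 1):
            const = np.full(T, e, dtype=np.int64)
            try:
                path = viterbi_decode(const, spec)
            except NoFeasiblePathError:
                ok = False
                break
            if not np.array_equal(path, shortcut_constant(e, spec, T)):
                ok = False
                break
        agreement[e] = ok
        if warn and not ok:
            warnings.warn(
                f"constant-observation shortcut disagrees with Viterbi for "
                f"observable {e}",
                stacklevel=2,
            )
    return agreement
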