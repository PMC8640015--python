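"""Hidden Markov model parameter objects and builders.

The refinement HMMs are fully specified by four ingredients: a row-stochastic
transition matrix ``T`` (``T[i, j] = P(X_t = j | X_{t-1} = i)`` over hidden
segmentation classes), a row-stochastic emission matrix ``O``
(``O[s, e] = P(E_t = e | X_t = s)`` over observable states), a starting
probability vector ``S`` and the class/bin counts that fix the observable
alphabet.  For the plain temporal model the observables are the per-timepoint
classifier predictions themselves (``M = N``); for the confidence-aware model
each prediction is split by the classifier's leading-class probability into
``b`` confidence bins, giving ``M = b * N`` composite observables.

None of these parameters are learned: the transition matrix encodes the
expected physical behaviour of the imaged system (e.g. an irreversible
dissolving -> product conversion), the emission matrix is the row-normalised
confusion matrix of the upstream segmenter on its test set, and the start
vector is uniform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HmmSpec",
    "ConfusionMatrix",
    "build_transition_default",
    "build_transition_naive",
    "build_transition_naive_stable",
    "build_start_uniform",
    "emission_from_confusion",
    "adjust_emission_diagonal",
    "confidence_bin",
    "composite_observable",
    "composite_labels",
    "make_spec",
    "MODEL_NAMES",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: tolerance for row-stochasticity checks
_ROW_SUM_ATOL = 1e-9


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    if np.any(mat < -1e-15) or np.any(mat > 1 + 1e-12):
        raise ValueError(f"{name} has entries outside [0, 1]")
    sums = mat.sum(axis=-1)
    if not np.allclose(sums, 1.0, rtol=0.0, atol=_ROW_SUM_ATOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"{name} is not row-stochastic: row {bad} sums to {sums.flat[bad]!r}"
        )


@dataclass(frozen=True)
class HmmSpec:
    """Complete parameter set for one refinement HMM.

    Parameters
    ----------
    n_classes
        Number of hidden states ``N`` (the segmentation classes).
    n_bins
        Number of confidence bins ``b``; 1 for the plain temporal model,
        >= 2 for the confidence-aware model.
    transition
        ``(N, N)`` row-stochastic matrix of hidden-state transitions.
    emission
        ``(N, N * b)`` row-stochastic matrix of observation probabilities.
    start
        Length-``N`` probability vector for the hidden state at ``t = 0``.
    class_names
        Optional display names, one per class.
    """

    n_classes: int
    n_bins: int
    transition: np.ndarray
    emission: np.ndarray
    start: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        t = np.asarray(self.transition, dtype=float)
        e = np.asarray(self.emission, dtype=float)
        s = np.asarray(self.start, dtype=float)
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "emission", e)
        object.__setattr__(self, "start", s)
        n, m = self.n_classes, self.n_classes * self.n_bins
        if t.shape != (n, n):
            raise ValueError(f"transition must be ({n}, {n}), got {t.shape}")
        if e.shape != (n, m):
            raise ValueError(
                f"emission must be ({n}, {m}) for n_bins={self.n_bins}, got {e.shape}"
            )
        if s.shape != (n,):
            raise ValueError(f"start must have length {n}, got {s.shape}")
        _check_stochastic(t, "transition")
        _check_stochastic(e, "emission")
        _check_stochastic(s[None, :], "start")
        if self.class_names is not None:
            names = tuple(self.class_names)
            if len(names) != n:
                raise ValueError("class_names must have one entry per class")
            object.__setattr__(self, "class_names", names)

    @property
    def n_observables(self) -> int:
        return self.n_classes * self.n_bins

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the full spec to a JSON document (full double precision)."""
        doc = {
            "n_classes": self.n_classes,
            "n_bins": self.n_bins,
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "start": self.start.tolist(),
            "class_names": list(self.class_names) if self.class_names else None,
            "observable_labels": composite_labels(
                self.n_classes, self.n_bins, self.class_names
            ),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HmmSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(
            n_classes=int(doc["n_classes"]),
            n_bins=int(doc["n_bins"]),
            transition=np.asarray(doc["transition"], dtype=float),
            emission=np.asarray(doc["emission"], dtype=float),
            start=np.asarray(doc["start"], dtype=float),
            class_names=tuple(doc["class_names"]) if doc.get("class_names") else None,
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Raw integer confusion tallies: ground-truth rows x observable columns.

    Square (``N x N``) for plain class predictions, rectangular (``N x bN``)
    when predictions are split by confidence bin.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = field(default=())
    col_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))
        n, m = c.shape
        rl = tuple(self.row_labels) or tuple(f"class{i}" for i in range(n))
        cl = tuple(self.col_labels) or tuple(f"obs{j}" for j in range(m))
        if len(rl) != n or len(cl) != m:
            raise ValueError("label lengths inconsistent with counts shape")
        object.__setattr__(self, "row_labels", rl)
        object.__setattr__(self, "col_labels", cl)
        if m % n != 0:
            raise ValueError(
                f"column count {m} is not a multiple of the class count {n}"
            )

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1] // self.counts.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            counts=df.to_numpy(),
            row_labels=tuple(str(r) for r in df.index),
            col_labels=tuple(str(c) for c in df.columns),
        )


# ---------------------------------------------------------------------------
# transition / start builders
# ---------------------------------------------------------------------------

def build_transition_default(
    n_classes: int,
    class_roles: Mapping[int, str] | None = None,
    *,
    dissolve_prob: float = 0.10,
    eps: float = 1e-3,
) -> np.ndarray:
    """Empirically motivated transition matrix for an irreversible conversion.

    One class (role ``"dissolving"``) converts to another (role ``"product"``)
    with probability ``dissolve_prob`` per time step (default 10%, the expected
    corrosion rate of magnesium deposits into gas pockets).  Every other
    ordered class pair receives a small symmetric cross-term ``eps`` to keep
    rare transitions (misalignment, thermal drift) possible rather than
    forbidden.  Diagonals absorb the remaining mass, so the matrix is strongly
    diagonal-dominant.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    dissolving = product = None
    if class_roles:
        for cls_idx, role in class_roles.items():
            if not 0 <= int(cls_idx) < n_classes:
                raise ValueError(f"role class {cls_idx} out of range [0, {n_classes})")
            if role == "dissolving":
                dissolving = int(cls_idx)
            elif role == "product":
                product = int(cls_idx)
    elif n_classes >= 4:
        # conventional ordering: air, base, dissolving, product
        dissolving, product = 2, 3

    t = np.full((n_classes, n_classes), eps, dtype=float)
    np.fill_diagonal(t, 0.0)
    if dissolving is not None and product is not None:
        t[dissolving, product] = dissolve_prob
    diag = 1.0 - t.sum(axis=1)
    if np.any(diag < 0):
        raise ValueError("off-diagonal mass exceeds 1; reduce eps or dissolve_prob")
    t[np.diag_indices(n_classes)] = diag
    return t


def build_transition_naive(n_classes: int) -> np.ndarray:
    """All transitions, including self-transitions, equally probable (1/N)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return np.full((n_classes, n_classes), 1.0 / n_classes)


def build_transition_naive_stable(n_classes: int) -> np.ndarray:
    """50% chance to stay; the other 50% spread uniformly over other classes."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    t = np.full((n_classes, n_classes), 0.5 / (n_classes - 1))
    np.fill_diagonal(t, 0.5)
    return t


def build_start_uniform(n_classes: int) -> np.ndarray:
    """Uniform starting probabilities: no class is more plausible at t = 0."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return np.full(n_classes, 1.0 / n_classes)


# ---------------------------------------------------------------------------
# emission builders
# ---------------------------------------------------------------------------

def emission_from_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalise a confusion matrix into an emission matrix.

    Each row (a ground-truth class) is divided by its total count, so entry
    ``[s, e]`` becomes the empirical probability that the segmenter emits
    observable ``e`` for a voxel whose true class is ``s``.
    """
    counts = cm.counts.astype(float)
    row_sums = counts.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        names = ", ".join(cm.row_labels[i] for i in zero)
        raise ValueError(
            f"confusion matrix row(s) with zero total: {names}; the test set "
            "never contained these classes so their emission is undefined"
        )
    return counts / row_sums[:, None]


def adjust_emission_diagonal(emission: np.ndarray, boost: float = 1.001) -> np.ndarray:
    """Force each observable's column argmax onto its same-title class.

    A confidence-binned emission matrix derived from an imbalanced test set
    can claim that, say, a mid-confidence base-material prediction is most
    likely emitted by a rare class — an artefact of small denominators, not
    physics.  This reproduces the manual fix: for every composite observable
    column whose argmax is a foreign class, the same-title class's entry is
    multiplicatively boosted just past the column maximum, then rows are
    renormalised.  Idempotent up to floating-point noise.
    """
    e = np.array(emission, dtype=float)
    n, m = e.shape
    if m % n != 0:
        raise ValueError("emission column count must be a multiple of the class count")
    if boost <= 1.0:
        raise ValueError("boost must exceed 1")
    b = m // n
    owners = np.repeat(np.arange(n), b)
    if np.any(~np.any(e > 0, axis=0)):
        col = int(np.flatnonzero(~np.any(e > 0, axis=0))[0])
        raise ValueError(f"emission column {col} is entirely zero")
    # row renormalization can hand dominance back to a foreign class, so
    # boost-and-renormalize is iterated to its fixed point
    for _ in range(200):
        bad = [c for c in range(m)
               if int(np.argmax(e[:, c])) != owners[c]
               or e[owners[c], c] < e[:, c].max()]
        if not bad:
            break
        for col in bad:
            e[owners[col], col] = boost * e[:, col].max()
        e = e / e.sum(axis=1, keepdims=True)
    else:
        raise RuntimeError("diagonal adjustment did not converge")
    return e


# ---------------------------------------------------------------------------
# confidence binning and composite observables
# ---------------------------------------------------------------------------

def confidence_bin(p, n_classes: int, n_bins: int):
    """Quantize leading-class probabilities into equal-width confidence bins.

    The leading-class probability of an ``N``-way classifier lives in
    ``(1/N, 1]``; that range is split into ``n_bins`` equal-width intervals,
    lower-closed and upper-open except the top bin, which is closed at 1.
    Degenerate values ``p <= 1/N`` clamp to bin 0.  Accepts scalars or arrays.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    lo = 1.0 / n_classes
    width = (1.0 - lo) / n_bins
    idx = np.floor((arr - lo) / width).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)
    if arr.ndim == 0:
        return int(idx)
    return idx


def composite_observable(pred_class, bin_index, n_bins: int):
    """Map (predicted class, confidence bin) to a composite observable index.

    Class-major ordering: observable ``= class * n_bins + bin``, so the
    ``n_bins`` confidence levels of one class are contiguous columns.
    Accepts scalars or arrays.
    """
    c = np.asarray(pred_class)
    k = np.asarray(bin_index)
    if np.any(c < 0):
        raise ValueError("pred_class must be non-negative")
    if np.any(k < 0) or np.any(k >= n_bins):
        raise ValueError(f"bin_index must lie in [0, {n_bins})")
    out = c * n_bins + k
    if out.ndim == 0:
        return int(out)
    return out


def composite_labels(
    n_classes: int, n_bins: int, class_names: Sequence[str] | None = None
) -> list[str]:
    """Human-readable labels for the composite observable columns."""
    names = list(class_names) if class_names else [f"class{i}" for i in range(n_classes)]
    if n_bins == 1:
        return names
    if n_bins == 3:
        levels = ["low", "mid", "high"]
    else:
        levels = [f"bin{k}" for k in range(n_bins)]
    return [f"{name}:{lvl}" for name in names for lvl in levels]


# ---------------------------------------------------------------------------
# spec assembly
# ---------------------------------------------------------------------------

MODEL_NAMES = ("hmm-t", "hmm-tc", "hmm-t-naive", "hmm-t-naive-stable")


def make_spec(
    model: str,
    confusion: ConfusionMatrix,
    class_roles: Mapping[int, str] | None = None,
    *,
    dissolve_prob: float = 0.10,
    eps: float = 1e-3,
    adjust: bool = True,
    class_names: Sequence[str] | None = None,
) -> HmmSpec:
    """Assemble a complete :class:`HmmSpec` from a confusion matrix.

    ``model`` selects the transition matrix: the empirically motivated default
    for ``hmm-t`` / ``hmm-tc``, or the uninformed baselines ``hmm-t-naive``
    (all transitions equally likely) and ``hmm-t-naive-stable`` (50% stay).
    The emission matrix is the row-normalised confusion matrix; for the
    confidence-aware model (rectangular confusion) the same-title diagonal
    adjustment is applied unless ``adjust`` is disabled.  Starting
    probabilities are uniform.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    n = confusion.n_classes
    b = confusion.n_bins
    if model == "hmm-tc" and b < 2:
        raise ValueError("hmm-tc requires a confidence-binned confusion matrix")
    if model != "hmm-tc" and b != 1:
        raise ValueError(f"{model} requires a square confusion matrix")
    emission = emission_from_confusion(confusion)
    if model == "hmm-tc" and adjust:
        emission = adjust_emission_diagonal(emission)
    if model == "hmm-t-naive":
        transition = build_transition_naive(n)
    elif model == "hmm-t-naive-stable":
        transition = build_transition_naive_stable(n)
    else:
        transition = build_transition_default(
            n, class_roles, dissolve_prob=dissolve_prob, eps=eps
        )
    return HmmSpec(
        n_classes=n,
        n_bins=b,
        transition=transition,
        emission=emission,
        start=build_start_uniform(n),
        class_names=tuple(class_names) if class_names else None,
    )


# ---------------------------------------------------------------------------
# matrix CSV I/O
# ---------------------------------------------------------------------------

def write_matrix_csv(
    mat: np.ndarray,
    path: str | Path,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> None:
    """Write a probability matrix as labelled CSV at full double precision."""
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    n, m = mat.shape
    idx = list(row_labels) if row_labels else [f"class{i}" for i in range(n)]
    cols = list(col_labels) if col_labels else [f"obs{j}" for j in range(m)]
    df = pd.DataFrame(mat, index=idx, columns=cols)
    df.to_csv(path, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> np.ndarray:
    """Read a labelled CSV matrix back into a float array.

    Uses the round-trip float parser so matrices written at full precision
    are recovered bit-exactly.
    """
    return pd.read_csv(path, index_col=0, float_precision="round_trip").to_numpy(
        dtype=float
    )
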