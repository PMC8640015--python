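"""Synthetic 4D phantoms with known hidden truth.

The generator emulates the statistical structure of a time-resolved corrosion
tomography experiment: a static background (air around a base-material
cylinder) plus a dynamic region in which spherical inclusions of a dissolving
class irreversibly convert to a gas-pocket-like product class over time.  The
hidden truth is observed through a diagonal-dominant per-toxel noise process
standing in for an imperfect 3D segmenter, with per-toxel confidence values:
high (near 1) in instance interiors and near-tied (near 1/N) within one voxel
of a class boundary, where the observed label flickers between the two
adjacent classes — the "edge-toxel" pathology the HMM is designed to clean up.

The geometry itself (cylinder plus spheres) is incidental: the temporal model
treats every spatial site independently, so only the per-site statistics
matter.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .decode import ToxelSequence
from .params import build_transition_default

__all__ = [
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "scenario_fig4",
    "scenario_timestep_wipe",
    "boundary_mask",
    "DEFAULT_ROLES",
]

#: conventional class roles: 0 air, 1 base material, 2 dissolving, 3 product
DEFAULT_ROLES = {0: "air", 1: "base", 2: "dissolving", 3: "product"}


def _default_hidden_transition() -> np.ndarray:
    # physical evolution: irreversible dissolving -> product at 10% per step,
    # everything else static (no eps cross-terms in the *truth*)
    return build_transition_default(4, DEFAULT_ROLES, eps=0.0)


def _default_emission() -> np.ndarray:
    # segmenter noise: 95% correct, errors spread uniformly
    n = 4
    e = np.full((n, n), 0.05 / (n - 1))
    np.fill_diagonal(e, 0.95)
    return e


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic 4D acquisition.

    Defaults follow the experimental series the package models: 21 time steps
    over a 64^3 spatial grid with four classes (air / base / dissolving /
    product), a 10% per-step irreversible dissolving -> product conversion,
    95%-correct observations, and near-tied confidences at class boundaries.
    """

    shape: tuple[int, int, int, int] = (21, 64, 64, 64)
    n_classes: int = 4
    hidden_transition: np.ndarray = field(default_factory=_default_hidden_transition)
    emission: np.ndarray = field(default_factory=_default_emission)
    #: Beta concentration for interior-toxel confidence (drawn near 1)
    conf_interior_beta: tuple[float, float] = (18.0, 2.0)
    #: boundary toxels draw confidence near the 1/N degeneracy
    conf_boundary_jitter: float = 0.05
    #: probability a boundary toxel's observed label flips to its neighbour
    boundary_flip_prob: float = 0.5
    n_inclusions: int = 12
    inclusion_radius: tuple[int, int] = (4, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape) or len(self.shape) != 4:
            raise ValueError("shape must be four positive integers (T, Z, Y, X)")
        ht = np.asarray(self.hidden_transition, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        n = self.n_classes
        if ht.shape != (n, n):
            raise ValueError(f"hidden_transition must be ({n}, {n})")
        if em.shape[0] != n:
            raise ValueError(f"emission must have {n} rows")
        object.__setattr__(self, "hidden_transition", ht)
        object.__setattr__(self, "emission", em)


@dataclass(frozen=True)
class Phantom:
    """One generated phantom: hidden truth, noisy observation, confidence."""

    hidden: np.ndarray
    observed: np.ndarray
    confidence: np.ndarray
    config: PhantomConfig


def _hidden_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial 3D truth: air outside a base cylinder with dissolving spheres."""
    _, Z, Y, X = cfg.shape
    zz, yy, xx = np.meshgrid(
        np.arange(Z), np.arange(Y), np.arange(X), indexing="ij"
    )
    vol = np.zeros((Z, Y, X), dtype=np.int64)  # air
    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    radius = 0.42 * min(Y, X)
    cylinder = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    vol[cylinder] = 1  # base material
    # clamp inclusion radii so spheres fit small volumes
    r_hi = min(cfg.inclusion_radius[1], (Z - 1) // 2, max(int(radius) - 1, 1))
    r_lo = min(cfg.inclusion_radius[0], r_hi)
    for _ in range(cfg.n_inclusions):
        r = rng.integers(r_lo, r_hi + 1)
        # keep sphere centres well inside the cylinder
        z0 = rng.integers(r, max(Z - r, r + 1))
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(radius - r - 1, 1))
        y0 = cy + rad * np.sin(ang)
        x0 = cx + rad * np.cos(ang)
        sphere = (zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2 <= r**2
        vol[sphere & cylinder] = 2  # dissolving inclusion
    return vol


def _evolve_hidden(
    start: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Evolve the 3D truth through time by the hidden transition matrix."""
    T = cfg.shape[0]
    n = cfg.n_classes
    trans = cfg.hidden_transition
    cum = np.cumsum(trans, axis=1)
    hidden = np.empty((T,) + start.shape, dtype=np.int64)
    hidden[0] = start
    for t in range(1, T):
        u = rng.random(start.shape)
        # per-toxel categorical draw from the current class's transition row
        hidden[t] = np.sum(u[..., None] > cum[hidden[t - 1]], axis=-1)
    return np.minimum(hidden, n - 1)


def boundary_mask(hidden_t: np.ndarray) -> np.ndarray:
    """Toxels within one voxel of a class boundary in a 3D label volume."""
    mx = ndimage.maximum_filter(hidden_t, size=3, mode="nearest")
    mn = ndimage.minimum_filter(hidden_t, size=3, mode="nearest")
    return mx != mn


def _neighbour_class(
    hidden_t: np.ndarray, boundary: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """For each boundary toxel, the other class it is tied with (grey dilation
    picks the larger adjacent label, erosion the smaller; whichever differs)."""
    mx = ndimage.maximum_filter(hidden_t, size=3, mode="nearest")
    mn = ndimage.minimum_filter(hidden_t, size=3, mode="nearest")
    other = np.where(mx != hidden_t, mx, mn)
    return other[boundary]


def generate_phantom(cfg: PhantomConfig | None = None) -> Phantom:
    """Generate a (hidden, observed, confidence) phantom triplet.

    Deterministic given ``cfg.seed``.  The hidden volume never contains a
    product -> dissolving transition (the conversion is irreversible by
    construction of the default hidden transition matrix).
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    start = _hidden_geometry(cfg, rng)
    hidden = _evolve_hidden(start, cfg, rng)

    T = cfg.shape[0]
    n = cfg.n_classes
    lo = 1.0 / n
    cum_em = np.cumsum(cfg.emission, axis=1)
    observed = np.empty_like(hidden)
    confidence = np.empty(hidden.shape, dtype=np.float64)
    a, b = cfg.conf_interior_beta
    for t in range(T):
        h = hidden[t]
        u = rng.random(h.shape)
        obs = np.sum(u[..., None] > cum_em[h], axis=-1)
        obs = np.minimum(obs, cfg.emission.shape[1] - 1)
        # interior confidence: concentrated near 1, rescaled into (1/N, 1]
        conf = lo + (1.0 - lo) * rng.beta(a, b, size=h.shape)
        boundary = boundary_mask(h)
        nb = int(boundary.sum())
        if nb:
            # edge-toxels: near-tied probabilities, label flickers between
            # the two adjacent classes
            other = _neighbour_class(h, boundary, rng)
            flip = rng.random(nb) < cfg.boundary_flip_prob
            obs_b = np.where(flip, other, h[boundary])
            obs[boundary] = obs_b
            conf[boundary] = lo + cfg.conf_boundary_jitter * rng.random(nb) * (
                1.0 - lo
            )
        observed[t] = obs
        confidence[t] = np.clip(conf, np.nextafter(lo, 1.0), 1.0)
    return Phantom(hidden=hidden, observed=observed, confidence=confidence, config=cfg)


# ---------------------------------------------------------------------------
# behavioural scenarios
# ---------------------------------------------------------------------------

def scenario_fig4(
    direction: str = "forward",
    noise_steps: tuple[int, ...] = (8, 16),
    *,
    T: int = 21,
    transition_step: int = 6,
    dissolving: int = 2,
    product: int = 3,
) -> ToxelSequence:
    """Observation sequences for the behavioural transition experiments.

    ``forward``: a physically expected dissolving -> product sequence (switch
    at ``transition_step``) with isolated contrary "dissolving" observations
    at ``noise_steps`` — a well-behaved refiner overrides these reversals.

    ``reverse``: the physically improbable product -> dissolving direction,
    with contrary "dissolving" observations at ``noise_steps`` — a single
    isolated contrary observation should not flip the state, while a
    sustained run eventually should.
    """
    if direction not in {"forward", "reverse"}:
        raise ValueError("direction must be 'forward' or 'reverse'")
    for s in noise_steps:
        if not 0 <= s < T:
            raise ValueError(f"noise step {s} out of range [0, {T})")
    if direction == "forward":
        obs = np.full(T, product, dtype=np.int64)
        obs[:transition_step] = dissolving
        for s in noise_steps:
            if s >= transition_step:
                obs[s] = dissolving
    else:
        obs = np.full(T, product, dtype=np.int64)
        for s in noise_steps:
            obs[s] = dissolving
    return ToxelSequence(observations=obs)


def scenario_timestep_wipe(
    observed: np.ndarray, t: int, fill_class: int
) -> np.ndarray:
    """Simulated single-timestep data loss: one time slice set to one class."""
    observed = np.asarray(observed)
    if not 0 <= t < observed.shape[0]:
        raise ValueError(f"time index {t} out of range [0, {observed.shape[0]})")
    if fill_class < 0:
        raise ValueError("fill_class must be non-negative")
    out = observed.copy()
    out[t] = fill_class
    return out
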