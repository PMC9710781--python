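"""Reservoir connectivity conditions derived from a connectome.

Five conditions are supported, each isolating a different aspect of the
empirical connectivity while weights are always freshly drawn from the
classical ESN initialization, Uniform[-1, 1]:

* ``bio_rank`` — empirical binary topology; weights placed so their rank
  order matches the empirical strengths (strong empirical links get the most
  positive sampled weights).
* ``bio_no_rank`` — empirical binary topology; weights placed in a uniformly
  random permutation (no rank structure).
* ``random_density`` — fully random wiring matching the empirical link count.
* ``random_k`` — fully random wiring with a fixed number of connections per
  neuron (fan-in by default, k = 10 in the classical setting).
* ``random_full`` — all-to-all wiring (density 1).

All conditions exclude self-loops and are deterministic under ``seed``.
``scale_spectral_radius`` rescales a reservoir so its largest absolute
eigenvalue equals a target value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "CONDITIONS",
    "ReservoirMatrix",
    "sample_link_weights",
    "make_bio_rank",
    "make_bio_no_rank",
    "make_random_density",
    "make_random_k",
    "make_random_full",
    "scale_spectral_radius",
]

#: Canonical condition names (underscored in code, hyphenated on the CLI).
CONDITIONS = ("bio_rank", "bio_no_rank", "random_density", "random_k", "random_full")


@dataclass(frozen=True)
class ReservoirMatrix:
    """A neuron-level reservoir weight matrix with its provenance.

    ``weights`` is square and signed; before spectral scaling all entries lie
    in [-1, 1]. ``mask`` is True exactly where ``weights`` is nonzero and has
    a zero diagonal. ``area_of_neuron`` maps neuron index to source area for
    reservoirs built from upscaled connectomes.
    """

    weights: np.ndarray
    mask: np.ndarray
    condition: str
    seed: Optional[int] = None
    area_of_neuron: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"reservoir matrix must be square, got {w.shape}")
        if m.shape != w.shape:
            raise ValidationError("mask shape must match weights shape")
        if np.any(np.diag(m)):
            raise ValidationError("reservoir mask must have a zero diagonal")
        if np.any((w != 0) != m):
            raise ValidationError("weights must be nonzero exactly where mask is set")
        w = w.copy()
        w.setflags(write=False)
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "mask", m)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weights))))

    def replace_weights(self, weights: np.ndarray) -> "ReservoirMatrix":
        return ReservoirMatrix(
            weights=weights,
            mask=self.mask,
            condition=self.condition,
            seed=self.seed,
            area_of_neuron=self.area_of_neuron,
        )


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _source_weights(source) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Extract a non-negative weight matrix (and area map) from a Connectome,
    an UpscaledConnectome, or a raw array."""
    w = np.asarray(getattr(source, "weights", source), dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"source matrix must be square, got {w.shape}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValidationError("source weights must be finite and non-negative")
    area_of_neuron = getattr(source, "area_of_neuron", None)
    if area_of_neuron is not None:
        area_of_neuron = np.asarray(area_of_neuron, dtype=int)
    return w, area_of_neuron


def sample_link_weights(
    n_links: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n_links`` i.i.d. Uniform[-1, 1] link weights.

    Exact zeros (measure zero, but possible in floating point) are resampled
    so every link carries a nonzero weight, keeping the mask/weights
    equivalence exact.
    """
    if n_links < 0:
        raise ValidationError("n_links must be >= 0")
    rng = _as_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=n_links)
    zero = w == 0.0
    while np.any(zero):  # pragma: no cover - astronomically rare
        w[zero] = rng.uniform(-1.0, 1.0, size=int(zero.sum()))
        zero = w == 0.0
    return w


def _links_row_major(mask: np.ndarray) -> np.ndarray:
    """Link coordinates in row-major (source, target) order."""
    return np.argwhere(mask)


def rank_assign(strengths: np.ndarray, sampled: np.ndarray) -> np.ndarray:
    """Assign ``sampled`` values to links so their rank order matches ``strengths``.

    Both lists are sorted ascending and matched position by position; ties in
    ``strengths`` are broken by list position (stable sort), i.e. by
    (source, target) index order when links are enumerated row-major. Returns
    the assigned value for each link in the original link order.
    """
    strengths = np.asarray(strengths, dtype=float)
    sampled = np.asarray(sampled, dtype=float)
    if strengths.shape != sampled.shape:
        raise ValidationError("strengths and sampled weights must have equal length")
    order = np.argsort(strengths, kind="stable")
    out = np.empty_like(sampled)
    out[order] = np.sort(sampled)
    return out


def make_bio_rank(source, seed: int | None = None) -> ReservoirMatrix:
    """Empirical topology, weight rank order preserved.

    The mask equals the source's binary mask; freshly sampled Uniform[-1, 1]
    weights are placed so that sorting links by empirical strength and by
    assigned weight gives the same order (the strongest empirical link gets
    the most positive weight, the weakest the most negative).

    For upscaled sources (``area_of_neuron`` present) the rank alignment
    applies to the between-area links only: within-area (intrinsic) links
    are rule-generated and have no empirical strength to rank against, so
    they receive randomly placed weights from the same sampled pool.
    """
    w_emp, area_of_neuron = _source_weights(source)
    mask = w_emp > 0
    links = _links_row_major(mask)
    if links.shape[0] == 0:
        raise DegenerateInputError("source connectome has no links")
    rng = _as_rng(seed)
    sampled = sample_link_weights(links.shape[0], rng)
    out = np.zeros_like(w_emp)
    if area_of_neuron is not None:
        interareal = area_of_neuron[links[:, 0]] != area_of_neuron[links[:, 1]]
    else:
        interareal = np.ones(links.shape[0], dtype=bool)
    n_intra = int((~interareal).sum())
    if n_intra:
        pool = sampled[rng.permutation(sampled.size)]
        intra_w, inter_w = pool[:n_intra], pool[n_intra:]
        intra_links = links[~interareal]
        out[intra_links[:, 0], intra_links[:, 1]] = intra_w
    else:
        inter_w = sampled
    inter_links = links[interareal]
    strengths = w_emp[inter_links[:, 0], inter_links[:, 1]]
    out[inter_links[:, 0], inter_links[:, 1]] = rank_assign(strengths, inter_w)
    return ReservoirMatrix(out, mask, "bio_rank", seed, area_of_neuron)


def make_bio_no_rank(source, seed: int | None = None) -> ReservoirMatrix:
    """Empirical topology, weights placed in a uniformly random permutation."""
    w_emp, area_of_neuron = _source_weights(source)
    mask = w_emp > 0
    links = _links_row_major(mask)
    if links.shape[0] == 0:
        raise DegenerateInputError("source connectome has no links")
    rng = _as_rng(seed)
    sampled = sample_link_weights(links.shape[0], rng)
    assigned = sampled[rng.permutation(links.shape[0])]
    out = np.zeros_like(w_emp)
    out[links[:, 0], links[:, 1]] = assigned
    return ReservoirMatrix(out, mask, "bio_no_rank", seed, area_of_neuron)


def make_random_density(source, seed: int | None = None) -> ReservoirMatrix:
    """Fully random wiring with exactly the empirical number of links."""
    w_emp, area_of_neuron = _source_weights(source)
    n = w_emp.shape[0]
    n_links = int(np.count_nonzero(w_emp))
    rng = _as_rng(seed)
    offdiag = np.argwhere(~np.eye(n, dtype=bool))
    chosen = offdiag[rng.choice(offdiag.shape[0], size=n_links, replace=False)]
    out = np.zeros((n, n))
    out[chosen[:, 0], chosen[:, 1]] = sample_link_weights(n_links, rng)
    return ReservoirMatrix(out, out != 0, "random_density", seed, area_of_neuron)


def make_random_k(
    n: int, k: int, seed: int | None = None, degree: str = "in"
) -> ReservoirMatrix:
    """Fully random wiring with exactly ``k`` connections per neuron.

    ``degree="in"`` (default) fixes the fan-in: every neuron receives exactly
    ``k`` incoming links from distinct other neurons. ``degree="out"`` fixes
    the fan-out instead. Total links = n * k.
    """
    if n < 2:
        raise DegenerateInputError("need at least 2 neurons")
    if not 1 <= k <= n - 1:
        raise DegenerateInputError(f"k must be in [1, n-1]={n - 1}, got {k}")
    if degree not in ("in", "out"):
        raise ValidationError("degree must be 'in' or 'out'")
    rng = _as_rng(seed)
    out = np.zeros((n, n))
    others = np.arange(n - 1)
    for j in range(n):
        partners = rng.choice(others, size=k, replace=False)
        partners = np.where(partners >= j, partners + 1, partners)  # skip self
        w = sample_link_weights(k, rng)
        if degree == "in":
            out[partners, j] = w
        else:
            out[j, partners] = w
    return ReservoirMatrix(out, out != 0, "random_k", seed)


def make_random_full(n: int, seed: int | None = None) -> ReservoirMatrix:
    """All-to-all wiring: every ordered off-diagonal pair is a link (density 1)."""
    if n < 2:
        raise DegenerateInputError("need at least 2 neurons for a full reservoir")
    rng = _as_rng(seed)
    mask = ~np.eye(n, dtype=bool)
    out = np.zeros((n, n))
    out[mask] = sample_link_weights(n * (n - 1), rng)
    return ReservoirMatrix(out, mask, "random_full", seed)


def scale_spectral_radius(w, rho: float):
    """Rescale a reservoir so its spectral radius equals ``rho``.

    ``w`` may be a :class:`ReservoirMatrix` (returned as a new instance with
    the same mask and provenance) or a raw square array (returned as an
    array). The spectral radius is the largest absolute eigenvalue; matrices
    with (numerically) zero spectral radius — e.g. nilpotent, strictly
    triangular wiring — cannot be scaled and raise
    :class:`DegenerateInputError`.
    """
    if rho <= 0:
        raise ValidationError("rho must be positive")
    matrix = w.weights if isinstance(w, ReservoirMatrix) else np.asarray(w, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"reservoir matrix must be square, got {matrix.shape}")
    sr = float(np.max(np.abs(np.linalg.eigvals(matrix))))
    scale_floor = 1e-12 * max(1.0, float(np.max(np.abs(matrix), initial=0.0)))
    if sr <= scale_floor:
        raise DegenerateInputError(
            "spectral radius is (numerically) zero — nilpotent or empty wiring "
            "cannot be rescaled; add cycles or use a random condition"
        )
    scaled = matrix * (rho / sr)
    if isinstance(w, ReservoirMatrix):
        return w.replace_weights(scaled)
    return scaled
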