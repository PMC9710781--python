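"""Upscale an area-level connectome to a neuron-level network (bio2art).

Each area is replicated into ``neurons_per_area`` neurons. For every
area-level link (i, j) the full block of neuron pairs between the two areas
is connected and the empirical weight w_ij is partitioned over the block:

* homogeneous mapping — every neuron pair carries w_ij / neurons_per_area**2;
* heterogeneous mapping — w_ij is split by random proportions
  p_k = u_k / sum(u), u_k i.i.d. Uniform(0, 1).

Block totals therefore always equal the empirical weights (weight
conservation), and the area-level wiring diagram is preserved exactly: blocks
of empirical non-links stay empty.

Within-area (intrinsic) connectivity has no comprehensive empirical
counterpart and follows a rule instead: each area's total intrinsic weight is
``intrinsic_ratio`` times its total extrinsic (between-area, outgoing by
default) weight — the default ratio 0.8 reflects estimates that within-region
strength is roughly 80% of between-region strength. A fraction
``intra_conn_fraction`` of the neurons_per_area*(neurons_per_area-1) ordered
within-area pairs is formed (all of them by default) and the intrinsic total
is partitioned over the formed pairs with the same homogeneous/heterogeneous
rule. There are never neuron-level self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .connectome import Connectome
from .errors import DegenerateInputError, ValidationError

__all__ = ["UpscaledConnectome", "upscale", "area_mask"]

INTERAREAL_MODES = ("homogeneous", "heterogeneous")


@dataclass(frozen=True)
class UpscaledConnectome:
    """A neuron-level network produced by upscaling an area-level connectome."""

    weights: np.ndarray
    area_of_neuron: np.ndarray
    neurons_per_area: int
    interareal_mode: str
    intrinsic_ratio: float
    intra_conn_fraction: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "area_of_neuron", np.asarray(self.area_of_neuron, dtype=int)
        )

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_areas(self) -> int:
        return int(self.area_of_neuron.max()) + 1


def _positive_uniform(rng: np.random.Generator, size) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, size=size)
    zero = u == 0.0
    while np.any(zero):  # pragma: no cover - measure-zero event
        u[zero] = rng.uniform(0.0, 1.0, size=int(zero.sum()))
        zero = u == 0.0
    return u


def upscale(
    c: Connectome,
    neurons_per_area: int,
    interareal_mode: str = "homogeneous",
    intrinsic_ratio: float = 0.8,
    intra_conn_fraction: float = 1.0,
    seed: int | None = None,
    *,
    extrinsic: str = "out",
) -> UpscaledConnectome:
    """Scale ``c`` up to ``n_areas * neurons_per_area`` neurons.

    Parameters
    ----------
    c
        Source area-level connectome.
    neurons_per_area
        Scaling factor (>= 1). With 1 the interareal weights equal the
        empirical matrix exactly and intrinsic blocks are empty (an area of
        one neuron has no within-area pairs).
    interareal_mode
        ``"homogeneous"`` (equal partition) or ``"heterogeneous"`` (random
        proportions). The intrinsic partition follows the same mode.
    intrinsic_ratio
        Intrinsic-to-extrinsic weight ratio per area (default 0.8).
    intra_conn_fraction
        Fraction of realizable within-area ordered pairs that are formed
        (default 1 — all of them).
    seed
        Drives the heterogeneous proportions and the intra-pair subsampling.
    extrinsic
        Which extrinsic budget defines the intrinsic total: ``"out"`` (row
        sum, default), ``"in"`` (column sum) or ``"total"`` (both).
    """
    if neurons_per_area < 1:
        raise DegenerateInputError("neurons_per_area must be >= 1")
    if interareal_mode not in INTERAREAL_MODES:
        raise ValidationError(
            f"interareal_mode must be one of {INTERAREAL_MODES}, got {interareal_mode!r}"
        )
    if intrinsic_ratio < 0:
        raise ValidationError("intrinsic_ratio must be >= 0")
    if not 0 < intra_conn_fraction <= 1:
        raise ValidationError("intra_conn_fraction must be in (0, 1]")
    if extrinsic not in ("out", "in", "total"):
        raise ValidationError("extrinsic must be 'out', 'in' or 'total'")

    k = int(neurons_per_area)
    n = c.n_areas
    w_area = c.weights
    rng = np.random.default_rng(seed)
    weights = np.zeros((n * k, n * k))

    def block(i: int, j: int) -> tuple[slice, slice]:
        return slice(i * k, (i + 1) * k), slice(j * k, (j + 1) * k)

    # interareal blocks
    for i in range(n):
        for j in range(n):
            if i == j or w_area[i, j] == 0:
                continue
            if interareal_mode == "homogeneous":
                weights[block(i, j)] = w_area[i, j] / k**2
            else:
                u = _positive_uniform(rng, (k, k))
                weights[block(i, j)] = w_area[i, j] * u / u.sum()

    # intrinsic blocks
    out_budget = w_area.sum(axis=1)
    in_budget = w_area.sum(axis=0)
    budget = {"out": out_budget, "in": in_budget, "total": out_budget + in_budget}[extrinsic]
    n_pairs_all = k * (k - 1)
    if n_pairs_all > 0 and intrinsic_ratio > 0:
        intra_coords = np.argwhere(~np.eye(k, dtype=bool))
        for i in range(n):
            total = intrinsic_ratio * budget[i]
            if total == 0:
                continue
            if intra_conn_fraction < 1.0:
                m = max(1, int(round(intra_conn_fraction * n_pairs_all)))
                coords = intra_coords[
                    rng.choice(n_pairs_all, size=m, replace=False)
                ]
            else:
                coords = intra_coords
            rows = i * k + coords[:, 0]
            cols = i * k + coords[:, 1]
            if interareal_mode == "homogeneous":
                weights[rows, cols] = total / coords.shape[0]
            else:
                u = _positive_uniform(rng, coords.shape[0])
                weights[rows, cols] = total * u / u.sum()

    area_of_neuron = np.repeat(np.arange(n), k)
    return UpscaledConnectome(
        weights=weights,
        area_of_neuron=area_of_neuron,
        neurons_per_area=k,
        interareal_mode=interareal_mode,
        intrinsic_ratio=intrinsic_ratio,
        intra_conn_fraction=intra_conn_fraction,
        seed=seed,
    )


def area_mask(u: UpscaledConnectome) -> np.ndarray:
    """Area-level binary mask realized by an upscaled network.

    Entry (i, j), i != j, is True iff any neuron of area i connects to any
    neuron of area j. Equals the source connectome's binary mask by the
    block-preservation invariant.
    """
    k = u.neurons_per_area
    n = u.n_neurons // k
    blocks = u.weights.reshape(n, k, n, k)
    mask = blocks.any(axis=(1, 3))
    np.fill_diagonal(mask, False)
    return mask
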