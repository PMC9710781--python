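"""Area-level connectomes: container, I/O and a synthetic generator.

A connectome is a weighted, directed graph over brain areas stored as a square
non-negative matrix. The convention used everywhere in this package is
row = source, column = target: ``weights[i, j]`` is the strength of the
projection from area ``i`` to area ``j``. Self-projections at the area level
are not represented (the diagonal is zero).

Exchange formats
----------------
* Delimited text (CSV/TSV/whitespace): rectangular numeric matrix, ``#``
  comment lines ignored, optional single header row of area labels. This is
  the canonical exchange format.
* Binary container: a NumPy ``.npz`` archive with arrays ``weights`` and
  ``labels`` (used for bit-exact round-tripping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, FormatError, ValidationError

__all__ = [
    "Connectome",
    "load_connectome",
    "write_connectome",
    "generate_synthetic_connectome",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Connectome:
    """A validated area-level connectome.

    Parameters
    ----------
    weights
        Square matrix of non-negative connection strengths (arbitrary units),
        zero diagonal. ``weights[i, j]`` = strength from area ``i`` to ``j``.
    labels
        Ordered area names; defaults to ``area_0 .. area_{N-1}``.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"connectome matrix must be square, got shape {w.shape}")
        if w.size == 0:
            raise FormatError("connectome matrix is empty")
        if not np.all(np.isfinite(w)):
            raise ValidationError("connectome weights must be finite")
        if np.any(w < 0):
            raise ValidationError("connectome weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValidationError(
                "connectome diagonal must be zero (use load_connectome to "
                "strip self-projections from raw exports)"
            )
        labels = tuple(self.labels) if self.labels else tuple(
            f"area_{i}" for i in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for a {w.shape[0]}-area matrix"
            )
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", labels)

    @property
    def n_areas(self) -> int:
        return self.weights.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Binary topology: True where a link exists."""
        return self.weights > 0

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def density(self) -> float:
        """Fraction of realized links among the N(N-1) ordered off-diagonal pairs."""
        n = self.n_areas
        return self.n_links / (n * (n - 1)) if n > 1 else 0.0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Connectome(n_areas={self.n_areas}, n_links={self.n_links}, "
            f"density={self.density:.3f})"
        )


def _parse_delimited(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delimiter = "," if "," in lines[0] else ("\t" if "\t" in lines[0] else None)

    def split(line: str) -> list[str]:
        return [t.strip() for t in (line.split(delimiter) if delimiter else line.split())]

    first = split(lines[0])
    labels: tuple[str, ...] = ()
    try:
        [float(t) for t in first]
        data_lines = lines
    except ValueError:
        labels = tuple(first)
        data_lines = lines[1:]
        if not data_lines:
            raise FormatError(f"{path}: header but no data rows")
    rows = []
    width = None
    for ln in data_lines:
        toks = split(ln)
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise FormatError(f"{path}: ragged rows ({len(toks)} vs {width} columns)")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry ({exc})") from exc
    return np.array(rows, dtype=float), labels


def load_connectome(path: str | Path, format: str | None = None) -> Connectome:
    """Load a connectome from delimited text or the binary ``.npz`` container.

    ``format`` is ``"delimited"``, ``"binary"`` or ``None`` (infer from the
    ``.npz`` suffix). Nonzero diagonal entries are zeroed with a logged
    warning; negative or non-finite entries raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "binary" if path.suffix == ".npz" else "delimited"
    if format == "binary":
        with np.load(path, allow_pickle=False) as archive:
            weights = np.asarray(archive["weights"], dtype=float)
            labels = tuple(str(x) for x in archive["labels"]) if "labels" in archive else ()
    elif format == "delimited":
        weights, labels = _parse_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise FormatError(f"{path}: matrix is not square, shape {weights.shape}")
    diag = np.diag(weights)
    if np.any(diag != 0):
        logger.warning(
            "%s: zeroing %d nonzero diagonal entries (area-level self-projections "
            "are not represented)", path, int(np.count_nonzero(diag)),
        )
        weights = weights.copy()
        np.fill_diagonal(weights, 0.0)
    return Connectome(weights, labels)


def write_connectome(c: Connectome, path: str | Path, format: str | None = None) -> None:
    """Write ``c`` to ``path``.

    Delimited text is written with 17 significant digits (round-trips float64
    exactly); the binary container round-trips bit-exactly by construction.
    """
    path = Path(path)
    if format is None:
        format = "binary" if path.suffix == ".npz" else "delimited"
    if format == "binary":
        np.savez(path, weights=c.weights, labels=np.array(c.labels))
        return
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        with open(path, "w") as fh:
            fh.write(delimiter.join(c.labels) + "\n")
            np.savetxt(fh, c.weights, fmt="%.17g", delimiter=delimiter)
    except OSError as exc:
        raise OSError(f"cannot write connectome to {path}: {exc}") from exc


def _module_assignment(n_areas: int, n_modules: int) -> np.ndarray:
    ids = np.empty(n_areas, dtype=int)
    for m, chunk in enumerate(np.array_split(np.arange(n_areas), n_modules)):
        ids[chunk] = m
    return ids


def generate_synthetic_connectome(
    n_areas: int,
    n_modules: int,
    density: float,
    weight_scale: float = 1.0,
    seed: int | None = None,
    *,
    reciprocity: float = 0.8,
) -> Connectome:
    """Generate a synthetic connectome emulating empirical area-level statistics.

    The generated graph is directed, sparse at the requested ``density``
    (fraction of the N(N-1) ordered off-diagonal pairs), and modular:
    within-module ordered pairs are filled before between-module pairs, so for
    densities below the within-module capacity the graph is purely modular.
    Link weights are marginally log-normal (``exp(N(0, 1)) * weight_scale``,
    heavy-tailed and strictly positive). Reciprocal links share a common
    log-weight component so that ``corr(log w_ij, log w_ji) = reciprocity``,
    mirroring the strong weight reciprocity of tract-tracing and
    diffusion-imaging connectomes.

    Deterministic under ``seed``.
    """
    if not 1 <= n_modules <= n_areas:
        raise ValidationError("need n_areas >= n_modules >= 1")
    if not 0 < density <= 1:
        raise ValidationError("density must be in (0, 1]")
    if not 0 <= reciprocity <= 1:
        raise ValidationError("reciprocity must be in [0, 1]")
    if weight_scale <= 0:
        raise ValidationError("weight_scale must be positive")
    n_possible = n_areas * (n_areas - 1)
    n_links = int(round(density * n_possible))
    if n_links < 1:
        raise DegenerateInputError(
            f"density {density} on {n_areas} areas yields no links"
        )
    rng = np.random.default_rng(seed)
    module = _module_assignment(n_areas, n_modules)
    src, dst = np.where(~np.eye(n_areas, dtype=bool))
    intra = module[src] == module[dst]
    intra_pairs = np.flatnonzero(intra)
    inter_pairs = np.flatnonzero(~intra)
    chosen_intra = rng.permutation(intra_pairs)[:n_links]
    n_extra = n_links - chosen_intra.size
    chosen = (
        np.concatenate([chosen_intra, rng.permutation(inter_pairs)[:n_extra]])
        if n_extra > 0 else chosen_intra
    )
    # log-weight field: symmetric pair component + independent directional part,
    # variances chosen so the marginal stays standard normal in log space
    pair_component = rng.standard_normal((n_areas, n_areas))
    pair_component = np.triu(pair_component, 1) + np.triu(pair_component, 1).T
    directional = rng.standard_normal((n_areas, n_areas))
    log_w = np.sqrt(reciprocity) * pair_component + np.sqrt(1.0 - reciprocity) * directional
    weights = np.zeros((n_areas, n_areas))
    weights[src[chosen], dst[chosen]] = weight_scale * np.exp(log_w[src[chosen], dst[chosen]])
    return Connectome(weights)
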