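"""Entropy curves over scale and the branch-point signal.

At each scale ``y`` the height-field row is normalized to a probability
distribution over ``x`` and its Shannon entropy ``S(y)`` (nats) is taken.
A uniform partition of the unit interval into ``n`` equal segments has
entropy ``log n``; with ``n`` the number of ELIS branches alive at level
``y``, the deviation

    S~(y) = S(y) - log n

leaps wherever the tree branches, i.e. where a lower-rank ELIS emerges,
because ``n`` jumps while ``S`` changes smoothly.  The forward difference
``S'(y) = S~(y+1) - S~(y)`` therefore spikes at branch levels: its local
maxima are the per-protein branch-point signal that the cohort layer
correlates across proteins.

Integrals over ``x`` are discrete sums at unit bin width, so ``S`` is the
discretized differential entropy on the residue grid.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .scalespace import ElisTree, HeightField, _plateau_maxima, elis_at_level

logger = logging.getLogger(__name__)


@dataclass
class EntropyCurves:
    """Per-protein entropy statistics over contiguous levels.

    ``S_prime`` holds the forward differences and has one fewer entry
    than ``y_levels``; ``S_prime[i]`` belongs to level ``y_levels[i]``.
    """

    y_levels: np.ndarray
    S: np.ndarray
    n: np.ndarray
    S_dev: np.ndarray
    S_prime: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y_levels = np.asarray(self.y_levels, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.S_dev = np.asarray(self.S_dev, dtype=float)
        self.S_prime = np.asarray(self.S_prime, dtype=float)
        m = self.y_levels.size
        if not (self.S.size == self.n.size == self.S_dev.size == m):
            raise ValueError("S, n, S_dev must align with y_levels")
        if self.S_prime.size != max(m - 1, 0):
            raise ValueError("S_prime must have one fewer entry than y_levels")

    @property
    def prime_levels(self) -> np.ndarray:
        """Levels at which the forward difference is defined."""
        return self.y_levels[:-1]


def normalize_level(field: HeightField, y: int) -> np.ndarray:
    """Height-field row as a probability vector over ``x`` (unit bins).

    The largest element absorbs the rounding residual so the vector sums
    to 1 exactly; an all-zero row raises ``ValueError`` (callers skip the
    level with a warning).
    """
    row = field.row(y)
    total = row.sum()
    if total <= 0:
        raise ValueError(f"level y={y}: all-zero height row cannot be normalized")
    p = row / total
    # absorb the rounding residual into the largest element, which
    # cannot be driven negative by an O(eps) correction; exactness is
    # with respect to compensated summation
    for _ in range(3):
        residual = 1.0 - math.fsum(p)
        if residual == 0.0:
            break
        p[int(np.argmax(p))] += residual
    return p


def shannon_entropy(p: np.ndarray) -> float:
    """``-sum p log p`` in nats, with ``0 log 0 := 0``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_curves(field: HeightField, tree: ElisTree) -> EntropyCurves:
    """Compute ``S``, branch counts ``n``, ``S~`` and ``S'`` per level.

    ``field`` and ``tree`` must come from the same protein (checked via
    provenance).  Levels whose height row has no mass, or where no branch
    is alive, are skipped with a warning; the curves keep the longest
    contiguous run of valid levels.
    """
    fid = field.provenance.get("id")
    tid = tree.provenance.get("id")
    if fid is not None and tid is not None and fid != tid:
        raise ValueError(f"provenance mismatch: field {fid!r} vs tree {tid!r}")

    levels = np.sort(field.y_levels)
    good: list[int] = []
    s_by_level: dict[int, float] = {}
    n_by_level: dict[int, int] = {}
    for y in levels:
        y = int(y)
        n_alive = len(elis_at_level(tree, y))
        if n_alive == 0:
            warnings.warn(f"level y={y}: no ELIS alive, skipped", stacklevel=2)
            continue
        try:
            p = normalize_level(field, y)
        except ValueError:
            warnings.warn(f"level y={y}: zero-mass row, skipped", stacklevel=2)
            continue
        s_by_level[y] = shannon_entropy(p)
        n_by_level[y] = n_alive
        good.append(y)
    if not good:
        raise ValueError("no usable levels for entropy curves")

    # longest contiguous run (first one on ties)
    runs: list[list[int]] = [[good[0]]]
    for y in good[1:]:
        if y == runs[-1][-1] + 1:
            runs[-1].append(y)
        else:
            runs.append([y])
    run = max(runs, key=len)
    if len(run) < len(good):
        warnings.warn("entropy levels not contiguous; keeping longest run",
                      stacklevel=2)

    y_arr = np.array(run, dtype=int)
    S = np.array([s_by_level[y] for y in run])
    n = np.array([n_by_level[y] for y in run], dtype=int)
    S_dev = S - np.log(n)
    S_prime = np.diff(S_dev)
    return EntropyCurves(
        y_levels=y_arr, S=S, n=n, S_dev=S_dev, S_prime=S_prime,
        provenance=dict(field.provenance),
    )


def branch_point_signal(curves: EntropyCurves) -> set[int]:
    """Levels where ``S'`` has a strict interior local maximum.

    These mark the branch points of the hierarchy tree.  Endpoints of
    the level range are excluded: a monotone derivative has no peaks.
    """
    idx = _plateau_maxima(curves.S_prime, include_endpoints=False)
    return {int(curves.prime_levels[i]) for i in idx}


def write_curves(curves: EntropyCurves, path, extra_header: dict | None = None) -> None:
    """Export ``y  S  n  S_dev  S_prime`` as TSV (S_prime blank at the top level)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# id={curves.provenance.get('id', '')}\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("# columns=y\tS\tn\tS_dev\tS_prime\n")
        for i, y in enumerate(curves.y_levels):
            sp = repr(float(curves.S_prime[i])) if i < curves.S_prime.size else ""
            fh.write(
                f"{int(y)}\t{float(curves.S[i])!r}\t{int(curves.n[i])}\t"
                f"{float(curves.S_dev[i])!r}\t{sp}\n"
            )


def read_curves(path) -> EntropyCurves:
    """Read curves written by :func:`write_curves`."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, float, int, float, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError("curves file must have 5 columns")
            rows.append((int(parts[0]), float(parts[1]), int(parts[2]),
                         float(parts[3]), parts[4]))
    if not rows:
        raise ValueError("empty curves file")
    y = np.array([r[0] for r in rows], dtype=int)
    S = np.array([r[1] for r in rows])
    n = np.array([r[2] for r in rows], dtype=int)
    S_dev = np.array([r[3] for r in rows])
    S_prime = np.array([float(r[4]) for r in rows if r[4] != ""])
    return EntropyCurves(y_levels=y, S=S, n=n, S_dev=S_dev, S_prime=S_prime,
                         provenance={"id": meta.get("id", "")})
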