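"""Cohort-level detection of characteristic hierarchy scales.

For every level ``y``, the vector ``V_y`` collects the entropy-derivative
values ``S'(y)`` of all proteins in the cohort that possess that level.
If branch points concentrate at particular scales across proteins, the
normalized correlation

    r(y, y') = <V_y, V_y'> / sqrt(<V_y, V_y> <V_y', V_y'>)

has blocks of large entries around the diagonal.  Thresholding the
matrix and partitioning the diagonal into maximal all-above-threshold
squares yields the continuous square areas (CSA); scanning a decreasing
threshold schedule until the block structure repeats identifies the
stable CSA, whose level ranges are the cohort's characteristic scales.

Proteins differ in length, hence in available levels: correlations are
computed over pairwise-complete protein intersections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .entropy import EntropyCurves

logger = logging.getLogger(__name__)

#: Decreasing threshold schedule spanning 0.9 to 0.001, nine values.
DEFAULT_THRESHOLDS = (0.9, 0.7, 0.5, 0.3, 0.1, 0.05, 0.02, 0.01, 0.001)


@dataclass
class LevelVectors:
    """Per-level derivative vectors with protein membership masks."""

    levels: np.ndarray
    vectors: dict[int, np.ndarray]
    members: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)


@dataclass
class CohortMatrix:
    """Correlation matrix over levels; undefined entries are NaN."""

    levels: np.ndarray
    r: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)


@dataclass
class CsaBlock:
    """A maximal all-above-threshold diagonal square, in level units."""

    y_start: int
    y_end: int
    threshold_first_stable: float | None = None

    def key(self) -> tuple[int, int]:
        return (self.y_start, self.y_end)

    def overlaps(self, lo: int, hi: int) -> bool:
        return self.y_start <= hi and lo <= self.y_end


@dataclass
class StabilityResult:
    """Outcome of a threshold stability scan."""

    blocks: list[CsaBlock]
    threshold: float
    stable: bool


def build_level_vectors(
    cohort: Sequence[EntropyCurves], min_proteins: int = 10
) -> LevelVectors:
    """Collect ``S'`` values per level across the cohort.

    A protein contributes at ``y`` only if its derivative is defined
    there.  Levels with fewer than ``min_proteins`` contributors are
    dropped; if none survive a ``ValueError`` is raised.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    values: dict[int, list[float]] = {}
    members: dict[int, list[int]] = {}
    for idx, curves in enumerate(cohort):
        for i, y in enumerate(curves.prime_levels):
            y = int(y)
            values.setdefault(y, []).append(float(curves.S_prime[i]))
            members.setdefault(y, []).append(idx)
    levels = sorted(y for y in values if len(values[y]) >= min_proteins)
    if not levels:
        raise ValueError(
            f"no level is present in at least {min_proteins} proteins"
        )
    return LevelVectors(
        levels=np.array(levels, dtype=int),
        vectors={y: np.array(values[y]) for y in levels},
        members={y: np.array(members[y], dtype=int) for y in levels},
    )


def correlation_matrix(vectors: LevelVectors, min_pair: int = 10) -> CohortMatrix:
    """Normalized correlation ``r(y, y')`` over shared proteins.

    Pairs sharing fewer than ``min_pair`` proteins, and pairs involving a
    zero-norm restriction, are left undefined (NaN, logged).  Entries are
    clipped to [-1, 1] (Cauchy-Schwarz can be broken by last-ulp
    rounding) and the diagonal is exactly 1 for non-degenerate vectors.
    """
    levels = vectors.levels
    m = levels.size
    r = np.full((m, m), np.nan)
    pair_counts = np.zeros((m, m), dtype=int)
    for a in range(m):
        ya = int(levels[a])
        va, ma = vectors.vectors[ya], vectors.members[ya]
        for b in range(a, m):
            yb = int(levels[b])
            vb, mb = vectors.vectors[yb], vectors.members[yb]
            shared, ia, ib = np.intersect1d(ma, mb, return_indices=True)
            pair_counts[a, b] = pair_counts[b, a] = shared.size
            if shared.size < min_pair:
                continue
            xa, xb = va[ia], vb[ib]
            na, nb = float(xa @ xa), float(xb @ xb)
            if na == 0.0 or nb == 0.0:
                logger.info(
                    "zero-norm vector for pair (y=%d, y'=%d): undefined", ya, yb
                )
                continue
            val = float(xa @ xb) / np.sqrt(na * nb)
            r[a, b] = r[b, a] = min(1.0, max(-1.0, val))
    # cosine of a vector with itself is 1 by algebra; enforce it exactly
    for a in range(m):
        ya = int(levels[a])
        va = vectors.vectors[ya]
        if float(va @ va) > 0.0:
            r[a, a] = 1.0
    return CohortMatrix(levels=levels, r=r, pair_counts=pair_counts)


def threshold_mask(matrix: CohortMatrix, t: float) -> np.ndarray:
    """Binary mask: 1 where ``r > t`` (strict); diagonal always 1."""
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    with np.errstate(invalid="ignore"):
        mask = (matrix.r > t).astype(int)
    np.fill_diagonal(mask, 1)
    return mask


def detect_csa(mask: np.ndarray, levels=None) -> list[CsaBlock]:
    """Partition the diagonal into maximal all-ones squares, left to right.

    Extending a block is valid only while every element of the enlarged
    square is 1; because any all-ones square contains all its leading
    sub-squares, the greedy left-to-right construction is the unique such
    partition.  Singletons are allowed.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("mask must be a square matrix")
    if not np.array_equal(mask, mask.T):
        raise ValueError("mask must be symmetric")
    if not np.all(np.diag(mask) == 1):
        raise ValueError("mask must have a unit diagonal")
    m = mask.shape[0]
    if levels is None:
        levels = np.arange(1, m + 1)
    levels = np.asarray(levels, dtype=int)
    blocks: list[CsaBlock] = []
    a = 0
    while a < m:
        b = a
        # incremental check: the new row/column suffices by symmetry
        while b + 1 < m and mask[a : b + 2, b + 1].all():
            b += 1
        blocks.append(CsaBlock(y_start=int(levels[a]), y_end=int(levels[b])))
        a = b + 1
    return blocks


def stability_scan(
    matrix: CohortMatrix, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> StabilityResult:
    """Lower the threshold until the CSA partition repeats.

    Returns the first block set identical for two consecutive thresholds
    (tagged with the lower threshold of the pair); if the partition never
    repeats the final set is returned flagged unstable.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("threshold schedule must have length >= 2")
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("threshold schedule must be strictly decreasing")
    prev: list[CsaBlock] | None = None
    blocks: list[CsaBlock] = []
    for t in thresholds:
        blocks = detect_csa(threshold_mask(matrix, t), levels=matrix.levels)
        if prev is not None and [b.key() for b in blocks] == [b.key() for b in prev]:
            for b in blocks:
                b.threshold_first_stable = t
            return StabilityResult(blocks=blocks, threshold=t, stable=True)
        prev = blocks
    return StabilityResult(blocks=blocks, threshold=thresholds[-1], stable=False)


def write_matrix(matrix: CohortMatrix, path, extra_header: dict | None = None) -> None:
    """Export the correlation matrix as TSV with level headers."""
    with open(path, "wt", encoding="utf-8") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("y\t" + "\t".join(str(int(y)) for y in matrix.levels) + "\n")
        for y, row in zip(matrix.levels, matrix.r):
            fh.write(str(int(y)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path) -> CohortMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    levels: list[int] | None = None
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if levels is None:
                levels = [int(p) for p in parts[1:]]
                continue
            rows.append([float(p) for p in parts[1:]])
    if levels is None or not rows:
        raise ValueError("empty matrix file")
    r = np.array(rows)
    m = len(levels)
    if r.shape != (m, m):
        raise ValueError("matrix file is not square")
    return CohortMatrix(levels=np.array(levels, dtype=int), r=r,
                        pair_counts=np.zeros((m, m), dtype=int))


def write_mask(mask: np.ndarray, levels, path, extra_header: dict | None = None) -> None:
    """Export a binary mask as 0/1 TSV with level headers."""
    with open(path, "wt", encoding="utf-8") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("y\t" + "\t".join(str(int(y)) for y in levels) + "\n")
        for y, row in zip(levels, mask):
            fh.write(str(int(y)) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_csa(result: StabilityResult, path, extra_header: dict | None = None) -> None:
    """Export CSA blocks: ``y_start  y_end  stable_threshold`` TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write(f"# stable={result.stable}\n")
        fh.write(f"# threshold={result.threshold!r}\n")
        fh.write("y_start\ty_end\tstable_threshold\n")
        for b in result.blocks:
            t = "" if b.threshold_first_stable is None else repr(b.threshold_first_stable)
            fh.write(f"{b.y_start}\t{b.y_end}\t{t}\n")
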