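"""Inscribed-Gaussian scale space and the ELIS hierarchy tree.

For each scale ``y`` the height field

    H(x, y) = max { h : F(z) - h * exp(-(z - x)^2 / 2y^2) >= 0 for all z }
            = min_z  F(z) * exp(+(z - x)^2 / 2y^2)

measures the amplitude of the widest Gaussian of half-width ``y`` centred
at ``x`` that fits entirely under the smoothed profile ``F`` (computed at
the same ``y``).  ``H`` lives on the isosceles triangle with base
``x in [1, N]`` and height ``y in [1, N/2]``.

Tracking the local maxima of ``H(., y)`` from the widest scale downward
yields a tree: each maximum persists as a branch until it splits into
several maxima at some level, the branch point.  Branches are the ELIS
(ELements of Informational Structure): contiguous sequence intervals
arranged hierarchically — top ranks behave like domains, bottom ranks
like super-secondary/secondary-scale fragments.

Numerics: the product ``F(z) * exp(+big)`` is evaluated in the log
domain (see :func:`anis.profile.log_smoothed_values`), because the linear
factors under/overflow while their product stays moderate; the
minimization ``z`` runs over the residue grid ``[1, N]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .freqdb import K
from .profile import FrequencyProfile, SmoothedProfile, log_smoothed_values

logger = logging.getLogger(__name__)


@dataclass
class HeightField:
    """``H(x, y)`` on the triangular grid: rows are scales, columns x=1..N."""

    N: int
    y_levels: np.ndarray
    H: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y_levels = np.asarray(self.y_levels, dtype=int)
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (self.y_levels.size, self.N):
            raise ValueError("H must have shape (len(y_levels), N)")

    def row(self, y: int) -> np.ndarray:
        idx = np.flatnonzero(self.y_levels == y)
        if idx.size == 0:
            raise ValueError(f"level y={y} not computed")
        return self.H[idx[0]]


def _min_log_product(log_f_vals: np.ndarray, x_grid: np.ndarray, y: float) -> np.ndarray:
    """exp(min_z [log F(z) + (z-x)^2/2y^2]) for every x on the grid."""
    dist = (x_grid[:, None] - x_grid[None, :]) ** 2 / (2.0 * y * y)
    with np.errstate(invalid="ignore"):
        term = log_f_vals[:, None] + dist
    return np.exp(np.min(term, axis=0))


def inscribed_height(F: SmoothedProfile, x: float) -> float:
    """Inscribed-Gaussian amplitude at centre ``x`` and the scale of ``F``.

    Equals the exhaustive minimum over every grid point ``z`` of
    ``F(z) * exp((z - x)^2 / 2 y^2)``; returns 0 where F vanishes
    somewhere on the grid.
    """
    if not (F.x[0] <= x <= F.x[-1]):
        raise ValueError(f"x={x} outside the profile grid")
    with np.errstate(invalid="ignore"):
        term = F.log_values + (F.x - float(x)) ** 2 / (2.0 * F.y * F.y)
    m = np.min(term)
    return float(np.exp(m)) if m > -np.inf else 0.0


def height_field(profile: FrequencyProfile, y_levels=None) -> HeightField:
    """Evaluate ``H(x, y)`` for every integer level ``y`` (default 1..N//2)."""
    n = profile.record.length
    if n < K:
        raise ValueError(f"sequence {profile.record.id!r} shorter than {K}")
    if y_levels is None:
        y_levels = np.arange(1, n // 2 + 1)
    y_levels = np.asarray(y_levels, dtype=int)
    if y_levels.size == 0 or y_levels.min() < 1 or y_levels.max() > n // 2:
        raise ValueError(f"y levels must lie in 1..{n // 2}")
    x_grid = np.arange(1, n + 1, dtype=float)
    j = profile.positions.astype(float)
    H = np.empty((y_levels.size, n), dtype=float)
    for i, y in enumerate(y_levels):
        log_f = log_smoothed_values(profile.values, j, x_grid, float(y))
        H[i] = _min_log_product(log_f, x_grid, float(y))
    return HeightField(
        N=n,
        y_levels=y_levels,
        H=H,
        provenance={"id": profile.record.id, "delta": profile.delta, "grid": "int"},
    )


def _plateau_maxima(values: np.ndarray, include_endpoints: bool = True) -> list[int]:
    """0-based indices of strict local maxima with the plateau rule.

    An equal-valued plateau flanked by strictly smaller values on both
    existing sides counts as one maximum at its midpoint (rounded down).
    With ``include_endpoints`` a missing flank (domain endpoint) does not
    veto the maximum — but a plateau spanning the whole domain is never
    one; without it, maxima must be interior (both flanks present and
    strictly smaller).
    """
    n = len(values)
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        at_left, at_right = i == 0, j == n - 1
        left_ok = values[i - 1] < values[i] if not at_left else include_endpoints
        right_ok = values[j + 1] < values[i] if not at_right else include_endpoints
        if left_ok and right_ok and not (at_left and at_right):
            out.append((i + j) // 2)
        i = j + 1
    return out


def level_maxima(field: HeightField, y: int) -> list[int]:
    """Positions (1-based x) of local maxima of ``H(., y)``."""
    return [i + 1 for i in _plateau_maxima(field.row(y))]


@dataclass(eq=False)  # identity semantics: nodes are unique tree positions
class ElisNode:
    """One branch of the hierarchy tree.

    ``interval`` is the branch's sequence footprint: basin boundaries
    (midpoints between adjacent maxima, 1 and N at the flanks) at the
    branch's last level of existence, clipped into the parent interval.
    ``branch_point = (x0, y0)`` marks where the branch splits: ``y0`` is
    the first (highest) level at which the children appear separately and
    ``x0`` the branch's maximum position at its last level; absent for
    leaves.
    """

    y_birth: int
    y_death: int = 0
    interval: tuple[int, int] | None = None
    branch_point: tuple[int, int] | None = None
    children: list["ElisNode"] = dc_field(default_factory=list)
    rank: int = 1
    positions: dict[int, int] = dc_field(default_factory=dict, repr=False)

    def position_at(self, y: int) -> int:
        return self.positions[y]

    def alive_at(self, y: int) -> bool:
        return self.y_death <= y <= self.y_birth

    def to_dict(self) -> dict:
        return {
            "interval": list(self.interval) if self.interval else None,
            "y_birth": int(self.y_birth),
            "y_death": int(self.y_death),
            "branch_point": list(self.branch_point) if self.branch_point else None,
            "rank": int(self.rank),
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class ElisTree:
    """Forest of ELIS branches for one protein."""

    roots: list[ElisNode]
    N: int
    provenance: dict = dc_field(default_factory=dict)

    def iter_nodes(self):
        stack = list(self.roots)
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def branch_points(self) -> list[tuple[int, int]]:
        return sorted(
            n.branch_point for n in self.iter_nodes() if n.branch_point is not None
        )

    def to_dict(self) -> dict:
        return {
            "N": int(self.N),
            "provenance": dict(self.provenance),
            "roots": [r.to_dict() for r in self.roots],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_newick(self) -> str:
        def fmt(node: ElisNode) -> str:
            start, end = node.interval if node.interval else (0, 0)
            label = f"{start}_{end}"
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){label}"
            return label

        if not self.roots:
            return ";"
        if len(self.roots) == 1:
            return fmt(self.roots[0]) + ";"
        return "(" + ",".join(fmt(r) for r in self.roots) + ");"


def _basin_intervals(positions: list[int], n: int) -> list[tuple[int, int]]:
    """Disjoint basins covering [1, N]: split at midpoints of adjacent maxima."""
    bounds: list[tuple[int, int]] = []
    for i, p in enumerate(positions):
        start = 1 if i == 0 else (positions[i - 1] + p) // 2 + 1
        end = n if i == len(positions) - 1 else (p + positions[i + 1]) // 2
        bounds.append((start, end))
    return bounds


def _clip(interval: tuple[int, int], outer: tuple[int, int]) -> tuple[int, int]:
    start = min(max(interval[0], outer[0]), outer[1])
    end = max(min(interval[1], outer[1]), outer[0])
    return (start, end)


def build_elis_tree(field: HeightField) -> ElisTree:
    """Track level maxima from the widest scale down into an ELIS forest.

    Linking rule (the field literature gives none): each maximum at level
    ``y`` is assigned to the alive branch whose position at level ``y+1``
    is nearest, ties broken to the left (smaller position).  A branch
    receiving >= 2 maxima splits there; one receiving none dies.
    """
    levels = np.sort(field.y_levels)[::-1]
    if not np.array_equal(np.sort(field.y_levels), np.arange(1, field.y_levels.max() + 1)):
        raise ValueError("field must cover contiguous levels 1..y_max")
    n = field.N
    roots: list[ElisNode] = []
    active: list[ElisNode] = []
    prev_y: int | None = None
    for y in levels:
        pos = level_maxima(field, int(y))
        if not active:
            for p in pos:
                node = ElisNode(y_birth=int(y), rank=1, positions={int(y): p})
                roots.append(node)
                active.append(node)
            prev_y = int(y)
            continue
        prev_positions = [b.positions[prev_y] for b in active]
        assigned: dict[int, list[int]] = {i: [] for i in range(len(active))}
        for p in pos:
            dists = [abs(p - q) for q in prev_positions]
            best = min(range(len(active)), key=lambda i: (dists[i], prev_positions[i]))
            assigned[best].append(p)
        new_active: list[ElisNode] = []
        for i, branch in enumerate(active):
            kids = assigned[i]
            if len(kids) == 1:
                branch.positions[int(y)] = kids[0]
                new_active.append(branch)
            elif len(kids) == 0:
                branch.y_death = prev_y
            else:
                branch.y_death = prev_y
                branch.branch_point = (branch.positions[prev_y], int(y))
                for p in sorted(kids):
                    child = ElisNode(
                        y_birth=int(y), rank=branch.rank + 1, positions={int(y): p}
                    )
                    branch.children.append(child)
                    new_active.append(child)
        active = new_active
        prev_y = int(y)
    for branch in active:
        branch.y_death = int(levels[-1])
    if not roots:
        warnings.warn("height field has no maxima at any level: empty forest",
                      stacklevel=2)
        return ElisTree(roots=[], N=n, provenance=dict(field.provenance))

    # positions of all alive branches per level, for basin boundaries
    alive_at: dict[int, list[ElisNode]] = {}
    all_nodes: list[ElisNode] = []
    stack = list(roots)
    while stack:
        node = stack.pop()
        all_nodes.append(node)
        for y, _ in node.positions.items():
            alive_at.setdefault(y, []).append(node)
        stack.extend(node.children)

    def sibling_cells(
        nodes: list[ElisNode], outer: tuple[int, int]
    ) -> list[tuple[int, int]]:
        """Partition ``outer`` at midpoints of the nodes' birth positions.

        Siblings are confined to disjoint cells so their final basins
        (evaluated at different death levels) cannot overlap.  Boundaries
        are clamped monotonically into ``outer`` reserving one position
        per sibling, so cells stay non-empty even when maxima drift
        outside the parent footprint between levels.
        """
        positions = [b.positions[b.y_birth] for b in nodes]
        k = len(positions)
        lo, hi = outer
        cells = []
        prev_end = lo - 1
        for i in range(k):
            ideal = hi if i == k - 1 else (positions[i] + positions[i + 1]) // 2
            end = max(prev_end + 1, min(ideal, hi - (k - 1 - i)))
            cells.append((prev_end + 1, end))
            prev_end = end
        return cells

    bottom = int(levels[-1])

    def set_intervals(node: ElisNode, outer: tuple[int, int]) -> None:
        y = node.y_death
        peers = sorted(alive_at[y], key=lambda b: b.positions[y])
        positions = [b.positions[y] for b in peers]
        basin = _basin_intervals(positions, n)[peers.index(node)]
        node.interval = _clip(basin, outer)
        node.children.sort(key=lambda c: c.positions[c.y_birth])
        width = node.interval[1] - node.interval[0] + 1
        if len(node.children) > width:
            # maxima drifted outside the branch footprint between levels:
            # the split cannot be represented by disjoint sub-intervals,
            # so it is discarded as a tracking artifact
            logger.info(
                "pruning unrepresentable split of %d children in footprint %s",
                len(node.children), node.interval,
            )
            node.children = []
            node.branch_point = None
            node.y_death = bottom
            return
        for child, cell in zip(
            node.children, sibling_cells(node.children, node.interval)
        ):
            set_intervals(child, cell)

    roots.sort(key=lambda r: r.positions[r.y_birth])
    for root, cell in zip(roots, sibling_cells(roots, (1, n))):
        set_intervals(root, cell)
    return ElisTree(roots=roots, N=n, provenance=dict(field.provenance))


def elis_at_level(tree: ElisTree, y: int) -> list[tuple[int, int]]:
    """Disjoint, ordered intervals of all branches alive at level ``y``.

    A branch's interval is its fixed sequence footprint (an ELIS is a
    scale-independent segment); simultaneously alive branches have
    disjoint footprints by construction, and the intervals at a low
    level refine the intervals at a high level because child footprints
    nest inside their parents'.
    """
    if not (1 <= y <= tree.N // 2):
        raise ValueError(f"level y={y} outside 1..{tree.N // 2}")
    intervals = [
        node.interval
        for node in tree.iter_nodes()
        if node.alive_at(y) and node.interval is not None
    ]
    return sorted(intervals)


def write_field(field: HeightField, path, extra_header: dict | None = None) -> None:
    """Export the height field as a TSV matrix (rows y, columns x)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# id={field.provenance.get('id', '')}\n")
        fh.write(f"# N={field.N}\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("# rows=y, columns=x 1..N\n")
        for y, row in zip(field.y_levels, field.H):
            fh.write(str(int(y)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
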