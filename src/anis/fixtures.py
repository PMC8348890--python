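"""Synthetic databases, profiles and cohorts with known planted structure.

Every stage of the analysis can be exercised without a real protein
collection: random sequence databases over the 20-letter alphabet
(optionally with inflated pentapeptide frequencies), profiles whose
hierarchy trees have branch points at prescribed scales, and cohorts of
entropy-derivative curves whose peaks cluster in chosen level bands.

All generators are driven by an integer seed through a single
``numpy.random.default_rng`` stream, so outputs are byte-identical across
runs and platforms.  Planted profiles are certified at generation time by
running the package's own scale-space tracker on them, so a fixture that
does not carry its advertised structure is rejected, never silently
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .entropy import EntropyCurves
from .freqdb import ALPHABET, K, PentaFrequencyTable, SequenceRecord, count_pentapeptides
from .profile import FrequencyProfile
from .scalespace import build_elis_tree, height_field

logger = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic sequence database."""

    seed: int
    n_sequences: int
    length_range: tuple[int, int] = (50, 400)
    composition: dict[str, float] | None = None
    planted_motifs: Sequence[tuple[str, int]] = dc_field(default_factory=tuple)
    id_prefix: str = "SYN"

    def validate(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.composition is not None:
            if set(self.composition) - set(ALPHABET):
                raise ValueError("composition keys must be canonical residues")
            if any(w < 0 for w in self.composition.values()):
                raise ValueError("composition weights must be non-negative")
            if sum(self.composition.values()) <= 0:
                raise ValueError("composition weights must not all vanish")
        for motif, copies in self.planted_motifs:
            if len(motif) != K or set(motif) - set(ALPHABET):
                raise ValueError(f"motif must be a canonical pentapeptide: {motif!r}")
            if copies < 0:
                raise ValueError("motif copies must be >= 0")


def random_database(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord], PentaFrequencyTable]:
    """Reproducible random protein records plus their frequency table.

    Planted motifs are written over random positions of random records
    (later plants may overwrite earlier ones), inflating the motif's
    count far above the background.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(ALPHABET))
    if spec.composition is None:
        probs = None
    else:
        weights = np.array([spec.composition.get(c, 0.0) for c in ALPHABET])
        probs = weights / weights.sum()
    lo, hi = spec.length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_sequences)
    seqs = [
        "".join(rng.choice(letters, size=int(n), p=probs)) for n in lengths
    ]
    for motif, copies in spec.planted_motifs:
        eligible = [i for i, s in enumerate(seqs) if len(s) >= K]
        if not eligible:
            if copies:
                logger.info("no sequence long enough to plant motif %r", motif)
            continue
        for _ in range(copies):
            i = eligible[int(rng.integers(len(eligible)))]
            pos = int(rng.integers(len(seqs[i]) - K + 1))
            seqs[i] = seqs[i][:pos] + motif + seqs[i][pos + K :]
    width = len(str(max(spec.n_sequences, 1)))
    records = [
        SequenceRecord(id=f"{spec.id_prefix}{i:0{width}d}", residues=s)
        for i, s in enumerate(seqs)
    ]
    return records, count_pentapeptides(records)


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic bytes)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _profile_from_values(values: np.ndarray, n: int, kind: str) -> FrequencyProfile:
    record = SequenceRecord(id=f"planted_{kind}", residues="A" * n)
    return FrequencyProfile(record=record, values=values)


def planted_profile(kind: str, **params) -> FrequencyProfile:
    """Synthetic profiles with known scale-space structure.

    kinds:
      ``impulse``      — one nonzero value ``c`` at position ``j0``;
                         a single branch, no branch points.
      ``two_impulse``  — equal impulses at ``j1 < j2``; one branch point
                         whose level grows with the separation.
      ``multi_scale``  — two impulse pairs arranged so branch points fall
                         inside two prescribed, well-separated level
                         ``bands``; certified by running the tracker.

    Common parameter: ``n`` (sequence length, default 100/120).
    """
    if kind == "impulse":
        n = int(params.pop("n", 100))
        j0 = int(params.pop("j0", n // 2))
        c = float(params.pop("c", 100.0))
        _reject_extra(params)
        _check_position(j0, n)
        values = np.zeros(n - K + 1)
        values[j0 - 3] = c
        return _profile_from_values(values, n, kind)

    if kind == "two_impulse":
        n = int(params.pop("n", 100))
        j1 = int(params.pop("j1", n // 3))
        j2 = int(params.pop("j2", 2 * n // 3))
        c = float(params.pop("c", 100.0))
        _reject_extra(params)
        if j2 <= j1:
            raise ValueError(f"need j1 < j2, got {j1}, {j2}")
        _check_position(j1, n)
        _check_position(j2, n)
        values = np.zeros(n - K + 1)
        values[j1 - 3] = c
        values[j2 - 3] = c
        return _profile_from_values(values, n, kind)

    if kind == "multi_scale":
        n = int(params.pop("n", 120))
        bands = [tuple(map(int, b)) for b in params.pop("bands", ((3, 6), (15, 20)))]
        c = float(params.pop("c", 100.0))
        _reject_extra(params)
        if len(bands) != 2:
            raise ValueError("multi_scale expects exactly two bands")
        (lo1, hi1), (lo2, hi2) = sorted(bands)
        if not (1 <= lo1 <= hi1 < lo2 <= hi2 <= n // 2):
            raise ValueError(f"bands must be disjoint and within 1..{n // 2}")
        return _planted_multi_scale(n, (lo1, hi1), (lo2, hi2), c)

    raise ValueError(f"unknown planted profile kind: {kind!r}")


def _reject_extra(params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters: {sorted(params)}")


def _check_position(j: int, n: int) -> None:
    if not (3 <= j <= n - 2):
        raise ValueError(f"impulse position {j} outside 3..{n - 2}")


def _branch_levels(profile: FrequencyProfile) -> list[int]:
    tree = build_elis_tree(height_field(profile))
    return [y0 for (_, y0) in tree.branch_points()]


def _planted_multi_scale(
    n: int, low: tuple[int, int], high: tuple[int, int], c: float
) -> FrequencyProfile:
    """Two impulse pairs; separations found by a small deterministic search.

    Two equal Gaussians merge into one maximum when the half-width
    reaches about half their separation, so candidate separations are
    scanned around twice each band midpoint and the first layout whose
    tracker-detected branch levels hit both bands is returned.
    """
    lo1, hi1 = low
    lo2, hi2 = high
    centre = (n + 1) / 2.0

    def candidates(lo: int, hi: int) -> list[int]:
        mid = (lo + hi) / 2.0
        base = int(round(2.0 * mid))
        seen, out = set(), []
        for d in sorted(range(2 * lo - 2, 2 * hi + 5), key=lambda d: abs(d - base)):
            if d >= 2 and d not in seen:
                seen.add(d)
                out.append(d)
        return out

    for d_high in candidates(lo2, hi2):
        for d_low in candidates(lo1, hi1):
            positions = []
            for cluster in (centre - d_high / 2.0, centre + d_high / 2.0):
                positions.extend(
                    [int(round(cluster - d_low / 2.0)), int(round(cluster + d_low / 2.0))]
                )
            if min(positions) < 3 or max(positions) > n - 2:
                continue
            if len(set(positions)) < 4:
                continue
            values = np.zeros(n - K + 1)
            for p in positions:
                values[p - 3] = c
            profile = _profile_from_values(values, n, "multi_scale")
            levels = _branch_levels(profile)
            if any(lo1 <= y <= hi1 for y in levels) and any(
                lo2 <= y <= hi2 for y in levels
            ):
                return profile
    raise ValueError(
        f"no impulse layout with branch points in bands {low} and {high} "
        f"fits a sequence of length {n}"
    )


def planted_cohort(
    seed: int,
    n_proteins: int,
    level_bands: Sequence[tuple[int, int]],
    noise: float = 0.1,
    n_levels: int = 26,
) -> list[EntropyCurves]:
    """Cohort of entropy curves whose derivative peaks sit in given bands.

    Each band gets one amplitude per protein, drawn standard normal and
    Gram-Schmidt-orthogonalized across bands, so at ``noise = 0`` the
    cohort correlation matrix is exactly block structured: 1 within a
    band, 0 between bands, degenerate elsewhere.  Gaussian noise of
    standard deviation ``noise`` is then added to every derivative value.
    Curves span levels ``1..n_levels`` (derivatives on ``1..n_levels-1``).
    """
    bands = [tuple(map(int, b)) for b in level_bands]
    for lo, hi in bands:
        if not (1 <= lo <= hi <= n_levels - 1):
            raise ValueError(f"band ({lo}, {hi}) outside 1..{n_levels - 1}")
    for (lo1, hi1), (lo2, hi2) in zip(sorted(bands), sorted(bands)[1:]):
        if hi1 >= lo2:
            raise ValueError("level bands must be disjoint")
    if n_proteins < len(bands) + 1:
        raise ValueError("need more proteins than bands for orthogonalization")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    amps = rng.standard_normal((len(bands), n_proteins))
    # orthogonalize band amplitude vectors (exact zero cross-band dot)
    for b in range(len(bands)):
        for prev in range(b):
            amps[b] -= (amps[b] @ amps[prev]) / (amps[prev] @ amps[prev]) * amps[prev]
        amps[b] *= np.sqrt(n_proteins) / np.linalg.norm(amps[b])
    n_prime = n_levels - 1
    sprime = np.zeros((n_proteins, n_prime))
    for b, (lo, hi) in enumerate(bands):
        sprime[:, lo - 1 : hi] = amps[b][:, None]
    if noise > 0:
        sprime = sprime + noise * rng.standard_normal(sprime.shape)
    curves = []
    for i in range(n_proteins):
        s_dev = np.concatenate([[0.0], np.cumsum(sprime[i])])
        curves.append(
            EntropyCurves(
                y_levels=np.arange(1, n_levels + 1),
                S=s_dev.copy(),
                n=np.ones(n_levels, dtype=int),
                S_dev=s_dev,
                S_prime=sprime[i],
                provenance={"id": f"planted_{i:04d}", "bands": bands},
            )
        )
    return curves
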