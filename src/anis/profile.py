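"""Per-protein total-frequency profiles and their Gaussian smoothing.

A protein ``I = i1..iN`` is read as the sequence of its overlapping
pentapeptides, enumerated by central residue ``j = 3..N-2``.  The profile
``f(j) = Phi(I_j)`` records the database total frequency of each window.
Smoothing with a Gaussian of half-width ``y``,

    F(x) = sum_j f(j) * g(x - j, y),    g(x, y) = exp(-x^2 / 2y^2) / (y sqrt(2 pi)),

turns the integer-indexed profile into a continuous-scale frequency
distribution evaluated on the residue grid ``x = 1..N``.  The sum runs
only over existing ``j`` — there is no renormalization at the sequence
ends, so F decays toward the termini by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .freqdb import K, PentaFrequencyTable, SequenceRecord, total_frequency

logger = logging.getLogger(__name__)

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Kernel truncation radius, in units of y, for the linear-domain sum.
#: The dropped tail mass is below 1e-14 of the kernel.
TRUNCATION_RADIUS = 8.0


@dataclass
class FrequencyProfile:
    """Total frequencies ``f(j)`` for one protein, ``j = 3..N-2`` (1-based)."""

    record: SequenceRecord
    values: np.ndarray
    delta: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.record.length
        if n < K:
            raise ValueError(f"sequence {self.record.id!r} shorter than {K}")
        if self.values.shape != (n - K + 1,):
            raise ValueError(
                f"profile must have N-4 = {n - K + 1} values, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        """Central-residue positions ``j = 3..N-2`` (1-based)."""
        return np.arange(3, self.record.length - 1)


@dataclass
class SmoothedProfile:
    """``F(x)`` at one scale ``y`` on the residue grid ``x = 1..N``.

    ``values`` is the truncated linear-domain sum (exported artifact);
    ``log_values`` is the untruncated log-domain evaluation used by the
    scale-space layer, where products with large exponential weights must
    stay finite.
    """

    y: float
    x: np.ndarray
    values: np.ndarray
    log_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, values, y: float, x=None) -> "SmoothedProfile":
        """Wrap explicit profile values (used for analytic fixtures)."""
        values = np.asarray(values, dtype=float)
        if x is None:
            x = np.arange(1, values.size + 1, dtype=float)
        with np.errstate(divide="ignore"):
            log_values = np.log(values)
        return cls(y=float(y), x=np.asarray(x, dtype=float), values=values,
                   log_values=log_values, provenance={"source": "explicit"})


def frequency_profile(
    record: SequenceRecord, table: PentaFrequencyTable, delta: int = 1
) -> FrequencyProfile:
    """Profile of total frequencies for every window of ``record``.

    Windows containing non-canonical residues get ``f = 0`` (with a
    warning from the frequency layer).
    """
    n = record.length
    if n < K:
        raise ValueError(f"sequence {record.id!r} shorter than {K} residues")
    values = np.empty(n - K + 1, dtype=float)
    for i in range(n - K + 1):
        values[i] = total_frequency(table, record.residues[i : i + K], delta)
    return FrequencyProfile(record=record, values=values, delta=delta)


def gaussian_kernel(x, y: float):
    """Normalized Gaussian ``g(x, y)``; symmetric, maximal at ``x = 0``."""
    if y <= 0:
        raise ValueError(f"scale y must be positive, got {y}")
    x = np.asarray(x, dtype=float)
    out = np.exp(-(x**2) / (2.0 * y * y)) / (y * _SQRT_2PI)
    return float(out) if out.ndim == 0 else out


def log_smoothed_values(
    f: np.ndarray, j: np.ndarray, x: np.ndarray, y: float
) -> np.ndarray:
    """``log F(x)`` by logsumexp over all windows, without truncation.

    Entries with ``f(j) = 0`` drop out as ``-inf`` terms; an all-zero
    profile yields ``-inf`` everywhere (F identically zero).
    """
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        log_f = np.log(f)
    terms = (
        log_f[None, :]
        - math.log(y * _SQRT_2PI)
        - (np.asarray(x, dtype=float)[:, None] - np.asarray(j, dtype=float)[None, :]) ** 2
        / (2.0 * y * y)
    )
    with np.errstate(invalid="ignore"):
        return logsumexp(terms, axis=1)


def smoothed_profile(
    profile: FrequencyProfile, y: float, truncate: float = TRUNCATION_RADIUS
) -> SmoothedProfile:
    """Gaussian-smoothed profile ``F(x)`` on the grid ``x = 1..N``.

    The linear-domain sum is truncated at ``|x - j| > truncate * y``
    (dropped mass < 1e-14); pass ``truncate=np.inf`` for the exact sum.
    """
    if y <= 0:
        raise ValueError(f"scale y must be positive, got {y}")
    n = profile.record.length
    x = np.arange(1, n + 1, dtype=float)
    j = profile.positions.astype(float)
    diff = x[:, None] - j[None, :]
    kernel = np.exp(-(diff**2) / (2.0 * y * y)) / (y * _SQRT_2PI)
    if np.isfinite(truncate):
        kernel = np.where(np.abs(diff) <= truncate * y, kernel, 0.0)
    values = kernel @ profile.values
    log_values = log_smoothed_values(profile.values, j, x, y)
    return SmoothedProfile(
        y=float(y),
        x=x,
        values=values,
        log_values=log_values,
        provenance={"id": profile.record.id, "delta": profile.delta},
    )


def write_profile(profile: FrequencyProfile, path, smoothed: SmoothedProfile | None = None,
                  extra_header: dict | None = None) -> None:
    """Export ``position <TAB> f`` (and optionally ``position <TAB> F``) as TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# id={profile.record.id}\n")
        fh.write(f"# delta={profile.delta}\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("# columns=position\tf\n")
        for j, v in zip(profile.positions, profile.values):
            fh.write(f"{int(j)}\t{float(v)!r}\n")
        if smoothed is not None:
            fh.write(f"# y={smoothed.y}\n")
            fh.write("# columns=position\tF\n")
            for xv, fv in zip(smoothed.x, smoothed.values):
                fh.write(f"{int(xv)}\t{float(fv)!r}\n")
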