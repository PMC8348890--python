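"""Pentapeptide occurrence tables over protein sequence collections.

The elementary unit of sequence here is the pentapeptide: a contiguous
window of five residues.  Scanning a (non-redundant) protein collection
with unit stride — neighbouring windows overlap by four residues — yields
an occurrence count ``phi(A)`` for every pentapeptide ``A``.  The *total
frequency* ``Phi(A)`` additionally pools the counts over the Hamming ball
of radius ``delta`` around ``A``, so that conservative substitutions of up
to ``delta`` residues contribute to the signal.  ``delta = 1`` is the
standard setting; radii up to 3 widen the evolutionary neighbourhood.

Only the 20 canonical residues are counted.  Windows containing any other
character (X, B, Z, U, J, O, ``*``, gaps, ...) are skipped during counting
and receive a total frequency of 0 during profiling; a per-scan skip count
is logged.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHASET = frozenset(ALPHABET)

#: Window size: the pentapeptide is the unit of sequence.
K = 5

#: Largest supported Hamming-ball radius.
MAX_DELTA = 3

FastaSource = Union[str, Path, IO[str]]


class FastaFormatError(ValueError):
    """Raised for unreadable or malformed FASTA input."""


class TableFormatError(ValueError):
    """Raised when a serialized frequency table is corrupt or partial."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: an identifier and its residue string.

    Residues are upper-cased on read and may retain non-canonical
    characters; those are excluded at the window level, not the record
    level, so residue numbering is preserved.
    """

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - trivial alias
        return len(self.residues)


@dataclass
class PentaFrequencyTable:
    """Occurrence counts ``phi(A)`` for pentapeptides over a collection.

    ``n_fragments_total`` is the number of windows actually counted, so
    the conservation invariant ``sum(counts.values()) ==
    n_fragments_total`` always holds; on input restricted to the canonical
    alphabet it equals ``sum(max(N - 4, 0))`` over records.
    """

    counts: dict[str, int]
    n_sequences: int
    n_fragments_total: int
    length_bounds: tuple[int, int] | None = None
    alphabet: str = ALPHABET
    _phi_cache: dict[tuple[str, int], int] = field(
        default_factory=dict, repr=False, compare=False
    )

    def phi(self, fragment: str) -> int:
        """Plain occurrence count of one pentapeptide (0 if unseen)."""
        return self.counts.get(fragment, 0)


def _as_handle(source: FastaSource):
    if hasattr(source, "read"):
        return source, False
    return open(source, "rt", encoding="utf-8"), True


def read_fasta(source: FastaSource) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into upper-cased records.

    Raises :class:`FastaFormatError` for empty identifiers, duplicate
    identifiers (the method presumes non-redundant input) and files that
    do not parse as FASTA.
    """
    handle, close = _as_handle(source)
    try:
        records: list[SequenceRecord] = []
        seen: set[str] = set()
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except (ValueError, UnicodeDecodeError) as exc:
            raise FastaFormatError(f"malformed FASTA input: {exc}") from exc
        for rec in parsed:
            if not rec.id:
                raise FastaFormatError("record with empty identifier")
            if rec.id in seen:
                raise FastaFormatError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper().replace(" ", "")
            records.append(SequenceRecord(id=rec.id, residues=residues))
        return records
    finally:
        if close:
            handle.close()


def scan_database(
    fasta_source: FastaSource, min_len: int = 50, max_len: int = 400
) -> list[SequenceRecord]:
    """Read a FASTA collection, keeping records with ``min_len <= N <= max_len``.

    Bounds are inclusive.  Input order is preserved.  An empty result
    triggers a :class:`UserWarning` and returns an empty list.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length bounds ({min_len}, {max_len})")
    records = read_fasta(fasta_source)
    kept = [r for r in records if min_len <= r.length <= max_len]
    if not kept:
        warnings.warn(
            f"no sequences within length bounds [{min_len}, {max_len}]",
            stacklevel=2,
        )
    return kept


def _canonical_window(window: str) -> bool:
    return all(c in _ALPHASET for c in window)


def count_pentapeptides(records: Iterable[SequenceRecord]) -> PentaFrequencyTable:
    """Count every overlapping pentapeptide window over ``records``.

    Windows advance by one residue.  Records shorter than 5 residues
    contribute nothing; windows containing non-canonical characters are
    skipped (logged in aggregate).
    """
    counts: dict[str, int] = {}
    n_sequences = 0
    n_windows = 0
    n_skipped = 0
    n_short = 0
    for rec in records:
        n_sequences += 1
        s = rec.residues
        if len(s) < K:
            n_short += 1
            continue
        for i in range(len(s) - K + 1):
            window = s[i : i + K]
            if _canonical_window(window):
                counts[window] = counts.get(window, 0) + 1
                n_windows += 1
            else:
                n_skipped += 1
    if n_short:
        logger.info("skipped %d records shorter than %d residues", n_short, K)
    if n_skipped:
        logger.info("skipped %d windows containing non-canonical residues", n_skipped)
    return PentaFrequencyTable(
        counts=counts, n_sequences=n_sequences, n_fragments_total=n_windows
    )


def _check_fragment(fragment: str) -> None:
    if len(fragment) != K:
        raise ValueError(f"fragment must have length {K}, got {fragment!r}")
    if not _canonical_window(fragment):
        raise ValueError(f"fragment contains non-canonical residues: {fragment!r}")


def hamming_neighbors(fragment: str, delta: int) -> set[str]:
    """All pentapeptides within Hamming distance ``delta`` of ``fragment``.

    Includes ``fragment`` itself.  Ball sizes over the 20-letter alphabet:
    1 (delta=0), 96 (delta=1), 3706 (delta=2), 72296 (delta=3).
    """
    _check_fragment(fragment)
    if delta not in range(MAX_DELTA + 1):
        raise ValueError(f"delta must be in 0..{MAX_DELTA}, got {delta}")
    ball = {fragment}
    for k in range(1, delta + 1):
        for positions in itertools.combinations(range(K), k):
            for repl in itertools.product(ALPHABET, repeat=k):
                # substitutions equal to the original letter belong to a
                # smaller radius and were added already
                if any(repl[i] == fragment[p] for i, p in enumerate(positions)):
                    continue
                chars = list(fragment)
                for i, p in enumerate(positions):
                    chars[p] = repl[i]
                ball.add("".join(chars))
    return ball


def total_frequency(
    table: PentaFrequencyTable, fragment: str, delta: int = 1
) -> int:
    """Total frequency ``Phi(A)``: counts summed over the Hamming ball.

    ``Phi(A, 0) == phi(A)`` and ``Phi`` is non-decreasing in ``delta``.
    Fragments containing non-canonical characters return 0 with a
    warning, so dirty windows simply vanish from profiles.
    """
    if delta not in range(MAX_DELTA + 1):
        raise ValueError(f"delta must be in 0..{MAX_DELTA}, got {delta}")
    if len(fragment) != K or not _canonical_window(fragment):
        warnings.warn(
            f"non-canonical fragment {fragment!r}: total frequency taken as 0",
            stacklevel=2,
        )
        return 0
    key = (fragment, delta)
    cached = table._phi_cache.get(key)
    if cached is not None:
        return cached
    counts = table.counts
    total = sum(counts.get(j, 0) for j in hamming_neighbors(fragment, delta))
    table._phi_cache[key] = total
    return total


def write_table(
    table: PentaFrequencyTable,
    path: str | Path,
    extra_header: dict[str, str] | None = None,
) -> None:
    """Serialize a table as TSV: ``#`` metadata headers, then sorted keys."""
    bounds = (
        "none"
        if table.length_bounds is None
        else f"{table.length_bounds[0]},{table.length_bounds[1]}"
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# pentapeptide frequency table\n")
        fh.write(f"# n_sequences={table.n_sequences}\n")
        fh.write(f"# n_fragments_total={table.n_fragments_total}\n")
        fh.write(f"# length_bounds={bounds}\n")
        for key, value in (extra_header or {}).items():
            fh.write(f"# {key}={value}\n")
        for fragment in sorted(table.counts):
            fh.write(f"{fragment}\t{table.counts[fragment]}\n")


def read_table(path: str | Path) -> PentaFrequencyTable:
    """Read a table written by :func:`write_table` (round-trip identity)."""
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
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
            if len(parts) != 2:
                raise TableFormatError(f"line {lineno}: expected 2 columns")
            fragment, raw = parts
            if len(fragment) != K:
                raise TableFormatError(
                    f"line {lineno}: key {fragment!r} is not a pentapeptide"
                )
            try:
                count = int(raw)
            except ValueError as exc:
                raise TableFormatError(f"line {lineno}: bad count {raw!r}") from exc
            if count < 0:
                raise TableFormatError(f"line {lineno}: negative count")
            if fragment in counts:
                raise TableFormatError(f"line {lineno}: duplicate key {fragment!r}")
            counts[fragment] = count
    try:
        n_sequences = int(meta["n_sequences"])
        n_fragments_total = int(meta["n_fragments_total"])
    except (KeyError, ValueError) as exc:
        raise TableFormatError(f"missing or invalid metadata header: {exc}") from exc
    bounds_raw = meta.get("length_bounds", "none")
    length_bounds = None
    if bounds_raw != "none":
        try:
            lo, hi = bounds_raw.split(",")
            length_bounds = (int(lo), int(hi))
        except ValueError as exc:
            raise TableFormatError(f"invalid length_bounds: {bounds_raw!r}") from exc
    if sum(counts.values()) != n_fragments_total:
        raise TableFormatError(
            "count conservation violated: file is corrupt or partial"
        )
    return PentaFrequencyTable(
        counts=counts,
        n_sequences=n_sequences,
        n_fragments_total=n_fragments_total,
        length_bounds=length_bounds,
    )
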