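"""End-to-end orchestration: FASTA collection in, CSA report out.

``run_pipeline`` composes all stages deterministically: frequency table
from the database, then per query protein the total-frequency profile,
inscribed-Gaussian height field, ELIS tree and entropy curves, and
finally the cohort correlation matrix, threshold masks and the stable
CSA report.  Every artifact carries the configuration hash in its
header; a rerun with identical inputs and configuration reproduces every
data artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import yaml

from . import cohort as cohort_mod
from . import entropy as entropy_mod
from . import freqdb, profile as profile_mod, scalespace

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameter home for a pipeline run."""

    delta: int = 1
    min_len: int = 50
    max_len: int = 400
    y_max: int | None = None  # None: floor(N/2) per protein
    thresholds: tuple[float, ...] = cohort_mod.DEFAULT_THRESHOLDS
    min_proteins: int = 10
    min_pair: int = 10
    seed: int = 0
    outdir: str = "anis_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.delta not in range(freqdb.MAX_DELTA + 1):
            raise ValueError(f"delta must be in 0..{freqdb.MAX_DELTA}")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if self.y_max is not None and self.y_max < 1:
            raise ValueError("y_max must be >= 1")
        if len(self.thresholds) < 2:
            raise ValueError("threshold schedule must have length >= 2")
        if any(not (0.0 < t < 1.0) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b >= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        if self.min_proteins < 1 or self.min_pair < 1:
            raise ValueError("min_proteins and min_pair must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (not output location/logging)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = tuple(float(t) for t in data["thresholds"])
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending record."""

    def __init__(self, stage: str, record_id: str | None, cause: Exception):
        self.stage = stage
        self.record_id = record_id
        at = f" (record {record_id!r})" if record_id else ""
        super().__init__(f"stage '{stage}'{at} failed: {cause}")


def run_pipeline(
    config: RunConfig,
    fasta_db: str | Path,
    query_fastas: Sequence[str | Path] | None = None,
) -> Path:
    """Run every stage; return the output directory.

    With no ``query_fastas`` the database records themselves are the
    cohort.  Any stage error aborts with the stage name and record id.
    """
    config.validate()
    fasta_db = Path(fasta_db)
    if not fasta_db.exists():
        raise FileNotFoundError(f"database FASTA not found: {fasta_db}")
    for q in query_fastas or []:
        if not Path(q).exists():
            raise FileNotFoundError(f"query FASTA not found: {q}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": config.config_hash}
    _setup_run_log(outdir, config.log_level)
    with open(outdir / "config.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        fh.write(f"# config_hash={config.config_hash}\n")

    try:
        records = freqdb.scan_database(fasta_db, config.min_len, config.max_len)
        table = freqdb.count_pentapeptides(records)
        table.length_bounds = (config.min_len, config.max_len)
    except Exception as exc:
        raise PipelineError("build-db", None, exc) from exc
    freqdb.write_table(table, outdir / "table.tsv", extra_header=header)
    logger.info("frequency table: %d sequences, %d windows",
                table.n_sequences, table.n_fragments_total)

    if query_fastas:
        queries: list[freqdb.SequenceRecord] = []
        for q in query_fastas:
            queries.extend(freqdb.read_fasta(q))
    else:
        queries = records
    queries = [q for q in queries if q.length >= freqdb.K]

    proteins_dir = outdir / "proteins"
    proteins_dir.mkdir(exist_ok=True)
    cohort_curves: list[entropy_mod.EntropyCurves] = []
    for i, rec in enumerate(queries):
        try:
            prof = profile_mod.frequency_profile(rec, table, config.delta)
            y_top = rec.length // 2
            if config.y_max is not None:
                y_top = min(y_top, config.y_max)
            field = scalespace.height_field(prof, range(1, y_top + 1))
            tree = scalespace.build_elis_tree(field)
            curves = entropy_mod.entropy_curves(field, tree)
        except Exception as exc:
            raise PipelineError("per-protein analysis", rec.id, exc) from exc
        pdir = proteins_dir / rec.id
        pdir.mkdir(exist_ok=True)
        profile_mod.write_profile(prof, pdir / "profile.tsv", extra_header=header)
        scalespace.write_field(field, pdir / "height.tsv", extra_header=header)
        (pdir / "tree.json").write_text(tree.to_json(indent=1) + "\n")
        (pdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        entropy_mod.write_curves(curves, pdir / "curves.tsv", extra_header=header)
        cohort_curves.append(curves)
        if (i + 1) % 100 == 0:
            logger.info("analyzed %d / %d proteins", i + 1, len(queries))

    try:
        vectors = cohort_mod.build_level_vectors(cohort_curves, config.min_proteins)
        matrix = cohort_mod.correlation_matrix(vectors, config.min_pair)
        result = cohort_mod.stability_scan(matrix, config.thresholds)
    except Exception as exc:
        raise PipelineError("cohort", None, exc) from exc
    cdir = outdir / "cohort"
    cdir.mkdir(exist_ok=True)
    cohort_mod.write_matrix(matrix, cdir / "matrix.tsv", extra_header=header)
    for t in config.thresholds:
        mask = cohort_mod.threshold_mask(matrix, t)
        cohort_mod.write_mask(mask, matrix.levels, cdir / f"mask_{t:g}.tsv",
                              extra_header=header)
    cohort_mod.write_csa(result, cdir / "csa.tsv", extra_header=header)
    logger.info("CSA: %d blocks, stable=%s at threshold %g",
                len(result.blocks), result.stable, result.threshold)
    return outdir


def _setup_run_log(outdir: Path, level: str) -> None:
    """File log for the run; timestamp-free so reruns stay comparable."""
    root = logging.getLogger("anis")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(outdir / "run.log", mode="wt", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root.addHandler(handler)
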