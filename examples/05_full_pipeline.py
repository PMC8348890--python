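"""End-to-end run: synthetic FASTA database to CSA report.

Equivalent to `anis run-all db.fasta --out out/` on the command line.
All artifacts (frequency table, per-protein profiles, height fields,
trees, entropy curves, cohort matrix, masks, CSA report) are written
under the output directory and are byte-identical across reruns.
"""

import tempfile
from pathlib import Path

from anis import FixtureSpec, RunConfig, random_database, run_pipeline, write_fasta

workdir = Path(tempfile.mkdtemp())
records, _ = random_database(
    FixtureSpec(seed=7, n_sequences=40, length_range=(50, 150))
)
fasta = workdir / "db.fasta"
write_fasta(records, fasta)

config = RunConfig(min_len=50, max_len=150, outdir=str(workdir / "out"), seed=7)
outdir = run_pipeline(config, fasta)

print(f"artifacts under {outdir}:")
for path in sorted(outdir.glob("*")) + sorted((outdir / "cohort").glob("*")):
    if path.is_file():
        print(f"  {path.relative_to(outdir)}")
print()
print((outdir / "cohort" / "csa.tsv").read_text())
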