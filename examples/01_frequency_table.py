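"""Build a pentapeptide frequency table and query total frequencies.

A synthetic 60-protein database stands in for a non-redundant protein
collection.  The table counts every overlapping 5-residue window; the
total frequency Phi(A) pools counts over the Hamming ball of radius
delta around A, so that single-residue substitutions contribute.
"""

from anis import FixtureSpec, random_database, total_frequency

spec = FixtureSpec(
    seed=0,
    n_sequences=60,
    length_range=(50, 150),
    planted_motifs=[("WWWWW", 300)],  # inflate one motif far above background
)
records, table = random_database(spec)

print(f"database: {table.n_sequences} sequences, "
      f"{table.n_fragments_total} windows, "
      f"{len(table.counts)} distinct pentapeptides")

for delta in (0, 1, 2):
    phi = total_frequency(table, "WWWWW", delta)
    print(f"Phi(WWWWW, delta={delta}) = {phi}")

# Phi grows with delta because the Hamming ball widens (96 fragments at
# delta=1, 3706 at delta=2); the planted motif dominates its neighbours.
print(f"plain count of an unplanted window, phi(ACDEF) = {table.phi('ACDEF')}")
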