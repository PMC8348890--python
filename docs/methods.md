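# Methods

## Model

The package treats the pentapeptide — a contiguous window of five
residues — as the unit of protein sequence, on the grounds that
informational redundancy in natural sequences is strongest at that
fragment length.  All structure is derived from occurrence statistics of
pentapeptides in a large non-redundant collection; no alignment,
physicochemical scale or structural input enters anywhere.

A protein's *informational profile* is f(j) = Φ(I_j), the Hamming-ball
total frequency of the window centred at residue j (j = 3…N−2).  The
ball radius δ widens the evolutionary neighbourhood: δ = 0 counts the
literal window, δ = 1 (default) admits one substitution (ball size 96),
δ = 2 and 3 admit more (3 706 and 72 296).  Φ is computed by exact ball
enumeration against the count table; a per-table memo cache gives the
same values faster.

Smoothing f with a normalized Gaussian of half-width y gives F(x) on
the residue grid x = 1…N.  The sum runs only over existing windows —
there is deliberately no renormalization at the termini, so F decays
toward the sequence ends and terminal segments behave as loosely
attached elements.

The *inscribed height* H(x,y) = min_z F(z)·exp((z−x)²/2y²) is the
amplitude of the widest Gaussian of half-width y centred at x that fits
entirely under F, with F recomputed at each y with kernel width y (the
smoothing scale and the inscribed width are coupled — one y).  H lives
on the triangle x ∈ [1,N], y ∈ {1,…,⌊N/2⌋}.  Local maxima of H(·,y),
linked from the widest scale downward, form the hierarchy tree whose
branches are the ELIS segments.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| δ | Hamming-ball radius for Φ | 1 | configurable 0–3 |
| length bounds | database records kept | 50–400 aa | inclusive |
| y levels | scales evaluated | 1…⌊N/2⌋ (integers) | finer grids are cosmetic |
| thresholds | CSA display schedule | 0.9, 0.7, 0.5, 0.3, 0.1, 0.05, 0.02, 0.01, 0.001 | strictly decreasing in (0,1) |
| min_proteins / min_pair | cohort support minima | 10 / 10 | levels/pairs below are dropped |

The nine-value threshold schedule spans the conventional display range
(0.9 down to 0.001, with 0.01 among them); only the endpoints and the
usual stabilization point are canonical, the intermediate values are a
reasonable ladder and fully configurable.

## Numerical choices

- **Log-domain evaluation of H.**  The product F(z)·exp(+(z−x)²/2y²)
  overflows/underflows in linear arithmetic (the exponent reaches ~10⁴),
  while its value is moderate.  log F is computed by `logsumexp` over
  the window terms without truncation, and H = exp(min_z [log F(z) +
  (z−x)²/2y²]).  This preserves the analytic identity H(j0,y) =
  c/(y√2π) for a single impulse to ~1e−12, which a truncated linear sum
  destroys.  The exported linear-domain F uses an 8y kernel cutoff
  (dropped mass < 1e−14) and agrees with the exact sum to 1e−12.
- **Minimization grid.**  z ranges over the residue grid [1,N]; F is
  not meaningfully supported beyond it and the exponential weight makes
  far z irrelevant.
- **Maxima and plateaus.**  A strict local maximum is required; an
  equal-valued plateau flanked by strictly smaller values counts once,
  at its midpoint (rounded down).  Domain endpoints may be maxima of a
  height-field row (strictly above their single neighbour), but the
  entropy-derivative branch signal uses interior maxima only, so a
  monotone derivative yields no branch points.
- **Level linking.**  Each maximum at level y is assigned to the alive
  branch whose position at y+1 is nearest (ties to the left).  A branch
  receiving two or more maxima splits; the branch point is recorded as
  (x0, y0) with y0 the first level at which the children appear
  separately and x0 the parent's position at its last level.
- **ELIS footprints.**  A branch's interval is its basin at its last
  level (midpoints between adjacent maxima; 1 and N at the flanks),
  confined to a cell of its parent's interval obtained by partitioning
  at midpoints of the sibling birth positions.  Cells make sibling
  footprints provably disjoint even when maxima drift between levels.
  In the rare case where drift leaves a branch with a footprint too
  small to hold disjoint children (fewer positions than children), the
  split is discarded as a tracking artifact and the branch runs through
  to the bottom level.  Footprints are scale-independent, matching how
  ELIS boundaries are reported as single residue ranges.
- **Entropy.**  Integrals over x are discrete sums at unit bin width;
  entropies are in nats.  Row normalization absorbs the rounding
  residual into the largest element (exact unit mass under compensated
  summation).  n in S̃ = S − log n is the number of ELIS branches alive
  at that level — the only protein-dependent count that produces the
  leap at branching; this is an interpretation, recorded here, not a
  forced consequence of the formulas.  S′ is the forward difference;
  a central difference moves detected maxima by at most one level on
  the fixtures.
- **Correlation.**  The printed form of the vector correlation has an
  inconsistent denominator; the implementation uses the cosine
  normalization ⟨V_y,V_y′⟩/√(⟨V_y,V_y⟩⟨V_y′,V_y′⟩), the unique reading
  with unit diagonal and entries bounded by 1.  Entries are clipped to
  [−1,1] (last-ulp guard) and the diagonal is set exactly to 1 for
  non-degenerate vectors (an algebraic identity, not an approximation).
  Variable-length proteins contribute pairwise-complete intersections;
  pairs sharing fewer than `min_pair` proteins stay undefined.
- **CSA.**  "Exceeds the threshold" is strict.  The greedy left-to-right
  diagonal partition is the unique partition into maximal all-ones
  squares because an all-ones square contains all its leading
  sub-squares.  The stability scan returns the first partition repeated
  at two consecutive thresholds.

## Synthetic data

The fixtures module generates the study conditions without a real
collection:

- *random databases* — i.i.d. residues over the 20-letter alphabet
  (optionally weighted), lengths uniform in a range, with optional
  planted motifs overwritten at random positions to inflate chosen
  pentapeptide counts;
- *planted profiles* — impulse/two-impulse/multi-scale frequency
  profiles whose tree structure is known; the multi-scale layout is
  found by a small deterministic search around twice the band midpoint
  (two equal Gaussians merge at about half their separation) and is
  certified at generation time by running the package's own tracker;
- *planted cohorts* — entropy-derivative curves with one amplitude per
  band per protein, Gram–Schmidt-orthogonalized across bands so the
  zero-noise correlation matrix is exactly block structured, plus
  i.i.d. Gaussian noise (default σ = 0.1 against unit-variance
  amplitudes).

All generators run from a single seeded `numpy.random.default_rng`
stream and are byte-reproducible.

What passing tests on these fixtures shows: the machinery — counting,
smoothing, inscription, tracking, entropy, correlation, CSA — is
mathematically correct and deterministic.  What it does not show:
anything about real proteins.  Random sequences lack compositional
bias, repeats, homology and the informational redundancy of natural
sequences; planted cohorts impose the band structure that a real cohort
would have to reveal.  Conclusions about natural characteristic scales
require a real non-redundant collection (tens of thousands of
sequences), which the pipeline accepts as ordinary FASTA.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
random profiles of 20–120 residues, cohorts of 200 curves over 25
levels, end-to-end runs of 100 proteins of 50–150 residues (a few
seconds on one core; cost is dominated by the O(N²) per-level height
field, O(N³/2) per protein).  Full-collection runs scale linearly in
the number of proteins.

## Known limitations

- The ELIS linking rule (nearest maximum, leftward ties) and the
  plateau conventions are choices; the mathematics of the height field
  does not dictate a unique linking.
- Branches are not extrapolated beyond the triangular domain, so
  N- and C-terminal elements near the apex are reported only within it.
- No significance testing or smoothing is applied to S′ peaks; single
  proteins can show minor spurious maxima (cohort correlation averages
  these out).
- Non-canonical residues (X, B, Z, U, J, O, `*`, gaps) are handled by
  skipping the windows that contain them, which locally depresses the
  profile; heavily degenerate sequences should be cleaned upstream.
- Redundancy reduction of the input collection is the user's job; the
  package checks only for duplicate identifiers.
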