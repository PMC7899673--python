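# Methods

## Scope and model

The package automates the desk half of developing a degenerate barcoding
primer pair: IUPAC sequence algebra, consensus design from a multiple
sequence alignment, reference-set dereplication, and in-silico PCR. It does
not compute alignments (use mafft and feed the result in), does not model
thermodynamics beyond two textbook Tm estimates, and makes no claim about
wet-lab success rates — amplification here means "a binding-site pair passes
the mismatch policy", nothing more.

## IUPAC algebra

Each ambiguity code is handled as the set of plain bases it denotes.
Matching is set intersection: template code *t* matches primer code *p* iff
*B(t)* ∩ *B(p)* ≠ ∅. This is deliberately permissive for degenerate
*template* positions — a template N matches everything — which is acceptable
for dereplicated reference sets where Ns are rare; no attempt is made to
score partial overlap.

Conventions fixed here and used everywhere:

* **Degeneracy** — `degeneracy()` is the mathematical product ∏|B\_i| (1 for
  a plain sequence). `reported_degeneracy()` applies the primer-table
  convention of printing 0 for a primer with no ambiguous position; the
  `props` report uses it.
* **GC%** — 100 × (count of G, C or S positions)/length, rounded half-up to
  one decimal. Only fixed-GC codes count; R/Y/K/M/… contribute zero. This is
  the convention under which the packaged primer table's values (25.0, 29.2,
  32.0, 34.6, 32.0, 34.6) are reproduced exactly; fractional weighting of
  partially-GC codes does not reproduce them and is not offered.
* **Tm** — Wallace rule 2(A+T)+4(G+C) and the GC formula
  64.9 + 41(GC − 16.4)/L, each averaging ambiguous positions over their base
  set. Published tables for these primers print 51/51/47 °C without naming a
  method; neither formula reproduces those values, so Tm is reported but
  never asserted. Nearest-neighbour/salt-corrected Tm is out of scope.
* Coordinates in all reports are 1-based inclusive. Gaps are legal only in
  alignment context, never inside a primer.

## Consensus design

`column_consensus` returns the code for the union of observed bases
(degenerate entries contribute their full set, gaps are ignored). A
`min_base_frequency` floor (default 0.0) lets noisy alignments drop rare
bases; if the floor excludes everything the most frequent base(s) are kept,
which makes consensus degeneracy monotonically non-increasing in the floor.
With the default floor the consensus matches every gap-free row with zero
mismatches by construction — that is the coverage guarantee the tests assert.

`scan_windows` enumerates every window of every permitted length (default
20–26 nt) whose columns are gap-eligible (default: any gap disqualifies a
column, since a primer site must be structurally conserved) and whose
consensus degeneracy is ≤ `max_degeneracy` (default 32). Candidates are
sorted by degeneracy ascending, coverage descending, then leftmost start and
shortest length for determinism; each window yields a forward candidate and
a reverse candidate carrying the reverse-complemented consensus. An empty
scan returns a diagnostic tally of which constraint rejected most windows.

`pair_primers` forms all non-overlapping forward/reverse pairs whose implied
product length (reverse-window end − forward-window start + 1, in alignment
columns) lies in the amplicon range (default 400–1000), ranked by combined
degeneracy then combined coverage. Alignment columns are used as the product
length proxy; on gappy alignments this overestimates the physical product.

**Recovery is defined on the top-ranked pair, not on single candidates.** In
a symmetric scan the reverse orientation of the *forward* region sorts above
the true reverse site (it ties on degeneracy and coverage and starts
earlier), and a 20-mer sub-window of a conserved 24-mer outranks the 24-mer
under the shortest-length tie-break. Pairing under the amplicon constraint
is what disambiguates both, exactly as in real design, so recovery tests
design at the planted window length (24 nt, the length of the published
primers) and compare the top pair against the planted truth.

## In-silico PCR

`find_binding_sites` slides the primer (reverse primers as their reverse
complement) across every offset of a gap-free template; aligned input is
de-gapped first with a column↦residue map (`seqio.degap`), and positions are
reported in the ungapped frame. A site is kept iff total mismatches ≤
`max_total_mismatches` (default 3) **and** mismatches within the
`three_prime_window` terminal bases of the primer's own 3′ end (default 5)
are ≤ `max_three_prime_mismatches` (default 0). For a minus-strand site the
3′ window is the template-leftmost end of the match — the end facing into
the amplicon. The defaults operationalise the qualitative rule that a few 5′
mismatches do not kill a PCR while 3′ mismatches do; the published workflow
mapped primers manually and stated no numeric threshold, so these are this
package's declared defaults, not a reconstruction.

All compatible site pairs are enumerated (no "best site" heuristic);
`success_matrix` counts a record as amplified when at least one predicted
amplicon exists, and tabulates per-group and overall fractions, with the
weighted group average equal to the overall rate by construction.

Properties the test suite enforces: zero-mismatch site sets equal the union
of exact scans over the primer's expansion pool; sites are mirror-symmetric
under reverse-complementing the template (with orientation flipped); and
relaxing any policy parameter never removes a site.

## Dereplication

`dereplicate` implements the greedy longest-first scheme (descending length,
ties by id; first-fit against existing centroids) at a default identity
threshold of 0.9 — the strategy cd-hit documents, without its k-mer
prefilter or word-size heuristics, which are speed optimisations this
correctness-first implementation omits at desk scale. Identity comes from an
in-package Needleman–Wunsch alignment (match +1, mismatch −1, gap −2,
linear; deterministic traceback preferring diagonal, then up, then left) as
exact matches over aligned columns. cd-hit divides by the shorter sequence
instead; `denominator="shorter"` switches to that convention, and the
alignment-column default is the documented divergence. The alignment score
is cross-checked against Bio.Align.PairwiseAligner and, on short strings,
against exhaustive alignment enumeration in the tests; the O(nm) Python DP
is adequate for reference sets of hundreds of barcode-length sequences.

## Synthetic design cases

`generate_design_case` emulates the design situation: one random ancestor,
copied `n_sequences` times (default 9, ~900 columns, the size of a typical
partial-mitogenome panel); two planted windows (defaults 21–44 and 857–880,
matching a forward site in the 20–50 bp region and a reverse site in the
860–880 bp region of a COI reference) kept invariant except for an explicit
per-column polymorphism spec; and every site outside the windows mutated
independently with `core_substitution_prob` (default 0.12, on the order of
within-genus COI divergence). Substitutions are uniform over the three
alternative bases. A single NumPy generator seeded once drives all draws,
so a case is bit-reproducible; passing an explicit `ancestor` regenerates an
independent panel from the same ancestor for validation.

Two deliberate design choices:

* **Maximal-run guarantee.** With 9 sequences at 12 % substitution a column
  flanking a planted window stays invariant by chance with probability
  ≈ 0.88⁹ ≈ 0.32, in which case the conserved run extends past the window
  and "the planted site" is no longer a well-defined ground truth (a shifted
  window is exactly as conserved). The generator therefore forces each
  column immediately adjacent to a planted window to show at least two
  bases (skipped when `core_substitution_prob` is 0, where the panel is
  intentionally invariant). This is an identifiability constraint on the
  truth, not a change to design or scoring.
* **No indels, no phylogeny.** Sequences are i.i.d. mutations of one
  ancestor; real panels are tree-structured and gapped. Passing recovery
  tests therefore demonstrates the design/validation machinery, not
  robustness to alignment error or rate variation across lineages — those
  must be judged on real alignments.

## Problem sizes and determinism

The test suite runs design recovery across 20 seeds of the 9 × 900 case,
matching-semantics equivalence on 1,000 random degenerate primers, and
clustering on panels of 2–4 ancestors of 150 nt with ~2 % within-group
divergence (chosen so within/between identities clearly straddle 0.9);
hypothesis profiles are derandomised. Everything, including the CLI's
provenance records (parameters, seed, input digests written next to each
output), is deterministic given the seed.

## Known limitations

No hairpin/dimer or multiplex screening; no thermodynamic binding model; no
touchdown-cycle simulation; FASTA only (no FASTQ/GenBank); amplicon length
in alignment columns when the input is an alignment; the permissive
template-N semantics noted above.
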