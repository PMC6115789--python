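# Methods

This note records the model implemented by `mirtarp`, the parameter choices
that matter, and what the synthetic tests do and do not demonstrate.

## Problem setting

A mature miRNA (~22 nt) can repress a transcript it can pair with; between
a host and an infecting virus neither conservation nor species-specific
context features are available, so prediction rests on (i) a run of
consecutive complementary bases anchoring the interaction and (ii) the
thermodynamic stability of the resulting RNA–RNA hybrid. `mirtarp`
implements exactly that two-stage screen, plus a local-folding
accessibility annotation, for both directions (host miRNA → viral target,
viral miRNA → host transcript); the direction is a bookkeeping tag
(`origin`) and never changes the algorithm.

## Sequence handling

All input is normalized to uppercase RNA (T→U) on read; records with
characters outside `ACGTUN` are dropped with a warning rather than masked.
`N` never pairs: it cannot sit inside a seed and is assigned no pair type
in the energy model, so unknown bases can only dilute, never fabricate, a
prediction. Coordinates are 0-based half-open on the forward strand of
each FASTA record everywhere internally and in the TSV; the GFF3 writer
converts to 1-based inclusive. Multi-segment genomes are keyed strictly
per FASTA record.

## Stage 1 — seed scan

A seed is a *maximal* run of ≥ `b` consecutive Watson–Crick pairs (G:U
wobble excluded from the seed, because a consecutive-identity match
against the reverse complement cannot represent wobble; wobble is allowed
in the duplex stage). The scan builds a hash index of all length-`b`
target words, looks up each window of the reverse-complemented miRNA, and
extends hits to maximality, deduplicating by (diagonal, extent). This is
exhaustive by construction — the test suite asserts set equality with a
naive per-diagonal scan on hundreds of random instances — and replaces the
heuristic similarity search a production screen might use with something
deterministic and provable. The seed may sit anywhere on the miRNA; no
canonical 5′ positions 2–8 constraint is imposed. `b ≥ 4` is enforced
(shorter seeds are biophysically meaningless and blow up the index).
Default `b = 7`.

## Stage 2 — duplex assessment

Each seed is widened by `site_flank` (default 15 nt per side — room for a
full ~22-nt miRNA plus bulges around any seed); overlapping windows of the
same (miRNA, target, strand) are merged so one merged window yields at
most one reported site. Merges are capped at the engine's 200-nt window
limit; a merge that would exceed the cap starts a fresh window instead.

The hybrid MFE is computed by dynamic programming over pairs (i on the
miRNA, j on the window) under the standard hybridization restriction: all
pairs intermolecular, antiparallel and non-crossing; loop types limited to
stacks, bulges and internal loops with l₁+l₂ ≤ 30; no multibranch loops,
no intramolecular structure. The energy of a structure is

ΔG = ΔG_init(duplex) + Σ stack(p₁,p₂) + Σ bulge/internal penalties
     + terminal penalties,

with a +0.50 kcal/mol penalty for every helix end closed by AU/UA/GU/UG
(applied at the two duplex ends and at the closing pairs of every loop
except stacks and 1-nt bulges; a 1-nt bulge retains the stack across it).
A pairless window returns **+∞**, not 0, so an empty structure can never
pass a cutoff. The cutoff comparison is inclusive: `mfe ≤ e` passes
(default `e = −25 kcal/mol`).

## Stage 3 — accessibility

For each passing site the surrounding window (`fold_flank` = 70 nt per
side by default, a common accessibility-window size; clipped so the window
never exceeds 300 nt) is folded by a Zuker-style MFE recursion over
hairpins (≥ 3 unpaired), stacks, bulges, internal loops (l₁+l₂ ≤ 30) and
multibranch loops scored linearly (offset 9.30, −0.90 per enclosed branch,
0.00 per unpaired base; the closing pair is covered by the offset). The
empty structure scores 0, so the fold MFE is ≤ 0 by construction. The TSV
reports the fold MFE and the fraction of site positions unpaired in the
MFE structure; these are *supplementary evidence* and never filter sites.
Among co-optimal structures the traceback deterministically prefers
two-loop continuations (stacks first, then larger loops), then hairpin
closure, then the multibranch split with the smallest split point, so the
unpaired fraction is reproducible.

## Energy parameters

`mirtarp/data/turner2004_min_v1.tsv` ships Turner-lab 2004-style ΔG°₃₇
increments rounded to 0.1 kcal/mol: the full 6×6 stack table over
{AU, UA, CG, GC, GU, UG} (strand-symmetric), hairpin/bulge/internal
initiations for sizes up to 30 with logarithmic extrapolation beyond
(ΔG(n) = ΔG(30) + 1.08·ln(n/30)), the internal-loop asymmetry term
(0.60 kcal/mol per nt, capped at 3.00), intermolecular initiation 4.10,
and the terminal weak-pair penalty 0.50. Simplifications relative to a
full modern parameterization, chosen so one unambiguous model serves the
DP engines, the re-scoring functions and the brute-force test oracles
identically: no sequence-dependent terminal mismatches, no dangling ends,
no coaxial stacking, no special 1×1/2×1/2×2 internal-loop tables (the
generic size-based initiation is used), no special hairpin bonuses.
Absolute energies therefore differ modestly from full-featured folding
engines, but orderings and helix energetics are realistic, and the default
−25 kcal/mol cutoff retains its intended meaning (a perfect ~22-bp site
scores far below it; short or weak complementarity does not reach it).

All energies are held internally as integers in 0.01 kcal/mol units; the
DP matrices, tracebacks and re-scoring functions use exact integer
arithmetic, which is why oracle-equivalence tests can demand exact
agreement and determinism tests can demand byte-identical output.

## Synthetic data

The fixture generator emulates the shape of real inputs — short
mature-miRNA records (20–24 nt, by default resampled to GC ≥ 0.4, the
regime where a full-length perfect duplex is confidently below the default
cutoff) and long i.i.d.-background targets at a requested GC — with
reverse-complement sites planted at known non-overlapping coordinates
(`perfect`, `mismatched` with 1–3 substitutions, or `bulged` with a 1–2 nt
target-side insertion) and a machine-readable truth table. The same seed
reproduces byte-identical output. A dinucleotide-preserving shuffle
(Altschul–Erikson Eulerian-walk) is provided as the negative control.

What passing these tests shows: the scan is complete, the thermodynamic
optimization is exact for its model, planted signals are recovered and
thresholds behave monotonically. What it does not show: performance on
real viral genomes, whose composition is not i.i.d. (codon structure,
skewed dinucleotides, repeats), nor biological validity of any particular
cutoff — `b` and `e` trade sensitivity against specificity and should be
tuned per application.

## Problem sizes and numerical choices

Oracle-equivalence checks run at combined lengths ≤ 18 nt (where
exhaustive enumeration of all non-crossing structures is tractable) plus
fixed small batteries; recovery and nesting checks use 50 single-site
fixtures of 300 nt and multi-miRNA fixtures of 500–600 nt; the throughput
check screens 30 miRNAs against 100 kb. These sizes were chosen to
exercise every code path at desk scale; the engines themselves are
routinely used on full viral genomes (the per-window DP cost is
independent of genome length, and indexing is linear). Degenerate inputs
are defined, not special-cased: empty seed sets yield empty results, the
pairless duplex is +∞, the empty fold is 0, and zero-hit batch runs exit
successfully with a header-only TSV.

## Known limitations

* No partition-function quantities (ensemble binding probabilities,
  opening energies); accessibility is a single-structure proxy.
* The duplex and accessibility energies are reported separately; no
  combined "net opening" score is computed.
* The seed stage's strict WC alphabet means sites held together purely by
  wobble-rich helices are found only if they also contain a ≥ b WC run.
* Temperature is fixed at 37 °C; no enthalpy tables are shipped.
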