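# Methods

This note documents the models implemented in `regsig`, the parameters that
matter, the numerical choices, what the synthetic data does and does not
emulate, and the known limitations.

## Profiles and scoring

A site alignment is gapless and rectangular (n sequences x L columns) over
{A, C, G, T, N}. The probability matrix adds a per-base pseudocount a to
the column counts, p(b,j) = (n_bj + a)/(n + 4a), with `N` contributing 1/4
of a count to each base. The default a = 0.5 is a Laplace-style smoothing
that keeps log-odds finite for any column observed at least once; a = 0 is
allowed and produces -inf log-odds for unobserved bases, in which case
windows crossing them are simply never emitted as hits.

Scores are log2-odds against the background q (default uniform), i.e. bits,
matching the bit-score convention of profile-HMM searches that the
trusted/noise/gathering cutoffs come from. Masked columns score exactly 0
and report 0 bits of information content, so masking k columns caps the
total IC at 2(L-k). Information content uses the uniform-background
definition IC_j = 2 + sum p log2 p; an optional small-sample correction
(subtracting 3/(2 ln2 n) per column) is available but off by default, since
logo conventions differ between sources and the uncorrected form is the one
the logo heights p(b,j)·IC_j are defined against.

Coordinates are 0-based half-open everywhere in memory; strand "+" is the
GenBank top strand. The 1-based inclusive convention exists only in GenBank
files.

## Exact p-values

P(S >= t) for a background-random L-mer is computed by discretizing each
column's four log-odds values to integer multiples of a granularity g
(default 0.001 bits) and convolving the column distributions. Every word's
discretized score differs from its exact score by at most L·g/2, so the DP
answer is bracketed by exact enumeration at t ± L·g; the test suite asserts
exactly this bracket against an independent enumeration over all 4^L words.
At motif scale (L <= 35) the grid spans a few hundred thousand cells and
the computation is effectively instant. Zero-probability bases (possible at
pseudocount 0) carry their background mass in a separate "-inf" bucket that
can never satisfy a finite threshold; a threshold of -inf returns p = 1.

## Scanning and calibration

Both strands are always scanned (minus strand via the reverse complement,
coordinates reflected to the top strand; start < end always) and
orientation questions are deferred to post-processing. Ties at the cutoff
are kept (>=). Circular replicons are scanned without wrapping the origin —
a simplification that loses at most L-1 windows. Scan modes: a bit-score
cutoff (defaulting to the profile's gathering cutoff) or a p-value cutoff,
which is converted to the smallest grid score whose survival probability is
below the cutoff.

Calibration follows the cutoff convention: trusted = min(training scores),
noise = max(decoy scores), gathering = (trusted + noise)/2. Without decoys
the noise cutoff falls back to trusted - 0.5·|trusted| and is flagged
provisional. noise >= trusted warns but is stored: non-canonical orderings
occur with weak profiles and must be representable.

## Context filtering

Hits are classified against the gene/CDS annotation (gene and CDS features
are both consulted; duplicate intervals collapse):

- **intragenic** — overlaps any gene;
- **converging-region** — strictly between the 3' ends of two adjacent
  convergently transcribed genes, a region that cannot be upstream of
  anything;
- **upstream-ok** — the nearest same-strand gene start downstream of the
  hit's 3' edge lies within [min_upstream, max_upstream];
- **wrong-orientation** — everything else.

Precedence is intragenic > converging-region > upstream-ok. The window
default of 0–300 nt reflects typical bacterial promoter/operator spacing
and is stored per profile, so promoter and TFBS profiles can carry
different windows. Palindromic profiles are double-reported by
strand-symmetric scanning; deduplication links opposite-strand hits with
reciprocal overlap >= 0.5 (engine-reported intervals can be offset by a
base, so exact coordinate equality is too strict) and keeps the best hit
per linked component, plus strand on exact ties. Downstream, regulon logic
treats TFBS sites as orientation-free.

## Intrinsic terminators

Candidates are stem-loop decompositions (stem 4–20 bp, loop 3–10 nt by
default) with at most one non-pairing stem position. Pair scores are
G:C +3, A:T +2, G·U +1 (DNA G-T, on by default), mismatch -3; the hairpin
score subtracts 0.5 per loop nt. The U-tail score sums positionally
decaying weights (1.0, 0.9, ..., floored at 0.1) over tail positions that
are T, maximal 5.2 at the default 8-nt tail; truncated tails at a contig
end are scored over the available bases. Confidence maps the two onto
0–100:

    confidence = 100 · logistic(0.35 · (hairpin + 3·tail − 18))

These constants are this package's own surrogate for the undisclosed
internals of the classical terminator finders, chosen so that a canonical
terminator (>= 6 bp clean stem + U-tail) comfortably exceeds the default
confidence cutoff of 70 while hairpin-free sequence never reaches it.
Overlapping decompositions of the same hairpin are resolved by greedy
non-maximum suppression on loop overlap (best score wins; ties prefer fewer
mismatches, then longer stems, then the leftmost start) — a local rule
chosen over transitive loop-overlap grouping, which chains across unrelated
candidates in hairpin-dense sequence.

Random DNA does contain genuine hairpins near the default cutoff, at about
1–2 calls per kb per strand. For genome-wide scans whose terminator calls
delimit transcription units, `high_specificity_params()` (confidence >= 99
plus a required tail score >= 4.0) reduces the false-call rate to a few per
megabase per strand at no cost to canonical terminators, and is what the
genome-scan pipeline and the end-to-end tests use. Candidates are not
suppressed near genes: placement relevance is the regulon module's
decision.

## Transcription-unit inference

Every annotated TFBS (`protein_bind`) or promoter feature is a potential
unit start. The first gene on the unit strand whose start lies within
[site_to_start_min, site_to_start_max] (default 0–300 nt) of the site
anchors the unit; extension over successive co-oriented genes stops at (in
order of precedence) a same-strand terminator between genes, a non-coding
gap >= max_gap (default 200 nt) or an intervening opposite-strand gene, or
the replicon end. An opposite-strand gene ends extension because
read-through across an antisense gene is not inferable from annotation
alone. The non-coding gap is measured gene-end to gene-start on the top
strand, ignoring regulatory features in the gap.

TFBS features try both directions (a bound regulator between divergent
operons can control both); promoters use their annotated strand. When both
directions yield units and divergon listing is enabled, the two arms merge
into one unit flagged `divergon`, counted once. Counts aggregate by
regulator name (the `bound_moiety` qualifier, or the promoter note prefix).

## Profile optimisation

The loop mirrors cross-species regulog projection: scan target genomes with
the current profile, retain hits scoring >= the retention cutoff (a fixed
bit score or the profile's noise cutoff) that pass the context filter,
always re-include hits overlapping the seed alignment's own genomic
intervals ("orthologous sites are always retained"), rebuild the matrix,
then probe `extension_probe` (default 5) columns on each side. Probe
columns are kept while their pseudocount-free IC stays >= `column_keep_ic`
(default 0.3 bits — an order of magnitude above the sampling noise of a
few dozen random sequences, far below any conserved column); weak original
edge columns are trimmed by the same criterion. Convergence is reached when
the (site set, width) pair repeats. Curator judgement about which
additional sites are biologically plausible is operationalised as an
explicit `target_regions` allowlist. The final profile is calibrated with
trusted = weakest retained-site score and noise = best-scoring rejected
hit; the result object carries the final alignment and a per-round history
because the alignment itself (provenance, width) is part of the outcome.

## Synthetic data

The generator emulates the *layout* of a bacterial replicon, not its
sequence statistics: i.i.d. background at a configurable GC content,
operons of 2–4 genes (300–900 nt, intra-operon gaps 20–120 nt, below the
regulon max_gap) laid out alternately on the two strands with inter-operon
gaps of 450–650 nt (above max_gap, and wide enough that a site planted
20–100 nt upstream of one operon can never fall inside the 300-nt window
of the divergently transcribed neighbour — divergon layouts are tested
separately with hand-built annotations). One motif instance is planted
upstream of each selected operon; with a consensus-string motif the
instances are exact copies, so every planted site scores at the profile
maximum and recovery failures indicate pipeline defects rather than
sampling noise. A `Profile` motif samples instances column-wise instead.
Half the operons (by default) end in a canonical terminator cassette:
CC guard + 8-bp mixed-base stem + 4-nt loop + complement + 8 T. The guard
blocks accidental stem extension into flanking sequence (two outward
mismatches exceed the mismatch budget) and the fixed stem has no
equal-scoring shifted pairing register, so detection is exact at the
planted coordinates. Decoy motif copies are planted inside genes and
between converging operon pairs, exercising the two context filters.
Everything is deterministic per seed, down to byte-identical GenBank
output (the written date field is fixed).

What passing these tests shows: the pipeline's logic — scoring, p-values,
filtering, terminator geometry, unit extension — is correct on data whose
ground truth is known exactly. What it does not show: performance on real
genomes, where sites diverge from consensus, backgrounds are not i.i.d.,
operon spacing is irregular, and terminators are thermodynamic rather than
pattern-based objects.

## Problem sizes

The default test and acceptance workloads are sized for a single CPU: 50-kb
genomes with 10 operons for the end-to-end checks, four ~15-kb genomes with
12 sites each for optimisation, 10-kb sequences for terminator plantings,
and p-value enumeration up to 4^8 words. All scale linearly (scanning,
detection) or exponentially only in the enumeration oracle, which is a test
device, not part of the method.

## Known limitations

- Ungapped scoring only: no insert/delete states, so sites with variable
  spacers need masking rather than alignment gaps.
- Origin-spanning sites and terminators on circular replicons are not
  detected.
- Terminator scoring is pattern-based, not nearest-neighbour
  thermodynamics; rho-dependent terminators are out of scope.
- `join()` gene locations are treated as their enclosing span (preserved
  verbatim for round-trip); multi-exon-like structures are rare in the
  bacterial genomes this targets.
- Coverage tracks are parsed and exposed, not plotted.
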