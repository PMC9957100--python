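# Methods

## The motif model

`garfinder` treats a GAR motif as a maximal chain of anchor units under a
bounded-wildcard pattern grammar.  An **anchor** is an arginine immediately
followed by ≥ 1 glycine; its class is `RG` when exactly one motif-internal
glycine follows and `RGG` when two or more do.  The full pattern for a pair
of chained units is

```
G(0,3)-X(0,1)-R-G(1,2)-G(0,3)-X(0,5)-G(0,3)-X(0,1)-R-G(1,2)
```

with `X` any residue (glycine included) and `(lo,hi)` the slot's repeat
bounds.  Operationally the engine decomposes this into three rules:

1. **Gap rule.** The residue segment strictly between two consecutive anchor
   arginines must full-match `G(1,2)·G(0,3)·X(0,5)·G(0,3)·X(0,1)` for *some*
   slot assignment.  Implied bounds: at most 14 residues between chained
   arginines, at most 6 of them non-glycine.  Because the trailing `X` slot
   may itself hold a glycine, the literal grammar admits a 14-glycine
   straight tract even though 13 is the longest one needed by any reference
   motif; the grammar is implemented literally.
2. **Leading context.** A motif is prefixed by the longest suffix of the
   residues immediately preceding its first arginine that matches
   `G(0,3)-X(0,1)` (≤ 4 residues, all glycine except possibly the one
   adjacent to the arginine), without overlapping a previously emitted
   motif.  Whether the original interactive program allowed leading context
   to absorb a previous motif's trailing glycines is not documented
   anywhere we know of; the non-overlap rule is this package's choice.
3. **Trailing cap.** A motif ends with its last arginine plus
   `min(2, glycine-run)` glycines, matching the terminal `G(1,2)`.  The cap
   cannot demote a unit: a truncated run of ≥ 2 still classifies as `RGG`.

A chain must contain ≥ 2 anchors (`RGRG` is the minimal motif).  Arginines
not followed by glycine are never units; they are plain residues that
wildcard slots may absorb, and they count toward R% but never toward the
RG/RGG tallies or the "else" residues.  This is forced by the reference
values: the fourth FUS motif starts `RRGG...` and its published row counts
the leading bare R in R% while listing only Y, D, F as "else".

Two published variants of the pattern exist (one prints `G(0,2)` where the
other prints `G(0,3)` for the second glycine slot); only the `G(0,3)` form
accommodates the 13-glycine tract and the 14-residue inter-anchor maximum
that the reference motifs require, so that form is implemented.

**Assembly** is greedy and leftmost-maximal: seed at the leftmost anchor not
covered by an emitted motif, extend anchor-by-anchor while the gap rule
holds, keep chains of ≥ 2 anchors, emit, and resume scanning after the
motif's end.  This makes motifs per record pairwise disjoint, sorted, and
deterministic, and it reproduces every reference motif span, including the
split of the zebrafish fibrillarin domain into residues 7–38 and 50–79
around its 16-residue spacer (which exceeds the 14-residue gap bound).

## Statistics and rounding

Per-motif values: RG/RGG unit counts; "else" counts (non-G/R residues,
first-occurrence order); `Total%` = motif length / protein length × 100;
`G/R` = glycine/arginine count ratio; `G%`, `R%`, `Non-GR%` of motif length.
All one-decimal values use `round1`: nearest multiple of 0.1 with exact ties
rounded away from zero, computed on exact fractions (no binary-float
artifacts).  The reference tables do not state their rounding mode; nine of
their ~600 numeric cells are inconsistent with *any* single nearest-0.1
rounding (eight show the signature of rounding twice — first to two
decimals, then to one — and one is an arithmetic typo; where the same motif
string is printed in two tables, the two printed values disagree with each
other).  The fixtures module stores the printed values verbatim and carries
an explicit, commented corrections map
(`garfinder.fixtures.PRINTED_VALUE_CORRECTIONS`) giving the arithmetically
consistent value for exactly those nine cells; the golden test suite
requires exact agreement with the printed value, or with the correction for
those nine documented cells.

## Census and classification

The long-motif census keeps motifs with RG+RGG ≥ `min_units`.  The default
threshold is 10 with a ≥ comparison: the reference census derives from
"repeat numbers higher than 10" in one place and "at least 10" in another,
and its smallest entries have 11 units, so the two readings are not
distinguishable from the data; the threshold is exposed as a flag.  Richness
is a per-motif label (more RG than RGG units, the converse, or balanced).
The tri/di repeat classification follows the classic literature definitions
(`RGG(X0–4)RGG(X0–4)RGG` etc.), tested in priority order tri-RGG, di-RGG,
tri-RG, di-RG — necessary because every tri match contains a di match.  An
element is an arginine plus its whole glycine run (≥ 2 G for RGG elements,
exactly 1 for RG), elements never overlap, and consecutive elements may be
separated by 0–4 arbitrary residues; whether the original classification
permitted overlapping elements is not recoverable, so non-overlap is this
package's documented choice.  Isoform collapsing in proteome scans was done
by manual inspection in the reference census and is out of scope; a helper
groups census rows with identical motif sequences as a rough proxy.

## Packaged reference data and synthetic generators

`src/garfinder/data/golden_motifs.csv` holds 86 published motif strings with
their expected statistics in three sets: `T2` (22 motifs — fibrillarin,
nucleolin, GAR1 across zebrafish, clawed frog, green anole, mouse, human),
`T3` (43 motifs — 16 classic human RG/RGG-repeat proteins), `T4` (21 long
motifs from a human proteome census).  Positions and `Total%` in these rows
refer to the full-length proteins and are kept for reference only; the
golden tests exclude them because only the motif strings ship.  Fixture
FASTA is generated on demand from this CSV (`garfinder fixtures`) rather
than shipped redundantly.

`make_synthetic_record` concatenates tagged parts into records with known
expected motif coordinates.  `random_gar_motif` samples grammar-valid
motifs: unit classes are Bernoulli(`p_rgg`), and inter-unit spacers are
drawn uniformly within the grammar's slot bounds under one of three gap
models (`minimal`, `mixed`, `polyg`); wildcard residues are drawn from an
alphabet without G or R so the generator can neither create nor destroy an
anchor, guaranteeing the engine finds exactly one motif with the requested
unit count.  Default seed 20230330.  These generators emulate motif
*grammar* structure only — not real amino-acid background composition,
homology, or the residue biases of real GAR domains — so generator-based
tests demonstrate grammar/engine consistency, not recall on real proteomes.

## Verification strategy and problem sizes

The engine is checked against an independent brute-force oracle (exhaustive
slot-assignment search for gaps, enumeration for leading context) on 1000
random sequences of length ≤ 200 over a G/R-biased alphabet, plus 3000
random gap segments; idempotence (a motif re-scanned in isolation is found
whole, with identical unit classes) is asserted for all 86 reference strings
and 10,000 generated motifs.  The full suite runs in a few seconds.

## Known limitations

- Proteome-wide gene/isoform statistics (e.g. "161 isoforms of 18 genes")
  require the actual proteome FASTA and are not reproduced here; the census
  logic itself is fully tested on the packaged motif strings.
- Motif positions and coverage within full-length proteins cannot be checked
  from the packaged strings alone (only the strings were published).
- No fuzzy matching, no user-editable grammar (constants are exposed
  read-only), and no FG/FGG unit support.
- Domain-boundary choices other than the grammar's (e.g. manually delimited
  domains) must be supplied by the user as subsequences.
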