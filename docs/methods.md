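# Methods

## The screening procedure

`phoscross` implements an ungapped, center-anchored peptide comparison.
Every annotated phosphoserine/phosphotyrosine in a reviewed proteome
defines a candidate window of 13 residues (half-width 6) centered on the
site; each candidate is compared to each seed window position-by-position
at offsets −6…+6 from the center.

1. **Anchor filter.** The residues at offsets −1 and +1 must equal the
   seed's exactly. A window truncated at either flank fails automatically —
   a missing residue cannot be a perfect match. This is the only hard
   constraint; in particular the central residue itself is *not* required
   to match (a phosphotyrosine site may be compared to a serine-centered
   seed). A `strict_center` switch adds that requirement for users who
   want it.
2. **Match tallies.** A position is *exact* when the residues are
   identical, and *similar* when they are non-identical with PAM120 score
   strictly greater than the threshold (default 1). The tallies are
   disjoint: an identical pair counts once, as exact. Terminus padding is
   neither exact nor similar and breaks stretches.
3. **Stretch metrics.** `exact_stretch` and `exact_or_similar_stretch` are
   the lengths of the longest run of consecutive qualifying positions that
   contains offset 0; both are 0 when offset 0 itself fails the predicate
   (hence 0 exact stretch whenever the central residues differ).
4. **Ranking.** Within each (seed, organism) group: exact stretch,
   exact+similar stretch, exact count, similar count — all descending —
   then molecular weight, then accession and site position as final
   deterministic tie-breaks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `half_width` | 6 | window half-width; 13-mer windows are the only width used in practice |
| `threshold` | 1 | similarity requires PAM120 score strictly greater than this |
| `strict_center` | off | additionally require the central residue to equal the seed's |
| `mw_ascending` | true | direction of the molecular-weight sort key |
| organisms | 9606, 10090 | NCBI taxa kept after parsing (human, mouse) |

The PAM120 table is embedded as a 20×20 constant over the standard
residues; any other code (B, Z, X, U, O, padding) scores a sentinel far
below any threshold, so nonstandard residues can never count as similar,
while two identical nonstandard codes still count as an exact character
match. A unit test cross-checks the embedded table cell-by-cell against
the independently packaged NCBI PAM120 matrix.

## Design choices made where the procedure was open

* **Center residues need not match.** The stated hard constraint concerns
  only the flanking residues; the "encompassing the phosphosite" clause
  then zeroes the exact stretch when centers differ. The strict-center
  mode exposes the alternative reading.
* **Molecular-weight key direction: ascending.** The weight is the last,
  weakest key and its direction is not dictated by the four metric keys;
  ascending ranks the candidate most plausibly co-migrating with small
  proteins (like aSyn itself, 14.5 kDa) first on metric ties. A flag flips
  it.
* **Cross-organism commonality by case-folded gene symbol**, falling back
  to the entry-name stem when a gene name is absent. This is the lightest
  assumption that makes SNCA/Snca a common hit without an orthology
  database; the intersection is reported both per seed and over the seed
  union, since either reading of "common to both organisms" is defensible.
* **Biofluid overlap deduplicates proteins across seeds** before counting,
  so the percentage refers to distinct candidate proteins.
* **Isoform-scoped MOD_RES features are skipped**; only canonical-sequence
  sites are scanned, since sequence and weight come from the canonical
  record. Duplicate annotations at one position collapse to one site.
  A site annotated on a residue that cannot carry it (e.g. phosphoserine
  on Met) is dropped with a warning; structural malformations (missing
  ID/SQ, length disagreeing with the SQ header, feature beyond the
  sequence) reject the whole record, recorded in the parse report.

## Reference constants

The canonical human (P37840) and mouse (O55042) alpha-synuclein sequences
ship as constants; they differ at seven positions, including the
asparagine at 87 that makes pS87 impossible in mouse. The default seeds
are the six 13-mers at Y39, S87, Y125, S129, Y133, Y136 (the Y136 window
is C-terminally truncated by two residues, rendered with a `*`).
`NFL_PS472_WINDOW` is the 13-mer of the human neurofilament light chain
C-terminal tail centered on the phosphoserine reported to cross-react with
pS129 antibodies; against the S129 seed it shows exactly the published
configuration (exact stretch 3, one disjoint exact match, two similars).
No equivalently validated window is packaged for the ABLIM1 pY439
comparison, so the worked ABLIM1-like example is a *synthetic* window
planted to the reported configuration (exact stretch 5 plus two conserved
residues outside it) and verified by the oracle.

## The synthetic proteome generator

The generator emulates the screen's input format — flat-text records with
ID/AC/GN/OS/OX lines, MOD_RES features, CC SUBCELLULAR LOCATION paragraphs
and a 60-column sequence block — with exact ground-truth control:

* **Planted candidates** realize a requested
  (exact_stretch, n_exact, n_similar) target against a chosen seed: the
  anchors and center are copied from the seed, the exact run is placed
  around the center with non-exact boundary slots, isolated extra exacts
  are kept non-adjacent to the run, similar slots draw from residues
  scoring above the threshold, and every remaining slot draws from the
  seed residue's similarity complement so it contributes to neither tally.
  Targets with exact_stretch < 3 are rejected up front (anchors + center
  are exact by construction), as are targets that no run placement can
  host. Feasibility can also depend on the seed: a similar slot needs a
  partner residue scoring > 1 against the seed residue at that offset
  (none exists for Gly or Trp), and a terminus-truncated seed cannot host
  runs reaching into its padding — the generator cycles to the next
  feasible target for that seed.
* **Decoys** are anchor-failing *by construction* (the −1 flank is drawn
  from residues used by no seed), so zero false positives is a hard
  assertion. This relies on the seeds having pairwise-distinct flank
  pairs, which the generator verifies.
* Sequences are uniform over the 20 standard residues (optionally
  user-weighted), lengths uniform on [100, 600], organisms interleaved
  human/mouse with paired gene symbols so commonality is testable.
  All output is a pure function of the configuration, including its random
  seed — identical configs give byte-identical flat text.

The generator makes no attempt to mimic real proteome composition, domain
structure, annotation density or phosphosite clustering. Passing the
recovery tests therefore demonstrates correctness of the scanning
machinery on controlled inputs, not performance characteristics on a real
proteome (where hit counts are dominated by the database snapshot's
annotation state).

## Verification strategy and problem sizes

`oracle_compare` is an independent brute-force reference that enumerates
every contiguous offset interval containing the center; it shares no code
with the production comparator. The acceptance run checks agreement on all
four metric fields over 10,000 randomized window pairs (including
truncated candidates) and planted-hit recovery (precision = recall = 1,
realized metrics equal to targets) on a 500-entry proteome with 24 planted
sites and 50 decoys — sizes chosen so the whole acceptance run completes
in a few seconds while exercising every feasibility branch of the
generator. Reports are verified byte-identical across repeated runs;
flat-file round-trip identity is property-tested over randomized records.

## Known limitations

* Strictly ungapped, center-anchored comparison: no indels, no E-values,
  no structural context — by design, since the screen models linear
  epitope similarity only.
* Location phrases containing internal periods or semicolons do not
  survive the fixture writer's round trip (real UniProt entries are
  unaffected on parse; only the writer's output is constrained).
* Secondary accessions are retained for presence-list matching but hits
  are keyed by primary accession; deduplication of obsolete/merged entries
  is left to the caller.
* The biofluid overlap uses user-supplied presence lists; no live database
  queries are performed.
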