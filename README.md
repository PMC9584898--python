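# phoscross

A proteome-wide screen for proteins whose annotated phosphorylation sites
could cross-react with antibodies raised against phosphosite-containing
peptide fragments — built around the alpha-synuclein (aSyn) phosphosites
central to Parkinson's disease research (Y39, S87, Y125, S129, Y133, Y136).

Antibodies against aSyn pS129 are the workhorse reagents for detecting
Lewy pathology, yet several of them bind other phosphoproteins (most
famously neurofilament light chain, NFL, via its C-terminal phosphoserine).
`phoscross` catalogs such candidates systematically: it parses reviewed
UniProtKB-style flat-text entries, extracts a 13-residue window centered on
every annotated phosphoserine/phosphotyrosine, and compares each window to
the seed fragments the antibody was raised against.

## Method

For a seed window $s$ and candidate window $c$, aligned center-to-center
over offsets $k = -6 \dots +6$:

* **Anchor filter** — the residues immediately flanking the phosphosite
  ($k = \pm 1$) must match the seed exactly; only anchored windows become
  hits.
* **Similarity** — positions with identical residues are *exact* matches;
  non-identical positions with PAM120 score $> 1$ are *similar*
  (Glu≅Gln = 2 and Tyr≅Phe = 4 qualify; Ile/Leu = 1 and Ile/Phe = 0 do
  not). Terminus padding is neither.
* **Stretch metrics** — the longest run of consecutive exact (or
  exact-or-similar) positions that encompasses the phosphosite.
* **Ranking** — per seed and organism, hits are sorted by exact stretch,
  then exact+similar stretch, then exact count, then similar count (all
  descending), then molecular weight (ascending by default).

Candidates found in both human and mouse are intersected by case-folded
gene symbol, and the candidate set can be checked against user-supplied
plasma/CSF presence lists.

Because the full reviewed human+mouse phosphoproteome must be supplied by
the user (no network retrieval is performed; the original snapshot query
was UniProtKB `(annotation:(type:mod_res phosphoserine) OR
annotation:(type:mod_res phosphotyrosine)) AND reviewed:yes` for taxa
9606 and 10090), the package ships a synthetic-proteome generator that
plants candidate windows with exact, requested metric values alongside
anchor-failing decoys — every pipeline stage is testable offline with
known ground truth.

## Worked example

The canonical S129 seed against the NFL pS472 window:

```python
from phoscross import compare_windows, default_seed_set, NFL_PS472_WINDOW
from phoscross.model import PeptideWindow

seeds = {s.seed_id: s for s in default_seed_set()}
nfl = PeptideWindow(NFL_PS472_WINDOW, center_pos=472)
print("seed  S129 :", seeds["S129"].window.render())
print("NFL pS472  :", nfl.render())
print("metrics    :", compare_windows(seeds["S129"], nfl))
```

prints

```
seed  S129 : EAYEMPSEEGYQD
NFL pS472  : AKDEPPSEGEAEE
metrics    : MatchMetrics(n_exact=4, n_similar=2, exact_stretch=3, exact_or_similar_stretch=3)
```

i.e. NFL shares with the aSyn pS129 region a continuous stretch of three
conserved residues around the phosphosite (P-S-E), a fourth disjoint
conserved residue, and two further positions with high PAM120 similarity —
a modest local similarity that nevertheless suffices for experimental
cross-reaction.

From the shell, scanning a two-entry human+mouse aSyn fixture:

```sh
phoscross scan --input asyn.dat --out out
# INFO phoscross: parsed 2 entries (0 rejected, 0 warnings)
# INFO phoscross: seed S129: 2 hits
# INFO phoscross: seed S87: 1 hits
# INFO phoscross: seed Y125: 2 hits
# INFO phoscross: seed Y133: 0 hits ...
```

Three seeds (S87, Y125, S129) return human aSyn — exactly the three
residues annotated as phosphorylated — and only Y125/S129 return mouse
aSyn, because mouse carries a non-phosphorylatable asparagine at
position 87. `out/` contains one ranked TSV per seed, a `summary.tsv`
(hit counts per seed/organism, cross-organism commonality, subcellular
locations, biofluid overlap percentages) and a reproducibility manifest.

`phoscross simulate --n-entries 500 --n-planted 4 --seed 42 --out sim`
writes a synthetic proteome plus its ground-truth table; scanning it
recovers exactly the planted hits.

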