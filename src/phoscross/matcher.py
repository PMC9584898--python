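"""Center-anchored window comparison: anchor filter, similarity, metrics, scan.

The comparison is strictly ungapped: seed and candidate windows are aligned
center-to-center over offsets -6..+6.  The only hard constraint is that the
residues immediately preceding and following the phosphosite must match the
seed exactly (the "anchors"); the remaining positions are tallied as exact
or highly similar (PAM120 score strictly greater than the threshold), and
the longest run of matching positions encompassing the phosphosite is
recorded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

from .model import (
    CandidateHit,
    MatchMetrics,
    PeptideWindow,
    ProteinEntry,
    SeedFragment,
)
from .pam120 import PAM120, SENTINEL_SCORE, pam120_score

__all__ = [
    "SimilarityRule",
    "pam120_score",
    "anchors_match",
    "compare_windows",
    "scan_proteome",
    "hits_to_tsv",
    "hits_from_tsv",
    "HIT_COLUMNS",
]


@dataclass(frozen=True)
class SimilarityRule:
    """Substitution matrix plus the strictly-greater-than similarity bound."""

    matrix: Mapping[tuple[str, str], int] = field(default_factory=lambda: PAM120)
    threshold: int = 1

    def score(self, a: str | None, b: str | None) -> int:
        if a is None or b is None:
            return SENTINEL_SCORE
        return self.matrix.get((a, b), SENTINEL_SCORE)

    def is_similar(self, a: str | None, b: str | None) -> bool:
        """Non-identical residues scoring strictly above the threshold."""
        return a is not None and b is not None and a != b \
            and self.score(a, b) > self.threshold


DEFAULT_RULE = SimilarityRule()


def _window_of(seed: SeedFragment | PeptideWindow) -> PeptideWindow:
    return seed.window if isinstance(seed, SeedFragment) else seed


def anchors_match(seed: SeedFragment | PeptideWindow,
                  candidate: PeptideWindow) -> bool:
    """True iff the residues at offsets -1 and +1 match the seed exactly.

    A candidate missing either flank (terminus truncation) fails
    automatically: a missing residue cannot be a perfect match.
    """
    sw = _window_of(seed)
    for offset in (-1, +1):
        a = sw.residue_at(offset)
        b = candidate.residue_at(offset)
        if a is None or b is None or a != b:
            return False
    return True


def compare_windows(seed: SeedFragment | PeptideWindow,
                    candidate: PeptideWindow,
                    rule: SimilarityRule = DEFAULT_RULE) -> MatchMetrics:
    """Tally the four match metrics over the center-aligned windows.

    A position where either window is terminus-padded is neither exact nor
    similar and breaks any stretch.  Both stretch metrics are the longest
    run of qualifying consecutive positions that contains offset 0, and are
    0 when offset 0 itself fails the predicate (in particular, when the
    central residues differ the exact stretch is 0).
    """
    sw = _window_of(seed)
    h = sw.half_width
    offsets = range(-h, h + 1)
    exact: dict[int, bool] = {}
    similar: dict[int, bool] = {}
    for k in offsets:
        a = sw.residue_at(k)
        b = candidate.residue_at(k)
        exact[k] = a is not None and b is not None and a == b
        similar[k] = rule.is_similar(a, b)

    def stretch(pred: dict[int, bool]) -> int:
        if not pred[0]:
            return 0
        lo = 0
        while lo > -h and pred[lo - 1]:
            lo -= 1
        hi = 0
        while hi < h and pred[hi + 1]:
            hi += 1
        return hi - lo + 1

    either = {k: exact[k] or similar[k] for k in offsets}
    return MatchMetrics(
        n_exact=sum(exact.values()),
        n_similar=sum(similar.values()),
        exact_stretch=stretch(exact),
        exact_or_similar_stretch=stretch(either),
    )


def scan_proteome(
    seeds: Sequence[SeedFragment],
    entries: Iterable[ProteinEntry],
    rule: SimilarityRule = DEFAULT_RULE,
    strict_center: bool = False,
) -> dict[str, list[CandidateHit]]:
    """Compare every annotated phosphosite of every entry to every seed.

    A hit is emitted iff the anchor filter passes; the seed's own source
    protein is not excluded (aSyn is expected among its own hits).  Every
    site is tested against every seed regardless of its kind — the anchor
    filter and metrics decide.  Duplicate annotations at one position are
    collapsed to a single site.  With ``strict_center`` the candidate's
    central residue must additionally equal the seed's (off by default; the
    flank anchors are the only stated hard constraint).
    """
    hits: dict[str, list[CandidateHit]] = {s.seed_id: [] for s in seeds}
    for entry in entries:
        seen_positions: set[int] = set()
        for site in entry.phosphosites:
            if site.position in seen_positions:
                continue
            seen_positions.add(site.position)
            window = None
            for seed in seeds:
                if window is None or window.half_width != seed.window.half_width:
                    from .seeds import extract_window
                    window = extract_window(
                        entry.sequence, site.position, seed.window.half_width
                    )
                if not anchors_match(seed, window):
                    continue
                if strict_center and window.center_residue != seed.window.center_residue:
                    continue
                hits[seed.seed_id].append(CandidateHit(
                    seed_id=seed.seed_id,
                    accession=entry.accession,
                    entry_name=entry.entry_name,
                    gene_name=entry.gene_name,
                    organism_taxon=entry.organism_taxon,
                    site=site,
                    window=window,
                    metrics=compare_windows(seed, window, rule),
                    mw_da=entry.mw_da,
                    locations=entry.locations,
                ))
    return hits


HIT_COLUMNS = [
    "seed_id", "accession", "entry_name", "gene", "organism_taxon",
    "site_position", "site_kind", "window",
    "n_exact", "n_similar", "exact_stretch", "exact_or_similar_stretch",
    "mw_da", "rank", "locations",
]


def hits_to_tsv(hits: Iterable[CandidateHit], handle: TextIO) -> None:
    """Serialize hits as UTF-8 TSV with a header row."""
    writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
    writer.writerow(HIT_COLUMNS)
    for h in hits:
        writer.writerow([
            h.seed_id, h.accession, h.entry_name, h.gene_name, h.organism_taxon,
            h.site.position, h.site.kind, h.window.render(),
            h.metrics.n_exact, h.metrics.n_similar,
            h.metrics.exact_stretch, h.metrics.exact_or_similar_stretch,
            h.mw_da, "" if h.rank is None else h.rank,
            ";".join(h.locations),
        ])


def _window_from_display(text: str, center_pos: int) -> PeptideWindow:
    half = len(text) // 2
    stripped = text.strip("-*")
    left = len(text) - len(text.lstrip("-"))
    right = len(text) - len(text.rstrip("-*"))
    return PeptideWindow(
        residues=stripped,
        center_pos=center_pos,
        left_missing=left,
        right_missing=right,
        c_terminal="*" in text,
        half_width=half,
    )


def hits_from_tsv(handle: TextIO) -> list[CandidateHit]:
    """Read hits previously written by :func:`hits_to_tsv` (for re-ranking)."""
    from .model import PhosphoSite
    reader = csv.DictReader(handle, delimiter="\t")
    hits = []
    for row in reader:
        pos = int(row["site_position"])
        window = _window_from_display(row["window"], pos)
        hits.append(CandidateHit(
            seed_id=row["seed_id"],
            accession=row["accession"],
            entry_name=row["entry_name"],
            gene_name=row["gene"],
            organism_taxon=int(row["organism_taxon"]),
            site=PhosphoSite(pos, window.center_residue, row["site_kind"]),
            window=window,
            metrics=MatchMetrics(
                n_exact=int(row["n_exact"]),
                n_similar=int(row["n_similar"]),
                exact_stretch=int(row["exact_stretch"]),
                exact_or_similar_stretch=int(row["exact_or_similar_stretch"]),
            ),
            mw_da=int(row["mw_da"]),
            locations=tuple(p for p in row["locations"].split(";") if p),
            rank=int(row["rank"]) if row.get("rank") else None,
        ))
    return hits
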