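"""Five-key ranking, cross-organism commonality, biofluid overlap, reports.

Hits are ordered by: longest continuous exact-match stretch, then longest
exact+similar stretch, then exact-match count, then similar-match count
(all descending), then molecular weight.  The weight direction is
configurable (ascending by default) and a final accession tie-break makes
reports byte-identical across runs and platforms.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .model import CandidateHit, OverlapSummary
from .matcher import hits_to_tsv

log = logging.getLogger(__name__)


def rank_hits(hits: Sequence[CandidateHit],
              mw_ascending: bool = True) -> list[CandidateHit]:
    """Sort one (seed, organism) group of hits and assign ranks 1..n.

    The input is not mutated; ranked copies are returned.  The order is
    total (accession then site position break any remaining ties), so the
    result is invariant under permutation of the input.
    """
    def key(h: CandidateHit):
        m = h.metrics
        return (
            -m.exact_stretch,
            -m.exact_or_similar_stretch,
            -m.n_exact,
            -m.n_similar,
            h.mw_da if mw_ascending else -h.mw_da,
            h.accession,
            h.site.position,
        )

    ranked = sorted((replace(h, rank=None) for h in hits), key=key)
    return [replace(h, rank=i) for i, h in enumerate(ranked, start=1)]


@dataclass(frozen=True)
class CommonalityResult:
    """Proteins found in both organisms, per seed and over the seed union."""

    per_seed: dict[str, frozenset[str]]
    union: frozenset[str]

    def size(self, seed_id: str) -> int:
        return len(self.per_seed.get(seed_id, frozenset()))


def common_across_organisms(
    human_hits: Mapping[str, Sequence[CandidateHit]],
    mouse_hits: Mapping[str, Sequence[CandidateHit]],
) -> CommonalityResult:
    """Case-insensitive gene-name intersection of the two organisms' hits.

    Proteins without gene names match on the entry-name stem (text before
    the "_" organism suffix).  Reported both per seed and over the union of
    seeds, since either reading of "common to both organisms" is defensible.
    """
    per_seed: dict[str, frozenset[str]] = {}
    for seed_id in sorted(set(human_hits) | set(mouse_hits)):
        h_keys = {h.protein_key for h in human_hits.get(seed_id, [])}
        m_keys = {h.protein_key for h in mouse_hits.get(seed_id, [])}
        per_seed[seed_id] = frozenset(h_keys & m_keys)
    h_all = {h.protein_key for hits in human_hits.values() for h in hits}
    m_all = {h.protein_key for hits in mouse_hits.values() for h in hits}
    return CommonalityResult(per_seed=per_seed, union=frozenset(h_all & m_all))


def read_presence_list(source: TextIO | str | Path) -> frozenset[str]:
    """One identifier per line; '#' comments allowed; case-folded."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    ids = set()
    for line in text.splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.add(token.upper())
    return frozenset(ids)


def annotate_biofluids(hits: Iterable[CandidateHit] | Iterable[str],
                       presence_list: frozenset[str] | set[str],
                       label: str) -> OverlapSummary:
    """Fraction of distinct candidate proteins found in a presence list.

    Proteins are deduplicated across seeds before counting; matching is
    case-insensitive against accession first, then gene name.  Plain
    identifier iterables are accepted for ad-hoc use.
    """
    presence = {p.upper() for p in presence_list}
    proteins: dict[str, bool] = {}
    for item in hits:
        if isinstance(item, str):
            key = item.upper()
            found = key in presence
        else:
            key = item.protein_key
            found = any(a.upper() in presence for a in (item.accession,)) \
                or (item.gene_name and item.gene_name.upper() in presence)
        proteins[key] = proteins.get(key, False) or bool(found)
    total = len(proteins)
    present = sum(proteins.values())
    if total == 0:
        log.warning("overlap %s: empty hit set; percentage reported as 0", label)
    return OverlapSummary(label=label, total=total, present=present)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_report(
    ranked: Mapping[str, Sequence[CandidateHit]],
    summaries: Sequence[OverlapSummary],
    destination: str | Path,
    manifest: Mapping[str, object] | None = None,
    commonality: CommonalityResult | None = None,
) -> list[Path]:
    """One TSV per seed, a summary TSV, and a run manifest.

    Output is deterministic: identical inputs yield byte-identical files.
    The destination is validated before any file is written.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    if not dest.is_dir():
        raise OSError(f"destination {dest} is not a writable directory")

    written: list[Path] = []
    for seed_id in sorted(ranked):
        path = dest / f"hits_{seed_id}.tsv"
        with path.open("w", newline="") as fh:
            hits_to_tsv(ranked[seed_id], fh)
        written.append(path)

    summary_path = dest / "summary.tsv"
    with summary_path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "record_type", "seed_id", "organism_taxon", "n_hits", "n_common",
            "locations", "overlap_label", "total", "present", "percentage",
        ])
        for seed_id in sorted(ranked):
            hits = ranked[seed_id]
            for taxon in sorted({h.organism_taxon for h in hits}):
                group = [h for h in hits if h.organism_taxon == taxon]
                locs = sorted({loc for h in group for loc in h.locations})
                n_common = (commonality.size(seed_id)
                            if commonality is not None else "")
                writer.writerow([
                    "hits", seed_id, taxon, len(group), n_common,
                    ";".join(locs), "", "", "", "",
                ])
        if commonality is not None:
            writer.writerow(["common_union", "", "", len(commonality.union),
                             "", "", "", "", "", ""])
        for s in summaries:
            writer.writerow([
                "overlap", "", "", "", "", "", s.label,
                s.total, s.present, f"{s.percentage:.2f}",
            ])
    written.append(summary_path)

    manifest_path = dest / "manifest.txt"
    with manifest_path.open("w") as fh:
        for k in sorted(manifest or {}):
            fh.write(f"{k}={manifest[k]}\n")
        all_hits = "".join(
            p.read_text() for p in written if p.name.startswith("hits_")
        )
        fh.write(f"hits_digest={_digest(all_hits)}\n")
    written.append(manifest_path)
    return written
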