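"""Synthetic flat-file proteomes with planted, metric-controlled candidates.

The generator emulates the screen's real input — reviewed flat-text entries
with annotated phosphosites — while controlling the ground truth exactly:
planted sites realize requested (exact_stretch, n_exact, n_similar) targets
against a chosen seed, and decoy sites fail the anchor filter for every
seed *by construction* (a mutated flank), so "no false positives" is a hard
assertion rather than a statistical one.  It makes no attempt to mimic real
proteome composition, domain structure or annotation biases.

:func:`oracle_compare` is an independent brute-force reference for the
window metrics, sharing no code with :func:`phoscross.matcher.compare_windows`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.SeqUtils import molecular_weight

from .matcher import DEFAULT_RULE, SimilarityRule
from .model import (
    EXTENDED_RESIDUES,
    MatchMetrics,
    PhoscrossError,
    PhosphoSite,
    ProteinEntry,
    SeedFragment,
    STANDARD_RESIDUES,
)

PAD_CHARS = "-*"


class InfeasibleTargetError(PhoscrossError):
    """A requested metric target violates the metric inequalities."""


class PlantingError(PhoscrossError):
    """No residue assignment can realize the requested target."""


# ---------------------------------------------------------------------------
# independent oracle

def oracle_compare(seed_text: str, candidate_text: str,
                   rule: SimilarityRule = DEFAULT_RULE) -> MatchMetrics:
    """Brute-force window metrics from two padded window texts.

    Both inputs are (2h+1)-character strings with explicit padding marks
    ('-' or '*').  Stretches are found by exhaustive enumeration of every
    contiguous offset interval containing the center.
    """
    n = len(seed_text)
    if len(candidate_text) != n or n % 2 == 0:
        raise PhoscrossError("oracle needs two odd, equal-length window texts")
    center = n // 2

    def is_exact(i: int) -> bool:
        a, b = seed_text[i], candidate_text[i]
        return a in EXTENDED_RESIDUES and b in EXTENDED_RESIDUES and a == b

    def is_similar(i: int) -> bool:
        a, b = seed_text[i], candidate_text[i]
        return (a in EXTENDED_RESIDUES and b in EXTENDED_RESIDUES
                and a != b and rule.score(a, b) > rule.threshold)

    def longest(pred) -> int:
        best = 0
        for i in range(0, center + 1):
            for j in range(center, n):
                if all(pred(k) for k in range(i, j + 1)):
                    best = max(best, j - i + 1)
        return best

    return MatchMetrics(
        n_exact=sum(is_exact(i) for i in range(n)),
        n_similar=sum(is_similar(i) for i in range(n)),
        exact_stretch=longest(is_exact),
        exact_or_similar_stretch=longest(lambda k: is_exact(k) or is_similar(k)),
    )


# ---------------------------------------------------------------------------
# residue pools under the similarity rule

def _similar_partners(residue: str, rule: SimilarityRule) -> list[str]:
    return [r for r in STANDARD_RESIDUES
            if r != residue and rule.score(r, residue) > rule.threshold]


def _dissimilar_pool(residue: str, rule: SimilarityRule) -> list[str]:
    return [r for r in STANDARD_RESIDUES
            if r != residue and rule.score(r, residue) <= rule.threshold]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic proteome.

    Defaults produce a small two-organism proteome with uniformly random
    sequences, a handful of planted candidates per seed spanning the
    worked-example metric configurations, and anchor-failing decoys.
    """

    n_entries: int = 50
    min_length: int = 100
    max_length: int = 600
    residue_frequencies: Mapping[str, float] | None = None  # uniform default
    n_planted_per_seed: int = 2
    metric_targets: tuple[tuple[int, int, int], ...] = (
        (3, 4, 2),    # NFL-like: stretch 3, one disjoint exact, two similars
        (5, 7, 0),    # ABLIM1-like: stretch 5, two extra conserved residues
        (4, 6, 1),
        (13, 13, 0),  # identity
    )
    organism_mix: tuple[tuple[int, float], ...] = ((9606, 0.5), (10090, 0.5))
    n_decoys: int = 20
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_entries < 1 or self.min_length < 13 \
                or self.max_length < self.min_length:
            raise InfeasibleTargetError("bad entry count or length bounds")
        for target in self.metric_targets:
            _check_target(target)


def _check_target(target: tuple[int, int, int], half_width: int = 6) -> None:
    es, ne, ns = target
    span = 2 * half_width + 1
    if es > ne:
        raise InfeasibleTargetError(
            f"target {target}: exact_stretch {es} cannot exceed n_exact {ne}")
    if ne + ns > span:
        raise InfeasibleTargetError(
            f"target {target}: n_exact + n_similar exceeds window span {span}")
    if es < 3:
        raise InfeasibleTargetError(
            f"target {target}: anchors and center are exact by construction, "
            f"so exact_stretch must be at least 3")
    if es > span:
        raise InfeasibleTargetError(
            f"target {target}: exact_stretch exceeds window span {span}")
    if not _run_placements(es, ne, ns, half_width):
        raise InfeasibleTargetError(
            f"target {target}: no run placement leaves room for "
            f"{ne - es} isolated exact matches and {ns} similar positions")


def _run_placements(es: int, ne: int, ns: int,
                    half_width: int) -> list[tuple[int, int]]:
    """Feasible (a, b) with run offsets [-a..b], a+b+1 == es, anchors inside."""
    placements = []
    span = 2 * half_width + 1
    for a in range(1, half_width + 1):
        b = es - 1 - a
        if not 1 <= b <= half_width:
            continue
        boundary = (1 if a < half_width else 0) + (1 if b < half_width else 0)
        extras = ne - es
        free = span - es - boundary
        if extras <= free and ns <= span - es - extras:
            placements.append((a, b))
    return placements


# ---------------------------------------------------------------------------
# planting

def plant_candidate(sequence: str, position: int, seed: SeedFragment,
                    target: tuple[int, int, int], rng: random.Random,
                    rule: SimilarityRule = DEFAULT_RULE) -> str:
    """Rewrite the 13-mer window at ``position`` to realize a metric target.

    The anchors and the center are made identical to the seed; exact
    matches form a run of exactly ``target[0]`` positions around the center
    plus isolated extras up to ``target[1]``; exactly ``target[2]``
    positions carry non-identical residues scoring above the similarity
    threshold; every remaining position is drawn from the seed residue's
    similarity complement, so it contributes to neither tally.
    """
    es, ne, ns = target
    _check_target(target)
    h = seed.window.half_width
    if position - h < 1 or position + h > len(sequence):
        raise PlantingError(
            f"position {position} does not admit a full window of half-width {h}")

    seed_res = {k: seed.window.residue_at(k) for k in range(-h, h + 1)}
    placements = _run_placements(es, ne, ns, h)
    rng.shuffle(placements)
    for a, b in placements:
        run = set(range(-a, b + 1))
        if any(seed_res[k] is None for k in run):
            continue  # run would extend into the seed's terminus padding
        boundary = {k for k in (-a - 1, b + 1) if -h <= k <= h}
        outside = [k for k in range(-h, h + 1) if k not in run]
        extra_slots = [k for k in outside
                       if k not in boundary and seed_res[k] is not None]
        rng.shuffle(extra_slots)
        extras = set(extra_slots[: ne - es])
        if len(extras) < ne - es:
            continue
        sim_candidates = [k for k in outside if k not in extras
                          and seed_res[k] is not None
                          and _similar_partners(seed_res[k], rule)]
        rng.shuffle(sim_candidates)
        similars = set(sim_candidates[:ns])
        if len(similars) < ns:
            continue

        chars = list(sequence)
        for k in range(-h, h + 1):
            s = seed_res[k]
            if k in run or k in extras:
                chars[position - 1 + k] = s
            elif k in similars:
                chars[position - 1 + k] = rng.choice(_similar_partners(s, rule))
            elif s is None:
                chars[position - 1 + k] = rng.choice(STANDARD_RESIDUES)
            else:
                chars[position - 1 + k] = rng.choice(_dissimilar_pool(s, rule))
        return "".join(chars)
    raise PlantingError(
        f"no placement can realize target {target} against seed {seed.seed_id}")


# ---------------------------------------------------------------------------
# proteome generation

@dataclass(frozen=True)
class PlantedSite:
    accession: str
    position: int
    seed_id: str
    metrics: MatchMetrics


@dataclass(frozen=True)
class SyntheticTruth:
    planted: tuple[PlantedSite, ...]
    decoys: tuple[tuple[str, int], ...]  # (accession, position)


_LOCATION_VOCAB = ("Cytoplasm", "Nucleus", "Membrane", "Secreted",
                   "Mitochondrion", "Endoplasmic reticulum")


def _random_sequence(length: int, rng: random.Random,
                     freqs: Mapping[str, float] | None) -> str:
    if freqs is None:
        return "".join(rng.choices(STANDARD_RESIDUES, k=length))
    residues = sorted(freqs)
    weights = [freqs[r] for r in residues]
    return "".join(rng.choices(residues, weights=weights, k=length))


def _taxon_assignment(config: GeneratorConfig) -> list[int]:
    taxa = [t for t, _ in config.organism_mix]
    counts = {t: int(p * config.n_entries) for t, p in config.organism_mix}
    leftover = config.n_entries - sum(counts.values())
    for t in taxa:
        if leftover <= 0:
            break
        counts[t] += 1
        leftover -= 1
    order, idx = [], 0
    while len(order) < config.n_entries:
        t = taxa[idx % len(taxa)]
        if counts[t] > 0:
            order.append(t)
            counts[t] -= 1
        idx += 1
        if idx > 10 * config.n_entries * len(taxa):  # all remaining one taxon
            for t2 in taxa:
                order.extend([t2] * counts[t2])
                counts[t2] = 0
    return order[: config.n_entries]


def generate_synthetic_proteome(
    config: GeneratorConfig,
    seeds: Sequence[SeedFragment] | None = None,
    rule: SimilarityRule = DEFAULT_RULE,
) -> tuple[str, SyntheticTruth]:
    """Emit a parseable flat-text proteome and its ground truth.

    Identical config (including ``random_seed``) yields byte-identical
    output.  Scanning the proteome with the same seeds and rule recovers
    exactly the planted hits: every planted window realizes its requested
    metric target (oracle-verified here), and every decoy differs from
    every seed at the -1 flank.
    """
    from .flatfile import write_fixture_proteome
    from .seeds import default_seed_set, extract_window

    config.validate()
    if seeds is None:
        seeds = default_seed_set()
    flank_pairs = {(s.window.residue_at(-1), s.window.residue_at(+1))
                   for s in seeds}
    if len(flank_pairs) < len(seeds):
        raise PhoscrossError(
            "seeds must have distinct (-1,+1) flank pairs for unambiguous truth")
    forbidden_left = {s.window.residue_at(-1) for s in seeds} - {None}

    rng = random.Random(config.random_seed)
    taxa = _taxon_assignment(config)
    per_taxon_index: dict[int, int] = {}
    sequences: list[str] = []
    meta: list[dict] = []
    for i in range(config.n_entries):
        taxon = taxa[i]
        k = per_taxon_index.get(taxon, 0)
        per_taxon_index[taxon] = k + 1
        gene = f"SG{k:04d}"
        suffix = {9606: "HUMAN", 10090: "MOUSE"}.get(taxon, str(taxon))
        sequences.append(_random_sequence(
            rng.randint(config.min_length, config.max_length), rng,
            config.residue_frequencies))
        meta.append({
            "entry_name": f"SP{i:04d}_{suffix}",
            "accession": f"X{i:05d}",
            "taxon": taxon,
            "gene": gene if taxon == 9606 else gene.capitalize(),
            "locations": tuple(sorted(rng.sample(
                _LOCATION_VOCAB, rng.randint(0, 3)))),
        })

    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(config.n_entries)}
    sites: dict[int, list[PhosphoSite]] = {i: [] for i in range(config.n_entries)}

    def _free_position(entry_idx: int, h: int) -> int | None:
        length = len(sequences[entry_idx])
        if length < 2 * h + 1:
            return None
        for _ in range(50):
            pos = rng.randint(h + 1, length - h)
            if all(not (pos - h <= hi and lo <= pos + h)
                   for lo, hi in occupied[entry_idx]):
                occupied[entry_idx].append((pos - h, pos + h))
                return pos
        return None

    planted: list[PlantedSite] = []
    for seed in seeds:
        h = seed.window.half_width
        center = seed.window.center_residue
        kind = "phosphoserine" if center == "S" else "phosphotyrosine"
        n_done = 0
        target_cycle = 0
        while n_done < config.n_planted_per_seed:
            # next target in the cycle that this seed can realize
            target = None
            for j in range(len(config.metric_targets)):
                cand = config.metric_targets[
                    (target_cycle + j) % len(config.metric_targets)]
                try:
                    plant_candidate("A" * (2 * h + 1), h + 1, seed, cand,
                                    random.Random(0), rule)
                    target = cand
                    target_cycle += j + 1
                    break
                except (PlantingError, InfeasibleTargetError):
                    continue
            if target is None:
                raise PlantingError(
                    f"seed {seed.seed_id}: no configured target is realizable")
            entry_idx = rng.randrange(config.n_entries)
            pos = _free_position(entry_idx, h)
            if pos is None:
                continue
            sequences[entry_idx] = plant_candidate(
                sequences[entry_idx], pos, seed, target, rng, rule)
            sites[entry_idx].append(PhosphoSite(pos, center, kind))
            window = extract_window(sequences[entry_idx], pos, h)
            metrics = oracle_compare(seed.window.render(), window.render(), rule)
            if (metrics.exact_stretch, metrics.n_exact,
                    metrics.n_similar) != target:
                raise PhoscrossError(
                    f"planted window failed target {target}: got {metrics}")
            planted.append(PlantedSite(meta[entry_idx]["accession"], pos,
                                       seed.seed_id, metrics))
            n_done += 1

    h0 = seeds[0].window.half_width
    decoys: list[tuple[str, int]] = []
    attempts = 0
    decoy_left_pool = sorted(set(STANDARD_RESIDUES) - set(forbidden_left))
    if config.n_decoys and not decoy_left_pool:
        raise PhoscrossError("seed flanks exhaust the alphabet; no decoy residue")
    while len(decoys) < config.n_decoys and attempts < 50 * config.n_decoys:
        attempts += 1
        entry_idx = rng.randrange(config.n_entries)
        pos = _free_position(entry_idx, h0)
        if pos is None:
            continue
        chars = list(sequences[entry_idx])
        center = rng.choice("SY")
        chars[pos - 1] = center
        chars[pos - 2] = rng.choice(decoy_left_pool)
        sequences[entry_idx] = "".join(chars)
        kind = "phosphoserine" if center == "S" else "phosphotyrosine"
        sites[entry_idx].append(PhosphoSite(pos, center, kind))
        decoys.append((meta[entry_idx]["accession"], pos))

    entries = []
    for i in range(config.n_entries):
        seq = sequences[i]
        entries.append(ProteinEntry(
            entry_name=meta[i]["entry_name"],
            accession=meta[i]["accession"],
            sequence=seq,
            organism_taxon=meta[i]["taxon"],
            mw_da=round(molecular_weight(seq, "protein")),
            gene_name=meta[i]["gene"],
            phosphosites=tuple(sorted(sites[i], key=lambda s: s.position)),
            locations=meta[i]["locations"],
        ))
    truth = SyntheticTruth(planted=tuple(planted), decoys=tuple(decoys))
    return write_fixture_proteome(entries), truth
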