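"""Phosphosite-centered window extraction and the alpha-synuclein seed set.

The default seeds are six 13-mers of canonical human alpha-synuclein
centered on Y39, S87, Y125, S129, Y133 and Y136 — the phosphosites the
antibodies under study were raised against.  The canonical human and mouse
sequences ship as constants so the defaults and the self-scan need no
download.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    PeptideWindow,
    PhoscrossError,
    PhosphoSite,
    ProteinEntry,
    SeedFragment,
    WindowRangeError,
)

# Canonical human alpha-synuclein (SYUA_HUMAN, P37840), 140 aa, 14460 Da.
HUMAN_ASYN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
    "EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)

# Canonical mouse alpha-synuclein (SYUA_MOUSE, O55042), 140 aa.  Differs from
# the human protein at seven positions (53, 87, 100, 103, 107, 121, 122);
# notably an asparagine replaces S87, so mouse aSyn cannot carry pS87.
MOUSE_ASYN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVTTVAEKTK"
    "EQVTNVGGAVVTGVTAVAQKTVEGAGNIAAATGFVKKDQMGKGEEGYPQEGILEDMPVDP"
    "GSEAYEMPSEEGYQDYEPEA"
)

#: default seed phosphosite positions on human aSyn
DEFAULT_SEED_POSITIONS: tuple[int, ...] = (39, 87, 125, 129, 133, 136)

# 13-mer of human neurofilament light polypeptide (NEFL) centered on the
# C-terminal-tail phosphoserine (pS472) reported to cross-react with
# antibodies raised against aSyn pS129.
NFL_PS472_WINDOW = "AKDEPPSEGEAEE"


def human_asyn_entry() -> ProteinEntry:
    """Human aSyn record carrying the annotated phosphosites S87, Y125, S129."""
    return ProteinEntry(
        entry_name="SYUA_HUMAN",
        accession="P37840",
        sequence=HUMAN_ASYN_SEQUENCE,
        organism_taxon=9606,
        mw_da=14460,
        gene_name="SNCA",
        phosphosites=(
            PhosphoSite(87, "S", "phosphoserine"),
            PhosphoSite(125, "Y", "phosphotyrosine"),
            PhosphoSite(129, "S", "phosphoserine"),
        ),
        locations=("Cytoplasm", "Membrane", "Nucleus"),
    )


def mouse_asyn_entry() -> ProteinEntry:
    """Mouse aSyn record; only Y125 and S129 are annotatable (N at 87)."""
    return ProteinEntry(
        entry_name="SYUA_MOUSE",
        accession="O55042",
        sequence=MOUSE_ASYN_SEQUENCE,
        organism_taxon=10090,
        mw_da=14485,
        gene_name="Snca",
        phosphosites=(
            PhosphoSite(125, "Y", "phosphotyrosine"),
            PhosphoSite(129, "S", "phosphoserine"),
        ),
        locations=("Cytoplasm", "Membrane", "Nucleus"),
    )


def extract_window(sequence: str, position: int, half_width: int = 6) -> PeptideWindow:
    """Extract the window spanning ``position ± half_width`` (1-based).

    Positions falling before residue 1 or beyond the C-terminus are counted
    in ``left_missing`` / ``right_missing``; the ``c_terminal`` flag is set
    when the window reaches the final residue.
    """
    if not 1 <= position <= len(sequence):
        raise WindowRangeError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    lo = position - half_width
    hi = position + half_width
    left_missing = max(0, 1 - lo)
    right_missing = max(0, hi - len(sequence))
    residues = sequence[max(lo, 1) - 1 : min(hi, len(sequence))]
    return PeptideWindow(
        residues=residues,
        center_pos=position,
        left_missing=left_missing,
        right_missing=right_missing,
        c_terminal=hi >= len(sequence),
        half_width=half_width,
    )


def build_seed_set(
    source: ProteinEntry,
    positions: Sequence[int] = DEFAULT_SEED_POSITIONS,
    half_width: int = 6,
) -> list[SeedFragment]:
    """One seed fragment per position, labeled ``<residue><position>``.

    A seed must sit on a phosphorylatable residue (S or Y).
    """
    seeds = []
    for pos in positions:
        window = extract_window(source.sequence, pos, half_width)
        residue = window.center_residue
        if residue not in "SY":
            raise PhoscrossError(
                f"{source.entry_name} position {pos}: seed center must be "
                f"S or Y, found {residue}"
            )
        seeds.append(SeedFragment(f"{residue}{pos}", window, source))
    return seeds


def default_seed_set(half_width: int = 6) -> list[SeedFragment]:
    """The six human aSyn seeds: Y39, S87, Y125, S129, Y133, Y136."""
    return build_seed_set(human_asyn_entry(), DEFAULT_SEED_POSITIONS, half_width)


def seeds_to_fasta(seeds: Iterable[SeedFragment], handle: TextIO) -> None:
    """Write seeds as FASTA; headers encode the center bookkeeping."""
    records = []
    for s in seeds:
        w = s.window
        desc = (
            f"pos={w.center_pos} left={w.left_missing} right={w.right_missing} "
            f"cterm={int(w.c_terminal)} half_width={w.half_width}"
        )
        records.append(SeqRecord(Seq(w.residues), id=s.seed_id, description=desc))
    SeqIO.write(records, handle, "fasta")


def seeds_from_fasta(handle: TextIO) -> list[SeedFragment]:
    """Read a seed FASTA written by :func:`seeds_to_fasta`."""
    seeds = []
    for rec in SeqIO.parse(handle, "fasta"):
        fields = dict(
            token.split("=", 1) for token in rec.description.split()[1:] if "=" in token
        )
        window = PeptideWindow(
            residues=str(rec.seq).upper(),
            center_pos=int(fields.get("pos", 0)),
            left_missing=int(fields.get("left", 0)),
            right_missing=int(fields.get("right", 0)),
            c_terminal=bool(int(fields.get("cterm", 0))),
            half_width=int(fields.get("half_width", 6)),
        )
        seeds.append(SeedFragment(rec.id, window))
    return seeds
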