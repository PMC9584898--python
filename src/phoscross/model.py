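"""Core data model for the phosphosite cross-reactivity screen.

The screen compares 13-residue peptide windows centered on annotated
phosphoserine/phosphotyrosine sites against a small set of seed windows
(the epitope regions an antibody was raised against).  All residue
numbering is 1-based, matching UniProt feature coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# 20 standard one-letter codes plus the ambiguity/rare codes the flat-file
# format permits.  The rare codes are parsed but always score as dissimilar.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_RESIDUES = frozenset(STANDARD_RESIDUES) | frozenset("BZXUO")

#: map from the MOD_RES description token to the expected residue
PHOSPHO_KINDS = {"phosphoserine": "S", "phosphotyrosine": "Y"}


class PhoscrossError(Exception):
    """Base class for errors raised by this package."""


class InvalidEntryError(PhoscrossError):
    """A protein record violates a model invariant."""


class WindowRangeError(PhoscrossError):
    """A requested window center lies outside the sequence."""


@dataclass(frozen=True)
class PhosphoSite:
    """One annotated phosphorylation site on the canonical sequence."""

    position: int  # 1-based
    residue: str   # "S" or "Y"
    kind: str      # "phosphoserine" or "phosphotyrosine"

    def __post_init__(self) -> None:
        if self.kind not in PHOSPHO_KINDS:
            raise InvalidEntryError(f"unknown phosphosite kind {self.kind!r}")
        if PHOSPHO_KINDS[self.kind] != self.residue:
            raise InvalidEntryError(
                f"{self.kind} must sit on {PHOSPHO_KINDS[self.kind]}, got {self.residue!r}"
            )
        if self.position < 1:
            raise InvalidEntryError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class ProteinEntry:
    """One reviewed proteome record.

    ``accession`` is the primary accession; secondary accessions are kept
    because biofluid presence lists may cite them.
    """

    entry_name: str
    accession: str
    sequence: str
    organism_taxon: int
    mw_da: int
    gene_name: str = ""
    secondary_accessions: tuple[str, ...] = ()
    phosphosites: tuple[PhosphoSite, ...] = ()
    locations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entry_name:
            raise InvalidEntryError("entry_name must be non-empty")
        if not self.sequence:
            raise InvalidEntryError(f"{self.entry_name}: empty sequence")
        bad = set(self.sequence) - EXTENDED_RESIDUES
        if bad:
            raise InvalidEntryError(
                f"{self.entry_name}: residues outside the permitted alphabet: {sorted(bad)}"
            )
        for site in self.phosphosites:
            if site.position > len(self.sequence):
                raise InvalidEntryError(
                    f"{self.entry_name}: site position {site.position} beyond "
                    f"sequence length {len(self.sequence)}"
                )
            actual = self.sequence[site.position - 1]
            if actual != site.residue:
                raise InvalidEntryError(
                    f"{self.entry_name}: residue at {site.position} is {actual}, "
                    f"site annotated as {site.residue}"
                )

    @property
    def all_accessions(self) -> tuple[str, ...]:
        return (self.accession, *self.secondary_accessions)


@dataclass(frozen=True)
class PeptideWindow:
    """A peptide window centered on a phosphosite, possibly terminus-truncated.

    ``residues`` holds only the in-sequence part; ``left_missing`` /
    ``right_missing`` count positions falling before residue 1 or beyond the
    C-terminus.  For the default half-width of 6 the full window spans 13
    aligned positions (offsets -6..+6 from the center).
    """

    residues: str
    center_pos: int
    left_missing: int = 0
    right_missing: int = 0
    c_terminal: bool = False
    half_width: int = 6

    def __post_init__(self) -> None:
        span = 2 * self.half_width + 1
        if self.left_missing + len(self.residues) + self.right_missing != span:
            raise PhoscrossError(
                f"window parts sum to "
                f"{self.left_missing + len(self.residues) + self.right_missing}, "
                f"expected {span}"
            )

    @property
    def center_index(self) -> int:
        """Index of the center residue within ``residues``."""
        return self.half_width - self.left_missing

    @property
    def center_residue(self) -> str:
        return self.residues[self.center_index]

    def residue_at(self, offset: int) -> str | None:
        """Residue at a signed offset from the center; None where padded."""
        idx = self.center_index + offset
        if 0 <= idx < len(self.residues) and -self.half_width <= offset <= self.half_width:
            return self.residues[idx]
        return None

    def render(self) -> str:
        """Display form: '-' padding, with '*' marking the C-terminal end.

        Padding characters never participate in scoring.
        """
        left = "-" * self.left_missing
        if self.right_missing and self.c_terminal:
            right = "*" + "-" * (self.right_missing - 1)
        else:
            right = "-" * self.right_missing
        return left + self.residues + right


@dataclass(frozen=True)
class SeedFragment:
    """A query window centered on a seed phosphosite (e.g. aSyn S129)."""

    seed_id: str           # "<residue><position>", e.g. "S129"
    window: PeptideWindow
    source: ProteinEntry | None = None

    def __post_init__(self) -> None:
        if self.seed_id and self.seed_id[0] != self.window.center_residue:
            raise PhoscrossError(
                f"seed_id {self.seed_id} disagrees with center residue "
                f"{self.window.center_residue}"
            )


@dataclass(frozen=True)
class MatchMetrics:
    """The four statistics of a center-aligned window comparison.

    * ``n_exact`` — aligned positions with identical residues.
    * ``n_similar`` — aligned, non-identical positions whose substitution
      score is strictly greater than the similarity threshold.
    * ``exact_stretch`` — length of the longest run of consecutive exact
      matches that contains the central phosphosite position (0 when the
      centers differ).
    * ``exact_or_similar_stretch`` — same under the exact-or-similar
      predicate.
    """

    n_exact: int
    n_similar: int
    exact_stretch: int
    exact_or_similar_stretch: int

    def __post_init__(self) -> None:
        if self.exact_stretch > self.n_exact:
            raise PhoscrossError("exact_stretch cannot exceed n_exact")
        if self.exact_or_similar_stretch > self.n_exact + self.n_similar:
            raise PhoscrossError(
                "exact_or_similar_stretch cannot exceed n_exact + n_similar"
            )
        if min(self.n_exact, self.n_similar,
               self.exact_stretch, self.exact_or_similar_stretch) < 0:
            raise PhoscrossError("metrics must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_exact, self.n_similar,
                self.exact_stretch, self.exact_or_similar_stretch)


@dataclass
class CandidateHit:
    """A (seed, entry, site) triple that passed the anchor filter."""

    seed_id: str
    accession: str
    entry_name: str
    gene_name: str
    organism_taxon: int
    site: PhosphoSite
    window: PeptideWindow
    metrics: MatchMetrics
    mw_da: int
    locations: tuple[str, ...] = ()
    rank: int | None = None

    @property
    def protein_key(self) -> str:
        """Case-folded protein identity used for cross-organism matching.

        Gene name when present, otherwise the entry-name stem (text before
        the "_" organism suffix).
        """
        if self.gene_name:
            return self.gene_name.upper()
        return self.entry_name.split("_", 1)[0].upper()


@dataclass(frozen=True)
class OverlapSummary:
    """Overlap of the candidate protein set with a biofluid presence list."""

    label: str
    total: int
    present: int

    def __post_init__(self) -> None:
        if not 0 <= self.present <= max(self.total, 0):
            raise PhoscrossError("present must lie in [0, total]")

    @property
    def percentage(self) -> float:
        if self.total == 0:
            return 0.0
        return self.present / self.total * 100.0


@dataclass
class ParseReport:
    """Outcome of parsing a flat-file stream: accepted entries, per-record
    rejections (never silent truncation) and non-fatal warnings."""

    entries: list[ProteinEntry] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (label, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.entries) + len(self.rejected)
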