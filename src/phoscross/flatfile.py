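"""Reading and writing UniProtKB-style flat-text entries.

Record-level parsing is delegated to Biopython's Swiss-Prot parser; this
module splits the stream on the ``//`` record separator first so that a
malformed record is rejected individually — with the reason recorded in a
:class:`~phoscross.model.ParseReport` — instead of aborting or silently
truncating the stream.  A FASTA + TSV site-table alternative is provided
for users without flat files.
"""

from __future__ import annotations

import io
import logging
import re
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO, SwissProt

from .model import (
    EXTENDED_RESIDUES,
    InvalidEntryError,
    ParseReport,
    PhosphoSite,
    ProteinEntry,
)

log = logging.getLogger(__name__)

_KIND_BY_TOKEN = {"Phosphoserine": "phosphoserine",
                  "Phosphotyrosine": "phosphotyrosine"}


def _split_records(stream: TextIO) -> list[str]:
    """Split a flat-text stream into records terminated by '//'."""
    records, current = [], []
    for line in stream:
        if line.rstrip() == "//":
            records.append("".join(current) + "//\n")
            current = []
        else:
            current.append(line)
    if any(line.strip() for line in current):
        records.append("".join(current))  # trailing record missing its '//'
    return records


def _phosphosites_from_features(record, sequence: str,
                                label: str, report: ParseReport) -> list[PhosphoSite]:
    sites: list[PhosphoSite] = []
    for feat in record.features:
        if feat.type != "MOD_RES":
            continue
        # isoform-scoped features (e.g. "P37840-2:62") and uncertain
        # locations are skipped; only canonical-sequence sites are scanned
        try:
            position = int(feat.location.end)
        except (TypeError, ValueError):
            continue
        if getattr(feat, "id", None) and ":" in str(feat.id):
            continue
        note = feat.qualifiers.get("note", "")
        # match on the leading token: "Phosphoserine; by PLK3" still counts
        token = re.split(r"[;.]", note, 1)[0].strip()
        kind = _KIND_BY_TOKEN.get(token)
        if kind is None:
            continue
        if position > len(sequence):
            raise InvalidEntryError(
                f"{label}: MOD_RES position {position} beyond sequence "
                f"length {len(sequence)}"
            )
        expected = "S" if kind == "phosphoserine" else "Y"
        actual = sequence[position - 1]
        if actual != expected:
            msg = (f"{label}: {kind} at {position} sits on {actual!r}, "
                   f"expected {expected!r}; site dropped")
            log.warning(msg)
            report.warnings.append(msg)
            continue
        sites.append(PhosphoSite(position, expected, kind))
    # duplicate annotations at one position collapse to a single site
    unique: dict[int, PhosphoSite] = {}
    for s in sites:
        unique.setdefault(s.position, s)
    return [unique[p] for p in sorted(unique)]


def _strip_evidence(phrase: str) -> str:
    """Remove evidence tags (text in braces/brackets) from a phrase."""
    phrase = re.sub(r"\{[^}]*\}", "", phrase)
    phrase = re.sub(r"\[[^]]*\]", "", phrase)
    return re.sub(r"\s+", " ", phrase).strip()


def parse_subcellular_locations(entry_text: str) -> list[str]:
    """Location phrases from the ``CC -!- SUBCELLULAR LOCATION:`` paragraph.

    Phrases are split on semicolons and periods and returned verbatim with
    evidence tags stripped; absence of the paragraph yields an empty list.
    """
    paragraphs = re.findall(
        r"^CC   -!- SUBCELLULAR LOCATION:(.*?)(?=^CC   -!-|^[^C]|\Z)",
        entry_text, flags=re.S | re.M,
    )
    phrases: list[str] = []
    for para in paragraphs:
        text = " ".join(
            line.replace("CC   ", "", 1).strip()
            for line in para.splitlines()
        )
        for raw in re.split(r"[;.]", text):
            cleaned = _strip_evidence(raw)
            if cleaned and not cleaned.lower().startswith("note="):
                phrases.append(cleaned)
    return phrases


def _parse_one(text: str, report: ParseReport) -> ProteinEntry:
    record = SwissProt.read(io.StringIO(text))
    label = record.entry_name or "<unnamed>"
    sequence = re.sub(r"[\s\d]", "", record.sequence).upper()
    declared_length, mw_da, _crc = record.seqinfo
    if len(sequence) != declared_length:
        raise InvalidEntryError(
            f"{label}: sequence length {len(sequence)} disagrees with "
            f"SQ header ({declared_length})"
        )
    taxon = int(record.taxonomy_id[0]) if record.taxonomy_id else 0
    gene = ""
    if record.gene_name:
        first = record.gene_name[0]
        if isinstance(first, dict):
            gene = first.get("Name", "").split()[0] if first.get("Name") else ""
        else:  # older biopython returns a string
            m = re.search(r"Name=([^;{ ]+)", str(record.gene_name))
            gene = m.group(1) if m else ""
    return ProteinEntry(
        entry_name=record.entry_name,
        accession=record.accessions[0],
        sequence=sequence,
        organism_taxon=taxon,
        mw_da=int(mw_da),
        gene_name=gene,
        secondary_accessions=tuple(record.accessions[1:]),
        phosphosites=tuple(
            _phosphosites_from_features(record, sequence, label, report)
        ),
        locations=tuple(parse_subcellular_locations(text)),
    )


def parse_flatfile(stream: TextIO | str) -> ParseReport:
    """Parse zero or more flat-text entries into the data model.

    Entries from any organism are parsed; taxon filtering is the caller's
    job.  Malformed records are rejected individually with the reason kept
    in the report (count conservation: records == entries + rejected).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    report = ParseReport()
    for i, text in enumerate(_split_records(stream)):
        try:
            if not re.search(r"^ID   ", text, re.M):
                raise InvalidEntryError(f"record {i}: missing ID line")
            if not re.search(r"^SQ   ", text, re.M):
                raise InvalidEntryError(f"record {i}: missing SQ line")
            report.entries.append(_parse_one(text, report))
        except (InvalidEntryError, ValueError, KeyError, IndexError) as exc:
            m = re.search(r"^ID   (\S+)", text, re.M)
            label = m.group(1) if m else f"record {i}"
            log.warning("rejected %s: %s", label, exc)
            report.rejected.append((label, str(exc)))
    return report


def filter_organisms(entries: Iterable[ProteinEntry],
                     taxa: Iterable[int]) -> list[ProteinEntry]:
    """Keep entries whose taxon is in the configured set (default 9606+10090)."""
    taxa = set(taxa)
    return [e for e in entries if e.organism_taxon in taxa]


_ORGANISM_NAMES = {9606: "Homo sapiens (Human)", 10090: "Mus musculus (Mouse)"}


def write_fixture_entry(entry: ProteinEntry) -> str:
    """Emit a minimal, standard-conformant flat-text record.

    ``parse_flatfile`` of the output reproduces the input exactly (the
    round-trip contract the fixture generator and tests rely on).
    """
    if not isinstance(entry, ProteinEntry):
        raise InvalidEntryError("write_fixture_entry requires a ProteinEntry")
    lines = [
        f"ID   {entry.entry_name:<24}Reviewed;{len(entry.sequence):>12} AA.",
        "AC   " + " ".join(f"{a};" for a in entry.all_accessions),
        "DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.",
        f"DE   RecName: Full={entry.entry_name};",
    ]
    if entry.gene_name:
        lines.append(f"GN   Name={entry.gene_name};")
    organism = _ORGANISM_NAMES.get(entry.organism_taxon,
                                   f"Taxon {entry.organism_taxon}")
    lines.append(f"OS   {organism}.")
    lines.append(f"OX   NCBI_TaxID={entry.organism_taxon};")
    if entry.locations:
        lines.append("CC   -!- SUBCELLULAR LOCATION: "
                     + " ".join(f"{loc}." for loc in entry.locations))
    for site in entry.phosphosites:
        lines.append(f"FT   MOD_RES         {site.position}")
        lines.append(f'FT                   /note="{site.kind.capitalize()}"')
    lines.append(
        f"SQ   SEQUENCE   {len(entry.sequence)} AA;  {entry.mw_da} MW;  "
        "0000000000000000 CRC64;"
    )
    for i in range(0, len(entry.sequence), 60):
        chunk = entry.sequence[i : i + 60]
        lines.append("     " + " ".join(chunk[j : j + 10]
                                        for j in range(0, len(chunk), 10)))
    lines.append("//")
    return "\n".join(lines) + "\n"


def write_fixture_proteome(entries: Iterable[ProteinEntry]) -> str:
    return "".join(write_fixture_entry(e) for e in entries)


def load_fasta_sites(fasta: TextIO | str, sites_tsv: TextIO | str) -> ParseReport:
    """Alternative input path: FASTA sequences plus a TSV site table.

    The TSV needs columns ``accession``, ``position``, ``kind``; FASTA
    headers may carry ``gene=``, ``taxon=`` and ``name=`` key=value tokens
    after the accession.  Molecular weight is computed from the sequence.
    """
    from Bio.SeqUtils import molecular_weight

    report = ParseReport()
    table = pd.read_csv(sites_tsv, sep="\t", comment="#")
    required = {"accession", "position", "kind"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidEntryError(f"site table missing columns: {sorted(missing)}")
    by_acc: dict[str, list[PhosphoSite]] = {}
    for row in table.itertuples():
        kind = str(row.kind).strip().lower()
        residue = {"phosphoserine": "S", "phosphotyrosine": "Y"}.get(kind)
        if residue is None:
            report.warnings.append(
                f"{row.accession}: unsupported modification {row.kind!r}; skipped"
            )
            continue
        by_acc.setdefault(str(row.accession), []).append(
            PhosphoSite(int(row.position), residue, kind)
        )
    for rec in SeqIO.parse(fasta, "fasta"):
        fields = dict(t.split("=", 1) for t in rec.description.split()[1:] if "=" in t)
        sequence = str(rec.seq).upper()
        try:
            if set(sequence) - EXTENDED_RESIDUES:
                raise InvalidEntryError(f"{rec.id}: non-amino-acid characters")
            sites = sorted(by_acc.get(rec.id, []), key=lambda s: s.position)
            report.entries.append(ProteinEntry(
                entry_name=fields.get("name", rec.id),
                accession=rec.id,
                sequence=sequence,
                organism_taxon=int(fields.get("taxon", 0)),
                mw_da=round(molecular_weight(sequence.replace("X", "A")
                                             .replace("B", "N").replace("Z", "Q")
                                             .replace("U", "C").replace("O", "K"),
                                             "protein")),
                gene_name=fields.get("gene", ""),
                phosphosites=tuple(sites),
            ))
        except InvalidEntryError as exc:
            report.rejected.append((rec.id, str(exc)))
    return report
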