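"""Protein sequence I/O: FASTA reading/writing, record filtering,
deduplication and background amino-acid composition.

The census pipeline starts from a proteome in FASTA.  Records are
carried as lightweight :class:`ProteinRecord` objects; UniProt-style
``db|ACC|NAME`` headers are unwrapped so the accession becomes the
record id.  Background residue frequencies are the denominator of the
X1 enrichment analysis, so ambiguity codes (B, J, O, U, X, Z) are kept
in the sequences but excluded from the composition counts.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated non-canonical / ambiguity codes.  They never satisfy a
#: pattern position and never enter composition counts.
AMBIGUOUS_AA: str = "BJOUXZ"

#: Description substrings that mark partial entries, removed before the
#: census by default.
DEFAULT_EXCLUDE_WORDS: tuple[str, ...] = ("(Fragment)", "Truncated")


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier and description.

    Parameters
    ----------
    id : str
        Accession; for UniProt ``db|ACC|NAME`` headers this is ``ACC``.
    description : str
        Remainder of the header line after the first token.
    sequence : str
        Uppercase amino-acid string, gaps and stop symbols stripped.
    species : str or None
        Optional taxon label used by the cross-species table.
    """

    id: str
    description: str = ""
    sequence: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"record {self.id!r}: whitespace in sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_species(self, species: str | None) -> "ProteinRecord":
        return replace(self, species=species)


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Residue composition of a sequence set.

    ``freq`` maps each canonical residue to its fraction among counted
    residues; fractions sum to 1.  ``counted_residues`` is the number of
    canonical residues that entered the count (ambiguity codes are
    excluded from numerator and denominator).
    """

    freq: Mapping[str, float]
    counted_residues: int

    def __getitem__(self, residue: str) -> float:
        return self.freq.get(residue, 0.0)

    @property
    def f_g(self) -> float:
        """Glycine background fraction (used by the expected G-motif CDF)."""
        return self.freq.get("G", 0.0)


def _unwrap_uniprot_id(token: str) -> str:
    # "sp|P20930|FILA_HUMAN" -> "P20930"; plain tokens pass through.
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def _clean_sequence(seq: str) -> str:
    return seq.upper().replace("-", "").replace(".", "").replace("*", "")


def read_fasta(path: str | Path | _io.TextIOBase) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    The first header token becomes the id (UniProt ``db|ACC|NAME``
    unwrapped to ``ACC``), the remainder the description.  Sequences are
    uppercased with gap/stop symbols removed.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header; the message names
        the offending line number.
    """
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle, close = path, False
    try:
        first = handle.readline()
        lineno = 1
        while first and not first.strip():
            first = handle.readline()
            lineno += 1
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"line {lineno}: sequence data before first FASTA header"
            )
        if not first:
            warnings.warn("empty FASTA input: no records", stacklevel=2)
            return []
        stream = _io.StringIO(first + handle.read())
    finally:
        if close:
            handle.close()

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(stream, "fasta"):
        header = rec.description
        token, _, rest = header.partition(" ")
        records.append(
            ProteinRecord(
                id=_unwrap_uniprot_id(token),
                description=rest.strip(),
                sequence=_clean_sequence(str(rec.seq)),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, one wrapped entry per record."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def filter_records(
    records: Sequence[ProteinRecord],
    exclude_words: Sequence[str] = DEFAULT_EXCLUDE_WORDS,
) -> list[ProteinRecord]:
    """Drop records whose description contains any exclude word.

    Matching is case-sensitive substring, so the default words remove
    entries flagged as "(Fragment)" or "Truncated" without touching
    e.g. "fragment" in lowercase.  Idempotent.
    """
    kept = [
        r for r in records if not any(w in r.description for w in exclude_words)
    ]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_records: removed %d of %d records", removed, len(records))
    return kept


def dedupe(
    records: Sequence[ProteinRecord],
    representatives: Iterable[str] | None = None,
) -> list[ProteinRecord]:
    """Collapse exact-duplicate sequences, keeping the first-seen record.

    ``representatives`` optionally supplies a precomputed list of
    representative ids (e.g. from an external similarity-clustering run);
    when given, exactly those records are kept, in input order.
    """
    if representatives is not None:
        want = set(representatives)
        return [r for r in records if r.id in want]
    seen: set[str] = set()
    out: list[ProteinRecord] = []
    for r in records:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    if len(out) < len(records):
        logger.info("dedupe: %d -> %d records", len(records), len(out))
    return out


def aa_frequencies(records: Sequence[ProteinRecord]) -> BackgroundFrequencies:
    """Background composition over the concatenated sequences.

    Only the 20 canonical residues are counted; ambiguity codes are
    excluded from both numerator and denominator.

    Raises
    ------
    ValueError
        On empty input or when no canonical residue occurs at all.
    """
    if not records:
        raise ValueError("aa_frequencies: no records")
    counts = {aa: 0 for aa in CANONICAL_AA}
    for rec in records:
        for c in rec.sequence:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("aa_frequencies: no canonical residues in input")
    return BackgroundFrequencies(
        freq={aa: n / total for aa, n in counts.items()},
        counted_residues=total,
    )


def frequencies_table(bg: BackgroundFrequencies):
    """Background composition as a DataFrame (residue, count, fraction)."""
    import pandas as pd

    rows = [
        {
            "residue": aa,
            "count": round(bg.freq[aa] * bg.counted_residues),
            "fraction": bg.freq[aa],
        }
        for aa in CANONICAL_AA
    ]
    return pd.DataFrame(rows)
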