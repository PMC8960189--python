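"""PROSITE-style motif patterns, sequence scanning and overlap merging.

The Ni-hydrolytic motif is the six-residue window X1-[ST]-{CP}-H-{C}-X2:
a serine or threonine whose preceding peptide bond is cleaved, followed
by any residue except Cys/Pro, a histidine (the Ni2+ anchor), any
residue except Cys, flanked by arbitrary residues.  The "fast" G-motif
restricts X1 to glycine.  Overlapping windows are biologically one
cleavage region and are merged into a single hit.

Only the pattern subset needed for these motifs is supported: single
residues, ``x`` (any), ``[..]`` allowed classes and ``{..}`` forbidden
classes, dash-separated.  Repetition counts and anchors are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .io import AMBIGUOUS_AA, CANONICAL_AA, ProteinRecord

#: The general Ni-hydrolytic motif searched across the proteome.
X_PATTERN_TEXT = "x-[ST]-{CP}-H-{C}-x"
#: The fast (glycine) variant.
G_PATTERN_TEXT = "G-[ST]-{CP}-H-{C}-x"


class PatternSyntaxError(ValueError):
    """Unsupported or malformed pattern element."""


class _Kind(Enum):
    ANY = "any"
    ALLOWED = "allowed"
    FORBIDDEN = "forbidden"


@dataclass(frozen=True)
class _Position:
    kind: _Kind
    residues: frozenset[str] = frozenset()

    def matches(self, residue: str, ambiguous_as_any: bool = False) -> bool:
        if residue in AMBIGUOUS_AA or residue not in CANONICAL_AA:
            # A residue of unknown identity cannot be certified to satisfy
            # any constraint, including "not C"; optionally let it pass
            # everywhere except explicit allowed classes.
            return ambiguous_as_any and self.kind is not _Kind.ALLOWED
        if self.kind is _Kind.ANY:
            return True
        if self.kind is _Kind.ALLOWED:
            return residue in self.residues
        return residue not in self.residues


@dataclass(frozen=True)
class MotifPattern:
    """A parsed fixed-length pattern: one constraint per position."""

    positions: tuple[_Position, ...]
    label: str = ""
    text: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)


def parse_pattern(text: str, label: str = "") -> MotifPattern:
    """Parse a dash-separated pattern string into a :class:`MotifPattern`.

    >>> p = parse_pattern("x-[ST]-{CP}-H-{C}-x")
    >>> p.length
    6
    """
    if not text.strip():
        raise PatternSyntaxError("empty pattern")
    positions: list[_Position] = []
    for element in text.strip().split("-"):
        el = element.strip()
        if not el:
            raise PatternSyntaxError(f"empty element in pattern {text!r}")
        if "(" in el or ")" in el:
            raise PatternSyntaxError(f"repetition not supported: {el!r}")
        if el in ("<", ">") or el.startswith("<") or el.endswith(">"):
            raise PatternSyntaxError(f"anchors not supported: {el!r}")
        if el == "x":
            positions.append(_Position(_Kind.ANY))
        elif el.startswith("[") and el.endswith("]"):
            body = el[1:-1]
            if not body or any(c not in CANONICAL_AA for c in body):
                raise PatternSyntaxError(f"bad allowed class: {el!r}")
            positions.append(_Position(_Kind.ALLOWED, frozenset(body)))
        elif el.startswith("{") and el.endswith("}"):
            body = el[1:-1]
            if not body or any(c not in CANONICAL_AA for c in body):
                raise PatternSyntaxError(f"bad forbidden class: {el!r}")
            positions.append(_Position(_Kind.FORBIDDEN, frozenset(body)))
        elif len(el) == 1 and el in CANONICAL_AA:
            positions.append(_Position(_Kind.ALLOWED, frozenset(el)))
        else:
            raise PatternSyntaxError(f"unknown pattern element: {el!r}")
    return MotifPattern(tuple(positions), label=label, text=text.strip())


#: Parsed default patterns.
X_PATTERN = parse_pattern(X_PATTERN_TEXT, label="X-motif")
G_PATTERN = parse_pattern(G_PATTERN_TEXT, label="G-motif")


@dataclass(frozen=True)
class MotifHit:
    """One merged motif occurrence.

    Coordinates are 1-based inclusive.  ``window_starts`` lists the raw
    pattern-window start positions collapsed into this hit; residue
    annotations (``x1_residue``, ``st_residue``) come from the first
    window of the chain.
    """

    protein_id: str
    start: int
    end: int
    st_residue: str
    x1_residue: str
    window_starts: tuple[int, ...]
    label: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


def scan(
    sequence: str,
    pattern: MotifPattern,
    ambiguous_as_any: bool = False,
) -> list[int]:
    """All raw window start positions (1-based) matching the pattern."""
    L = pattern.length
    seq = sequence.upper()
    n = len(seq)
    starts: list[int] = []
    for s in range(n - L + 1):
        if all(
            pattern.positions[i].matches(seq[s + i], ambiguous_as_any)
            for i in range(L)
        ):
            starts.append(s + 1)
    return starts


def merge_overlaps(
    starts: Sequence[int],
    pattern_length: int,
    sequence: str = "",
    protein_id: str = "",
    label: str = "",
    mode: str = "chain",
) -> list[MotifHit]:
    """Collapse overlapping pattern windows into merged hits.

    ``mode="chain"`` (default) merges transitively any windows sharing
    at least one residue; ``mode="share_st"`` merges only windows whose
    S/T position (window start + 1) coincides.
    """
    if mode not in ("chain", "share_st"):
        raise ValueError(f"unknown merge mode {mode!r}")
    ordered = sorted(starts)
    hits: list[MotifHit] = []
    i = 0
    while i < len(ordered):
        chain = [ordered[i]]
        j = i + 1
        while j < len(ordered):
            nxt = ordered[j]
            if mode == "chain":
                joined = nxt <= chain[-1] + pattern_length - 1
            else:
                joined = nxt + 1 == chain[-1] + 1  # identical S/T position
            if joined:
                chain.append(nxt)
                j += 1
            else:
                break
        first = chain[0]
        end = chain[-1] + pattern_length - 1
        x1 = sequence[first - 1] if sequence else "?"
        st = sequence[first] if sequence else "?"
        hits.append(
            MotifHit(
                protein_id=protein_id,
                start=first,
                end=end,
                st_residue=st,
                x1_residue=x1,
                window_starts=tuple(chain),
                label=label,
            )
        )
        i = j
    return hits


def find_motifs(
    record: ProteinRecord,
    pattern: MotifPattern,
    ambiguous_as_any: bool = False,
    merge_mode: str = "chain",
) -> list[MotifHit]:
    """Scan one record and return merged hits."""
    raw = scan(record.sequence, pattern, ambiguous_as_any)
    return merge_overlaps(
        raw,
        pattern.length,
        sequence=record.sequence,
        protein_id=record.id,
        label=pattern.label,
        mode=merge_mode,
    )


def motif_density(n_motifs: int, seq_length: int) -> float:
    """Merged motif count per 100 residues: ``n * 100 / length``."""
    if seq_length <= 0:
        raise ValueError("sequence length must be positive")
    return n_motifs * 100.0 / seq_length


def count_motifs(
    record: ProteinRecord,
    x_pattern: MotifPattern = X_PATTERN,
    g_pattern: MotifPattern = G_PATTERN,
    ambiguous_as_any: bool = False,
    merge_mode: str = "chain",
) -> dict:
    """Census row for one protein: merged X- and G-motif counts and densities."""
    x_hits = find_motifs(record, x_pattern, ambiguous_as_any, merge_mode)
    g_hits = find_motifs(record, g_pattern, ambiguous_as_any, merge_mode)
    n = len(record.sequence)
    return {
        "protein_id": record.id,
        "length": n,
        "n_x_motifs": len(x_hits),
        "n_g_motifs": len(g_hits),
        "density_x": motif_density(len(x_hits), n),
        "density_g": motif_density(len(g_hits), n),
        "x_hits": x_hits,
        "g_hits": g_hits,
    }


class MotifScanner(BaseEstimator, TransformerMixin):
    """Proteome motif census as a scikit-learn style transformer.

    ``transform`` maps an iterable of :class:`ProteinRecord` to the
    per-protein census DataFrame; ``fit`` is stateless and records the
    parsed patterns.

    Parameters
    ----------
    x_pattern, g_pattern : str
        Pattern strings in the supported syntax.
    ambiguous_as_any : bool
        Let ambiguity codes satisfy non-allowed-class positions.
    merge_mode : {"chain", "share_st"}
        Overlap-merging rule.
    """

    def __init__(
        self,
        x_pattern: str = X_PATTERN_TEXT,
        g_pattern: str = G_PATTERN_TEXT,
        ambiguous_as_any: bool = False,
        merge_mode: str = "chain",
    ):
        self.x_pattern = x_pattern
        self.g_pattern = g_pattern
        self.ambiguous_as_any = ambiguous_as_any
        self.merge_mode = merge_mode

    def fit(self, X: Iterable[ProteinRecord] | None = None, y=None):
        self.x_pattern_ = parse_pattern(self.x_pattern, label="X-motif")
        self.g_pattern_ = parse_pattern(self.g_pattern, label="G-motif")
        return self

    def transform(self, X: Iterable[ProteinRecord]):
        """Per-protein census table; hits retrievable via :meth:`hits`."""
        import pandas as pd

        if not hasattr(self, "x_pattern_"):
            self.fit()
        rows = []
        hits: list[MotifHit] = []
        for rec in X:
            row = count_motifs(
                rec,
                self.x_pattern_,
                self.g_pattern_,
                self.ambiguous_as_any,
                self.merge_mode,
            )
            hits.extend(row.pop("x_hits"))
            hits.extend(row.pop("g_hits"))
            rows.append(row)
        self.hits_ = hits
        cols = [
            "protein_id",
            "length",
            "n_x_motifs",
            "n_g_motifs",
            "density_x",
            "density_g",
        ]
        return pd.DataFrame(rows, columns=cols)

    def hits(self, label: str | None = None) -> list[MotifHit]:
        """Merged hits from the last :meth:`transform` call."""
        if not hasattr(self, "hits_"):
            raise AttributeError("transform() has not been called")
        if label is None:
            return list(self.hits_)
        return [h for h in self.hits_ if h.label == label]


def hits_table(hits: Sequence[MotifHit]):
    """Hit list as a BED-like DataFrame (1-based inclusive coordinates)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "start": h.start,
                "end": h.end,
                "label": h.label,
                "x1_residue": h.x1_residue,
                "st_residue": h.st_residue,
                "n_windows": h.n_windows,
            }
            for h in hits
        ],
        columns=[
            "protein_id",
            "start",
            "end",
            "label",
            "x1_residue",
            "st_residue",
            "n_windows",
        ],
    )
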