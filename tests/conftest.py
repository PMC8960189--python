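import re

import numpy as np
import pytest

from nimotif.io import CANONICAL_AA, ProteinRecord

# ---------------------------------------------------------------------------
# Independent scanning oracle: a regex lookahead over explicit residue
# classes plus an interval-union merge.  Deliberately shares no code with
# the package's position-constraint scanner.

_ANY = CANONICAL_AA
_NOT_CP = "".join(c for c in CANONICAL_AA if c not in "CP")
_NOT_C = "".join(c for c in CANONICAL_AA if c != "C")

ORACLE_X_RE = re.compile(f"(?=([{_ANY}][ST][{_NOT_CP}]H[{_NOT_C}][{_ANY}]))")
ORACLE_G_RE = re.compile(f"(?=(G[ST][{_NOT_CP}]H[{_NOT_C}][{_ANY}]))")


def oracle_scan(sequence: str, regex: re.Pattern) -> list[int]:
    """Raw 1-based window starts by regex lookahead."""
    return [m.start() + 1 for m in regex.finditer(sequence)]


def oracle_merge(starts: list[int], length: int = 6) -> list[tuple[int, int]]:
    """Union of [start, start+L-1] intervals sharing >= 1 residue."""
    spans = []
    for s in sorted(starts):
        lo, hi = s, s + length - 1
        if spans and lo <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
        else:
            spans.append((lo, hi))
    return spans


@pytest.fixture
def rng():
    return np.random.default_rng(20220310)


@pytest.fixture
def random_sequences(rng):
    """Random canonical sequences of length <= 200, motif-rich alphabet."""
    def make(n, max_len=200, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        alphabet = np.array(list(CANONICAL_AA))
        # bias towards S/T/H/G so motifs actually occur
        w = np.ones(len(alphabet))
        for aa, boost in (("S", 5), ("T", 5), ("H", 8), ("G", 5)):
            w[list(CANONICAL_AA).index(aa)] = boost
        w /= w.sum()
        out = []
        for _ in range(n):
            L = int(r.integers(6, max_len + 1))
            out.append("".join(r.choice(alphabet, size=L, p=w)))
        return out
    return make


@pytest.fixture
def small_records():
    return [
        ProteinRecord("P1", "Filaggrin", "GSAHAGMMMM"),
        ProteinRecord("P2", "Keratin (Fragment)", "ASAHAG"),
        ProteinRecord("P3", "Truncated hemoglobin", "AAAAAA"),
        ProteinRecord("P4", "Copy of P1", "GSAHAGMMMM"),
    ]
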