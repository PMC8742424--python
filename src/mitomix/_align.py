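"""Shared low-level sequence/alignment helpers.

Sequences are handled as uppercase ASCII strings externally and as uint8
numpy arrays internally.  Banded edit-distance alignment is delegated to
edlib; its ``k`` parameter is what this package calls the *band*: it bounds
both the explored diagonals and the accepted edit distance.
"""

from __future__ import annotations

import re

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

N_BYTE = ord("N")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array (no copy of semantics, cheap compare)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse an extended CIGAR string into (length, op) pairs."""
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_to_gapped(query: str, target: str, cigar: str) -> tuple[str, str]:
    """Expand a query-vs-target CIGAR into two equal-length gapped strings.

    Follows the SAM convention used by edlib: ``I`` consumes query only,
    ``D`` consumes target only, ``=``/``X``/``M`` consume both.
    """
    out_q: list[str] = []
    out_t: list[str] = []
    qi = ti = 0
    for n, op in parse_cigar(cigar):
        if op in "=XM":
            out_q.append(query[qi : qi + n])
            out_t.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":
            out_q.append(query[qi : qi + n])
            out_t.append("-" * n)
            qi += n
        elif op == "D":
            out_q.append("-" * n)
            out_t.append(target[ti : ti + n])
            ti += n
    if qi != len(query) or ti != len(target):
        raise ValueError("CIGAR does not span both sequences")
    return "".join(out_q), "".join(out_t)


def best_ungapped_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment under +1 match / -1 mismatch.

    ``match`` is a boolean array over alignment columns.  Returns
    ``(start, end, n_matches)`` for the best segment (end exclusive); the
    empty segment (0, 0, 0) is returned when every column mismatches.
    Ties resolve to the earliest end, then earliest start.
    """
    score = np.where(match, 1, -1).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(score)))
    runmin = np.minimum.accumulate(cs)
    gains = cs - runmin
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return 0, 0, 0
    start = int(np.argmax(cs[: end + 1] == runmin[end]))
    span = end - start
    n_match = (span + int(gains[end])) // 2
    return start, end, n_match
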