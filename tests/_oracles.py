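"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results with different algorithms from the
package: exhaustive all-diagonal scans instead of k-mer seeding, and plain
dynamic-programming edit distance instead of edlib, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_segment_scan(match_rows: np.ndarray) -> list[tuple[int, int, int]]:
    """Per-row maximum-scoring (+1/-1) segment: (start, end, n_matches)."""
    score = np.where(match_rows, 1, -1).astype(np.int64)
    cs = np.concatenate(
        [np.zeros((score.shape[0], 1), dtype=np.int64), np.cumsum(score, axis=1)], axis=1
    )
    runmin = np.minimum.accumulate(cs, axis=1)
    gains = cs - runmin
    out = []
    for row in range(score.shape[0]):
        end = int(np.argmax(gains[row]))
        if gains[row, end] <= 0:
            out.append((0, 0, 0))
            continue
        start = int(np.argmax(cs[row, : end + 1] == runmin[row, end]))
        span = end - start
        out.append((start, end, (span + int(gains[row, end])) // 2))
    return out


def exhaustive_ungapped_hit(
    read_seq: str,
    genomes: dict[str, str],
    circular: bool,
    min_identity: float,
    min_span: int,
) -> tuple[str, float, int] | None:
    """Best ungapped hit over every diagonal of every genome, both strands.

    Returns (species_id, identity, span) of the highest-identity passing
    segment (ties to lexicographically smaller species), or None.
    """
    best = None
    rl = len(read_seq)
    for species in sorted(genomes):
        seq = genomes[species]
        target = seq + seq if circular else seq
        n_offsets = len(seq) if circular else max(len(seq) - rl + 1, 0)
        if n_offsets == 0 or len(target) < rl:
            continue
        windows = sliding_window_view(_enc(target), rl)[:n_offsets]
        for oriented in (read_seq, revcomp(read_seq)):
            arr = _enc(oriented)
            match = (windows == arr[None, :]) & (windows != ord("N")) & (arr[None, :] != ord("N"))
            for start, end, n_match in _best_segment_scan(match):
                span = end - start
                if span < min_span:
                    continue
                identity = n_match / span
                if identity < min_identity:
                    continue
                if best is None or identity > best[1]:
                    best = (species, identity, span)
    return best


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Edit distance of query aligned end-to-end inside target (free target
    ends), by row-wise dynamic programming with a prefix-min transform for
    the in-row insertion dependency."""
    q = _enc(query)
    t = _enc(target)
    n = t.size
    idx = np.arange(n + 1, dtype=np.int64)
    row = np.zeros(n + 1, dtype=np.int64)
    for i in range(1, q.size + 1):
        sub = (t != q[i - 1]).astype(np.int64)
        tmp = np.empty(n + 1, dtype=np.int64)
        tmp[0] = i
        tmp[1:] = np.minimum(row[:-1] + sub, row[1:] + 1)
        row = idx + np.minimum.accumulate(tmp - idx)
    return int(row.min())


def global_edit_distance(a: str, b: str) -> int:
    """Plain Needleman-Wunsch unit-cost edit distance."""
    x = _enc(a)
    y = _enc(b)
    n = y.size
    idx = np.arange(n + 1, dtype=np.int64)
    row = idx.copy()
    for i in range(1, x.size + 1):
        sub = (y != x[i - 1]).astype(np.int64)
        tmp = np.empty(n + 1, dtype=np.int64)
        tmp[0] = i
        tmp[1:] = np.minimum(row[:-1] + sub, row[1:] + 1)
        row = idx + np.minimum.accumulate(tmp - idx)
    return int(row[-1])


def oracle_mapped(
    read_seq: str, assembly: str, circular: bool, max_edit_frac: float = 0.1
) -> bool:
    """Mapper acceptance re-derived with the DP oracle."""
    target = assembly * 2 if circular else assembly
    threshold = int(np.floor(max_edit_frac * len(read_seq)))
    return (
        semiglobal_edit_distance(read_seq, target) <= threshold
        or semiglobal_edit_distance(revcomp(read_seq), target) <= threshold
    )
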