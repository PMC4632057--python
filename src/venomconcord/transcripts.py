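"""Transcript abundance estimation with the study's QC filters.

Coding sequences are clustered at <1% pairwise divergence (alleles, recent
paralogs, and assembly-error contigs collapse to one representative), read
counts become TPM, and two filters remove transcripts whose abundance cannot
be trusted: non-uniform coverage (CV across sites > 1) and a >=10-fold
disagreement between two independent estimation methods.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import CoverageProfile, TranscriptRecord

__all__ = [
    "pairwise_divergence",
    "cluster_transcripts",
    "tpm",
    "coverage_cv_filter",
    "cross_method_filter",
]

_GAP = -2
_MATCH = 1
_MISMATCH = -1


def _nw_counts(a: str, b: str) -> tuple[int, int, int]:
    """Global alignment (match +1, mismatch -1, gap -2); returns
    (mismatch columns, gap columns, alignment length) for one optimal
    alignment with a canonical diagonal > up > left traceback."""
    la, lb = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    M = np.empty((la + 1, lb + 1), dtype=np.int32)
    M[0, :] = _GAP * np.arange(lb + 1)
    M[:, 0] = _GAP * np.arange(la + 1)
    j2 = 2 * np.arange(1, lb + 1)
    for i in range(1, la + 1):
        sub = np.where(bv == av[i - 1], _MATCH, _MISMATCH)
        cand = np.maximum(M[i - 1, :-1] + sub, M[i - 1, 1:] + _GAP)
        # left-gap recursion M[i,j] = max(cand[j], M[i,j-1]-2) as a prefix max
        arr = np.empty(lb + 1, dtype=np.int32)
        arr[0] = M[i, 0]
        arr[1:] = cand + j2
        M[i, 1:] = np.maximum.accumulate(arr)[1:] - j2
    mism = gaps = length = 0
    i, j = la, lb
    while i > 0 and j > 0:
        s = _MATCH if av[i - 1] == bv[j - 1] else _MISMATCH
        if M[i, j] == M[i - 1, j - 1] + s:
            mism += s == _MISMATCH
            i -= 1
            j -= 1
        elif M[i, j] == M[i - 1, j] + _GAP:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
        length += 1
    gaps += i + j
    length += i + j
    return mism, gaps, length


def pairwise_divergence(a: str, b: str) -> float:
    """Fraction of mismatched plus gapped columns in a global alignment.

    Symmetric and in [0, 1]; 0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 0.0
    if (len(b), b) < (len(a), a):  # canonical order makes the result symmetric
        a, b = b, a
    mism, gaps, length = _nw_counts(a, b)
    return (mism + gaps) / length


def cluster_transcripts(
    records: Sequence[TranscriptRecord],
    abundances: Mapping[str, float],
    threshold: float = 0.01,
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage clusters at divergence < threshold, one representative each.

    The representative is the highest-abundance member (ties broken by the
    lexicographically smallest id). Output is invariant to input order.
    """
    recs = sorted(records, key=lambda r: r.id)
    for r in recs:
        if r.id not in abundances:
            raise ValueError(f"no abundance for transcript {r.id!r}")
    n = len(recs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = recs[i].cds, recs[j].cds
            la, lb = len(a), len(b)
            if abs(la - lb) / (la + lb) >= threshold:
                continue  # gap columns alone force divergence >= threshold
            if pairwise_divergence(a, b) < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters: list[list[str]] = []
    representatives: list[str] = []
    for root in sorted(groups):
        member_ids = [recs[i].id for i in groups[root]]
        clusters.append(member_ids)
        representatives.append(
            min(member_ids, key=lambda mid: (-abundances[mid], mid))
        )
    return clusters, representatives


def tpm(counts: Mapping[str, float], lengths: Mapping[str, int]) -> dict[str, float]:
    """Transcripts per million from read counts and CDS lengths.

    rate_i = count_i / length_i; TPM_i = 1e6 * rate_i / sum(rate). The output
    sums to 1e6 and is invariant to rescaling all counts by a constant.
    """
    ids = list(counts)
    missing = [i for i in ids if i not in lengths]
    if missing:
        raise ValueError(f"no length for ids: {missing}")
    lens = np.array([lengths[i] for i in ids], dtype=float)
    if (lens <= 0).any():
        raise ValueError("lengths must be positive")
    cnt = np.array([counts[i] for i in ids], dtype=float)
    if (cnt < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = cnt / lens
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    vals = 1e6 * rate / total
    return dict(zip(ids, vals.tolist()))


def _as_depth_map(
    profiles: Iterable[CoverageProfile] | Mapping[str, Sequence[int]],
) -> dict[str, np.ndarray]:
    if isinstance(profiles, Mapping):
        return {k: np.asarray(v, dtype=float) for k, v in profiles.items()}
    return {p.id: np.asarray(p.depth, dtype=float) for p in profiles}


def coverage_cv_filter(
    profiles: Iterable[CoverageProfile] | Mapping[str, Sequence[int]],
    max_cv: float = 1.0,
) -> set[str]:
    """Retain transcripts whose coverage CV across sites is <= max_cv.

    CV uses the sample standard deviation (n-1). Transcripts with zero mean
    depth (CV undefined) are excluded.
    """
    retained: set[str] = set()
    for tid, depth in _as_depth_map(profiles).items():
        if depth.size == 0:
            raise ValueError(f"{tid}: empty coverage profile")
        mean = depth.mean()
        if mean == 0:
            continue
        sd = depth.std(ddof=1) if depth.size > 1 else 0.0
        if sd / mean <= max_cv:
            retained.add(tid)
    return retained


def cross_method_filter(
    est1: Mapping[str, float],
    est2: Mapping[str, float],
    fold: float = 10.0,
) -> set[str]:
    """Retain ids whose relative shares agree within ``fold`` across methods.

    Both estimates are normalized to shares (methods report on different
    scales: raw counts vs TPM). An id is excluded when the share ratio in
    either direction reaches ``fold`` ("10-fold or higher"), or when its share
    is zero in exactly one method. Ids at zero in both methods are retained
    (the methods agree the transcript is absent).
    """
    if set(est1) != set(est2):
        raise ValueError("cross-method comparison requires identical id sets")
    ids = list(est1)
    s1 = np.array([est1[i] for i in ids], dtype=float)
    s2 = np.array([est2[i] for i in ids], dtype=float)
    if s1.sum() == 0 or s2.sum() == 0:
        raise ValueError("an estimate with all-zero values cannot be compared")
    s1 = s1 / s1.sum()
    s2 = s2 / s2.sum()
    retained: set[str] = set()
    for tid, a, b in zip(ids, s1, s2):
        if a == 0 and b == 0:
            retained.add(tid)
        elif a > 0 and b > 0 and max(a / b, b / a) < fold:
            retained.add(tid)
    return retained
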