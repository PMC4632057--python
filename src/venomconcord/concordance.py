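"""Compositional transforms and transcript-proteome concordance statistics.

Both RNA-seq and quantitative MS measure relative, sum-constrained
quantities, so abundance vectors are treated as compositions: normalized to
sum to 1 (closure) and mapped to real space with the centered log-ratio
transform,

    clr(x) = (ln x_1/g(x), ..., ln x_n/g(x)),   g(x) = (x_1 ... x_n)^(1/n).

clr shifts each vector's log values by a constant, so Spearman's rho is
unchanged and Pearson's R equals its value on the log scale; correlations are
nonetheless reported on clr values throughout. Concordance restricts both
layers to the ids quantified in BOTH (zeros never enter the transform) and
re-closes on that shared set.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import ConcordanceResult, DetectionSummary

__all__ = [
    "close",
    "clr",
    "spearman",
    "pearson_with_ci",
    "concordance",
    "detection_threshold_analysis",
]


def close(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a strictly positive vector to a composition summing to 1."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("a composition needs at least 2 components")
    if (x <= 0).any():
        raise ValueError(
            "compositions must be strictly positive: zeros are not representable "
            "on the clr scale"
        )
    return x / x.sum()


def clr(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Centered log-ratio transform of a closed composition."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive components")
    if abs(x.sum() - 1.0) > 1e-8:
        raise ValueError("clr input must be closed (sum to 1)")
    logx = np.log(x)
    return logx - logx.mean()


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman's rank correlation (average ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(a, b).statistic)


def pearson_with_ci(
    a: Sequence[float],
    b: Sequence[float],
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)); degenerate at |r|=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = a.size
    if n < 4:
        raise ValueError("Fisher-z CI needs at least 4 observations")
    r = float(stats.pearsonr(a, b).statistic)
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        return r, (r, r)
    zcrit = float(stats.norm.ppf(1.0 - (1.0 - level) / 2.0))
    z = math.atanh(r)
    half = zcrit / math.sqrt(n - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def _matched_clr(
    x: Mapping[str, float], y: Mapping[str, float], ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    xv = clr(close([x[i] for i in ids]))
    yv = clr(close([y[i] for i in ids]))
    return xv, yv


def concordance(
    tpm: Mapping[str, float],
    fmol: Mapping[str, float],
) -> ConcordanceResult:
    """Transcript-protein concordance over ids quantified in both layers.

    Both vectors are restricted to the shared ids, re-closed, clr-transformed,
    and compared by Spearman's rho and Pearson's R (with 95% Fisher-z CI).
    """
    shared = sorted(set(tpm) & set(fmol))
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 ids quantified in both layers, got {len(shared)}"
        )
    xv, yv = _matched_clr(tpm, fmol, shared)
    rho = spearman(xv, yv)
    r, ci = pearson_with_ci(xv, yv)
    return ConcordanceResult(
        n=len(shared),
        spearman_rho=rho,
        pearson_r=r,
        r_squared=r * r,
        pearson_ci_95=ci,
        matched_ids=tuple(shared),
    )


def detection_threshold_analysis(
    tpm_all: Mapping[str, float],
    detected: Iterable[str],
    k: int | None = None,
    top_fraction: float = 0.25,
) -> DetectionSummary:
    """Test whether proteomically undetected transcripts sit at low abundance.

    A detection threshold predicts that undetected toxins are the weakly
    expressed ones; post-transcriptional silencing would strike transcripts at
    any expression level. Reports the clr abundance of every transcript with
    its detection flag, a one-sided rank-sum (Mann-Whitney) test that
    undetected transcripts have lower abundance, the abundance rank (1 =
    highest) of the most-expressed undetected transcript, and whether the top
    ``k`` transcripts (default: top quartile) were all detected.
    """
    detected = set(detected)
    extra = detected - set(tpm_all)
    if extra:
        raise ValueError(f"detected ids not in abundance vector: {sorted(extra)}")
    ids = sorted(tpm_all)
    vals = clr(close([tpm_all[i] for i in ids]))
    clr_map = dict(zip(ids, vals.tolist()))
    flags = {i: i in detected for i in ids}

    by_abundance = sorted(ids, key=lambda i: -clr_map[i])
    n = len(ids)
    if k is None:
        k = max(1, math.ceil(top_fraction * n))
    all_top_k = all(flags[i] for i in by_abundance[:k])

    undet = [clr_map[i] for i in ids if not flags[i]]
    det = [clr_map[i] for i in ids if flags[i]]
    if undet and det:
        ties = len(set(undet + det)) < len(undet) + len(det)
        method = "exact" if (max(len(undet), len(det)) < 20 and not ties) else "asymptotic"
        p = float(
            stats.mannwhitneyu(undet, det, alternative="less", method=method).pvalue
        )
        rank_top_undet = 1 + min(
            by_abundance.index(i) for i in ids if not flags[i]
        )
    else:
        p = None
        rank_top_undet = None

    return DetectionSummary(
        clr_abundance=clr_map,
        detected_flags=flags,
        n_detected=len(det),
        n_undetected=len(undet),
        rank_sum_p=p,
        rank_most_expressed_undetected=rank_top_undet,
        all_top_k_detected=all_top_k,
        k=k,
    )
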