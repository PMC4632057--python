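"""Protein-level buffering test between two taxa.

If post-transcriptional regulation damps transcriptional divergence, protein
abundances of orthologous toxins should be more similar between taxa than
their transcript abundances. Orthologs are matched by reciprocal best hits
under local protein alignment, each abundance layer is clr-transformed over
the matched pairs, and the two cross-taxon Pearson correlations are compared
with the CI-mutual-exclusion rule: buffering is called only when each R lies
outside the other's 95% confidence interval AND the protein-level R exceeds
the transcript-level R. A two-sample Fisher-z comparison is reported as a
secondary statistic.
"""
from __future__ import annotations

import math
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .concordance import _matched_clr, pearson_with_ci
from .types import BufferingResult, OrthologMap

__all__ = [
    "make_aligner",
    "reciprocal_best_hit",
    "cross_taxon_correlation",
    "ci_exclusion_verdict",
    "buffering_test",
]


def ci_exclusion_verdict(
    r_t: float,
    ci_t: tuple[float, float],
    r_p: float,
    ci_p: tuple[float, float],
) -> tuple[bool, bool]:
    """(mutually_exclusive, buffering_detected) from the CI-exclusion rule.

    The correlations differ when each estimate lies outside the other's CI;
    buffering additionally requires the protein layer to be the more similar
    one (r_p > r_t). A mutually exclusive pair with r_p < r_t would indicate
    amplified, not buffered, divergence.
    """
    mutually_exclusive = not (ci_p[0] <= r_t <= ci_p[1]) and not (
        ci_t[0] <= r_p <= ci_t[1]
    )
    return mutually_exclusive, mutually_exclusive and r_p > r_t


def make_aligner(matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    """Local protein aligner with affine gaps (open 11, extend 1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _best_hits(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    aligner: Align.PairwiseAligner,
) -> dict[str, str]:
    """Best target per query; ties -> longer alignment, then smaller id."""
    hits: dict[str, str] = {}
    for qid, qseq in queries.items():
        scored = [(float(aligner.score(qseq, tseq)), tid) for tid, tseq in targets.items()]
        best = max(s for s, _ in scored)
        tied = sorted(tid for s, tid in scored if s == best)
        if len(tied) > 1:
            # prefer the longer best alignment, then the lexicographically
            # smallest id
            tied.sort(
                key=lambda tid: (-aligner.align(qseq, targets[tid])[0].length, tid)
            )
        hits[qid] = tied[0]
    return hits


def reciprocal_best_hit(
    prots_a: Mapping[str, str],
    prots_b: Mapping[str, str],
    matrix: str = "BLOSUM62",
) -> OrthologMap:
    """One-to-one orthology by reciprocal best local-alignment hits."""
    if not prots_a or not prots_b:
        raise ValueError("both protein sets must be nonempty")
    aligner = make_aligner(matrix)
    a_best = _best_hits(prots_a, prots_b, aligner)
    b_best = _best_hits(prots_b, prots_a, aligner)
    pairs = tuple(
        (aid, bid)
        for aid, bid in sorted(a_best.items())
        if b_best.get(bid) == aid
    )
    return OrthologMap(pairs=pairs, method=f"rbh-{matrix.lower()}")


def _usable_pairs(
    omap: OrthologMap, *layers: Mapping[str, float]
) -> list[tuple[str, str]]:
    # layers alternate taxon A / taxon B mappings
    out = []
    for aid, bid in omap.pairs:
        ok = all(
            (aid in layer if k % 2 == 0 else bid in layer)
            and layer[aid if k % 2 == 0 else bid] > 0
            for k, layer in enumerate(layers)
        )
        if ok:
            out.append((aid, bid))
    return out


def cross_taxon_correlation(
    vals_a: Mapping[str, float],
    vals_b: Mapping[str, float],
    omap: OrthologMap,
) -> tuple[float, tuple[float, float], int]:
    """Pearson R (with 95% Fisher-z CI) between clr abundances of orthologs."""
    pairs = _usable_pairs(omap, vals_a, vals_b)
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 usable ortholog pairs, got {len(pairs)}")
    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    renamed_b = {a: vals_b[b] for a, b in pairs}
    xv, yv = _matched_clr(vals_a, renamed_b, a_ids)
    r, ci = pearson_with_ci(xv, yv)
    return r, ci, len(pairs)


def buffering_test(
    transcripts_a: Mapping[str, float],
    transcripts_b: Mapping[str, float],
    proteins_a: Mapping[str, float],
    proteins_b: Mapping[str, float],
    omap: OrthologMap,
) -> BufferingResult:
    """CI-exclusion test for protein-level buffering over shared ortholog pairs.

    Both layers are restricted to the same pairs (those quantified in all four
    vectors) so the two correlations are directly comparable.
    """
    pairs = _usable_pairs(
        omap, transcripts_a, transcripts_b, proteins_a, proteins_b
    )
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 pairs quantified in all four layers, got {len(pairs)}")
    sub = OrthologMap(pairs=tuple(pairs), method=omap.method)
    r_t, ci_t, n = cross_taxon_correlation(transcripts_a, transcripts_b, sub)
    r_p, ci_p, _ = cross_taxon_correlation(proteins_a, proteins_b, sub)

    mutually_exclusive, detected = ci_exclusion_verdict(r_t, ci_t, r_p, ci_p)

    fisher_z = fisher_p = None
    if n > 3 and abs(r_t) < 1 and abs(r_p) < 1:
        fisher_z = (math.atanh(r_p) - math.atanh(r_t)) / math.sqrt(2.0 / (n - 3))
        fisher_p = float(2.0 * stats.norm.sf(abs(fisher_z)))

    return BufferingResult(
        n_pairs=n,
        r_transcript=r_t,
        ci_transcript=ci_t,
        r_protein=r_p,
        ci_protein=ci_p,
        mutually_exclusive=mutually_exclusive,
        buffering_detected=detected,
        fisher_z=fisher_z,
        fisher_z_p=fisher_p,
    )
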