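"""Internal-standard protein quantification from peptide intensity tables.

Molar protein abundances are estimated from label-free MS peptide intensities
calibrated against a spiked internal standard (yeast ADH at 50 fmol in the
original workflow). Two response-factor methods are provided:

* ``top3_quantify`` — the standard's known load divided by the summed
  intensities of its three highest-scoring peptides gives a response factor in
  fmol per intensity unit; each protein's top-three intensity sum is scaled by
  it. Only proteins with at least three detected peptides in a replicate are
  quantified in that replicate.
* ``allpeptide_quantify`` — an iBAQ-like measure: the standard's load times
  its molecular weight gives a femtogram load; divided by the sum of *all*
  standard peptide intensities this yields a response factor in fg per
  intensity unit. Each protein's total intensity is converted to fg and then
  to fmol via its theoretical molecular weight.

Response factors are computed independently per replicate; per-replicate fmol
estimates are averaged afterwards (``aggregate_replicates``), and proteins not
detected in every replicate are excluded from the quantitative set.
"""
from __future__ import annotations

import math
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from .types import ProteinQuantResult, StandardSpec

__all__ = [
    "tryptic_digest",
    "molecular_weight",
    "top3_quantify",
    "allpeptide_quantify",
    "aggregate_replicates",
    "apply_class_exclusions",
    "detected_set",
    "PEPTIDE_COLUMNS",
]

PEPTIDE_COLUMNS = ["replicate", "protein_id", "peptide_seq", "score", "intensity", "fpr"]

# trypsin cleaves C-terminal to K or R, blocked by a following proline
_CLEAVE = re.compile(r"(?<=[KR])(?!P)")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def tryptic_digest(seq: str, missed: int = 0) -> list[str]:
    """In-silico tryptic digest: cleave after K/R unless followed by P.

    With ``missed = m``, concatenations of up to ``m + 1`` adjacent fully
    cleaved fragments are also emitted, grouped by span size (all single
    fragments first, then all pairs, ...), each group in sequence order.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    if missed < 0:
        raise ValueError("missed cleavages must be >= 0")
    frags = [f for f in _CLEAVE.split(seq) if f]
    peptides: list[str] = []
    for k in range(1, missed + 2):
        for i in range(len(frags) - k + 1):
            peptides.append("".join(frags[i : i + k]))
    return peptides


def molecular_weight(seq: str) -> float:
    """Average (not monoisotopic) molecular weight of a protein in Da."""
    if not seq:
        raise ValueError("empty sequence has no molecular weight")
    bad = set(seq) - _AA20
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    return float(_bio_mw(seq, seq_type="protein", monoisotopic=False))


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if (table["intensity"] < 0).any():
        raise ValueError("peptide intensities must be nonnegative")
    return table


def _rank_peptides(group: pd.DataFrame) -> pd.DataFrame:
    # score descending; ties: higher intensity, then lexicographic peptide
    return group.sort_values(
        ["score", "intensity", "peptide_seq"], ascending=[False, False, True]
    )


def top3_quantify(
    table: pd.DataFrame, std: StandardSpec
) -> dict[int, dict[str, float]]:
    """Per-replicate fmol estimates from the top-three peptide intensities.

    Returns ``{replicate: {protein_id: fmol}}``; the standard itself is not
    reported. Proteins with fewer than three peptides in a replicate are
    absent from that replicate's map.
    """
    _check_table(table)
    out: dict[int, dict[str, float]] = {}
    for rep, sub in table.groupby("replicate", sort=True):
        std_rows = sub[sub["protein_id"] == std.protein_id]
        if len(std_rows) < 3:
            raise ValueError(
                f"standard {std.protein_id!r} has {len(std_rows)} peptides in "
                f"replicate {rep}; top-3 quantification needs at least 3"
            )
        std_top3 = _rank_peptides(std_rows).head(3)["intensity"].sum()
        rf = std.load_fmol / std_top3  # fmol per intensity unit
        rep_out: dict[str, float] = {}
        for pid, group in sub.groupby("protein_id"):
            if pid == std.protein_id or len(group) < 3:
                continue
            rep_out[pid] = rf * _rank_peptides(group).head(3)["intensity"].sum()
        out[int(rep)] = rep_out
    return out


def allpeptide_quantify(
    table: pd.DataFrame, std: StandardSpec, mw: Mapping[str, float]
) -> dict[int, dict[str, float]]:
    """Per-replicate fmol estimates from all peptide intensities (iBAQ-like).

    ``mw`` maps protein ids to theoretical molecular weights in Da; the
    standard's MW may be included or is derived from its sequence.
    """
    _check_table(table)
    mw_std = mw.get(std.protein_id, None)
    if mw_std is None:
        mw_std = molecular_weight(std.sequence)
    out: dict[int, dict[str, float]] = {}
    for rep, sub in table.groupby("replicate", sort=True):
        std_sum = sub.loc[sub["protein_id"] == std.protein_id, "intensity"].sum()
        if std_sum <= 0:
            raise ValueError(f"standard absent from replicate {rep}")
        rf = std.load_fmol * mw_std / std_sum  # fg per intensity unit
        rep_out: dict[str, float] = {}
        for pid, group in sub.groupby("protein_id"):
            if pid == std.protein_id:
                continue
            if pid not in mw:
                raise ValueError(f"no molecular weight for protein {pid!r}")
            rep_out[pid] = rf * group["intensity"].sum() / mw[pid]
        out[int(rep)] = rep_out
    return out


def peptide_counts(table: pd.DataFrame) -> dict[str, dict[int, int]]:
    """Number of peptide rows per protein per replicate."""
    counts: dict[str, dict[int, int]] = {}
    for (pid, rep), group in table.groupby(["protein_id", "replicate"]):
        counts.setdefault(str(pid), {})[int(rep)] = len(group)
    return counts


def aggregate_replicates(
    per_rep: Mapping[int, Mapping[str, float]],
    n_replicates: int,
    n_peptides: Mapping[str, Mapping[int, int]] | None = None,
) -> list[ProteinQuantResult]:
    """Average per-replicate fmol values and compute replicate CVs.

    A protein quantified in every one of the ``n_replicates`` replicates is
    flagged ``detected_all_replicates=True``; others are reported with the
    flag false and should be excluded from quantitative comparisons. The CV is
    the sample standard deviation (n-1) over replicate values divided by the
    mean; it is NaN when fewer than two values are available. High-CV proteins
    are flagged by their CV value, never removed here.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reps = sorted(per_rep)
    all_ids = sorted({pid for rep in reps for pid in per_rep[rep]})
    results: list[ProteinQuantResult] = []
    for pid in all_ids:
        vals = [per_rep[rep][pid] for rep in reps if pid in per_rep[rep]]
        detected_all = len(vals) == n_replicates
        mean = float(np.mean(vals))
        if len(vals) >= 2:
            cv = float(np.std(vals, ddof=1) / mean) if mean > 0 else math.nan
        else:
            cv = math.nan
        npep = []
        if n_peptides is not None:
            npep = [n_peptides.get(pid, {}).get(rep, 0) for rep in reps]
        results.append(
            ProteinQuantResult(
                protein_id=pid,
                per_replicate_fmol=[float(v) for v in vals],
                mean_fmol=mean,
                cv=cv,
                n_peptides_per_replicate=npep,
                detected_all_replicates=detected_all,
            )
        )
    return results


DEFAULT_EXCLUDED_CLASSES = frozenset({"BPP", "CNP"})


def apply_class_exclusions(
    results: Iterable[ProteinQuantResult],
    families: Mapping[str, str],
    classes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[ProteinQuantResult]:
    """Drop proteins whose family is in the excluded class set.

    Bradykinin-potentiating (BPP) and C-type natriuretic (CNP) peptides
    undergo extensive proteolytic processing, so their predicted tryptic
    peptides misrepresent the secreted product; they are removed from
    quantitative comparisons by default. Unknown or empty labels are retained.
    """
    kept = []
    for res in results:
        if families.get(res.protein_id, "") in classes:
            res.excluded_class = True
        else:
            kept.append(res)
    return kept


def detected_set(table: pd.DataFrame) -> set[str]:
    """Ids detected in at least one replicate with a 0% false-positive rate."""
    if len(table) == 0:
        return set()
    _check_table(table)
    hit = table[table["fpr"] == 0.0]
    return set(hit["protein_id"].astype(str).unique())
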