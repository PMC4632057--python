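"""Synthetic venom systems with known ground truth.

Every downstream stage of the pipeline (transcript filtering and TPM,
internal-standard protein quantification, concordance and buffering tests) is
exercised against data produced here, where the true toxin composition and the
true molar protein loads are known exactly. The generator emulates the
statistical structure of a venom study:

* a few dozen toxins whose molar abundances are log-normally distributed over
  several orders of magnitude;
* log transcript and log protein abundances correlated at a tunable level
  ``transcript_protein_rho``;
* read counts drawn multinomially in proportion to composition x CDS length,
  with near-uniform per-site coverage (anomalous transcripts, whose coverage
  is concentrated on a small fraction of sites, can be injected to exercise
  the coverage-CV filter);
* three MS replicates of peptide intensities with multiplicative lognormal
  noise, a spiked internal standard at a known fmol load, and an intensity
  detection threshold below which peptides go unreported.

It does NOT simulate raw reads, chromatography, spectra, spectral search, or
a nontoxin background proteome.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .proteins import PEPTIDE_COLUMNS, molecular_weight, tryptic_digest
from .types import OrthologMap, SimConfig, StandardSpec, ToxinRecord, VenomSystemTruth

__all__ = [
    "BUILTIN_STANDARD_SEQUENCE",
    "generate_toxin_sequences",
    "generate_abundances",
    "generate_read_data",
    "generate_peptide_table",
    "generate_taxon_pair",
]

# Synthetic internal-standard protein (13 tryptic peptides, ~11.6 kDa).
# This is NOT a natural sequence: it is a fixed, digestion-friendly stand-in
# for a spiked standard such as yeast ADH; quantification only needs the
# standard's digestibility and molecular weight. A real standard sequence can
# be supplied via `standard_sequence`.
BUILTIN_STANDARD_SEQUENCE = (
    "MSTELAVNK" "GFDQWIHR" "AVLYPESGK" "TNDFMQLR" "GSHWAEVK" "LPTYDNIR"
    "AGFESQVK" "WHDLMTNR" "SVAEGYPK" "FQNITDLR" "AHGWESVK" "YLPDMTNR"
    "GSEAFQVK"
)

STANDARD_ID = "STD"

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# K and R upweighted so tryptic sites are frequent enough in short toxins
_AA_P = np.full(20, (1.0 - 0.15) / 18)
_AA_P[_AA == "K"] = 0.075
_AA_P[_AA == "R"] = 0.075

_DEFAULT_FAMILIES = (
    "SVMP", "SVSP", "PLA2", "3FTx", "CTL", "LAAO", "CRISP", "VEGF", "NGF", "MYO",
)

# codon choices for reverse translation (standard genetic code)
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables  # noqa: E402

for _codon, _aa in _tables[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _v in _CODONS.values():
    _v.sort()


def _n_cleavage_sites(seq: str) -> int:
    return sum(
        1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    )


def _unique_peptides(seq: str) -> list[str]:
    seen: dict[str, None] = {}
    for pep in tryptic_digest(seq, missed=0):
        seen.setdefault(pep, None)
    return list(seen)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def generate_toxin_sequences(
    n: int,
    len_range: tuple[int, int],
    seed: int,
    families: Sequence[str] = _DEFAULT_FAMILIES,
) -> list[ToxinRecord]:
    """Random toxin protein/CDS pairs guaranteed to digest usefully.

    Each protein has at least four internal K/R cleavage sites (not followed
    by P) and at least four distinct tryptic peptides, so that top-three
    quantification is possible and the ideal-mode intensity allocation is
    well defined. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = len_range
    if lo < 30:
        raise ValueError(
            "sequence length below 30 residues cannot guarantee three tryptic peptides"
        )
    if lo > hi:
        raise ValueError("len_range must be (low, high) with low <= high")
    rng = np.random.default_rng(seed)
    records: list[ToxinRecord] = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(1000):
            seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
            if _n_cleavage_sites(seq) >= 4 and len(_unique_peptides(seq)) >= 4:
                break
        else:  # pragma: no cover - p(failure) vanishes after 1000 draws
            raise RuntimeError("could not generate a digestible sequence")
        records.append(
            ToxinRecord(
                id=f"TOX-{i + 1:03d}",
                protein=seq,
                cds=_reverse_translate(seq, rng),
                family=families[i % len(families)],
            )
        )
    return records


def generate_abundances(
    cfg: SimConfig,
    seed: int | None = None,
    standard_sequence: str = BUILTIN_STANDARD_SEQUENCE,
) -> VenomSystemTruth:
    """Draw a venom system's true composition and molar protein loads.

    Log transcript abundances are Normal(0, abundance_sigma^2), closed to a
    composition. Log protein abundances are ``rho*z_t + sqrt(1-rho^2)*z_e``
    with independent ``z_e`` of the same variance, so the population
    correlation of the log layers equals ``transcript_protein_rho``; protein
    loads are scaled so the median toxin is at ``fmol_scale`` fmol.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    seq_seed = int(rng.integers(2**31))
    toxins = generate_toxin_sequences(cfg.n_toxins, cfg.seq_len_range, seq_seed)
    ids = [t.id for t in toxins]

    rho = cfg.transcript_protein_rho
    z_t = rng.normal(0.0, cfg.abundance_sigma, cfg.n_toxins)
    z_e = rng.normal(0.0, cfg.abundance_sigma, cfg.n_toxins)
    log_p = rho * z_t + np.sqrt(1.0 - rho**2) * z_e

    raw = np.exp(z_t)
    comp = raw / raw.sum()
    fmol = cfg.fmol_scale * np.exp(log_p)

    standard = StandardSpec(
        protein_id=STANDARD_ID,
        sequence=standard_sequence,
        load_fmol=cfg.standard_load_fmol,
    )
    return VenomSystemTruth(
        toxins=toxins,
        true_transcript_comp=dict(zip(ids, comp.tolist())),
        true_protein_fmol=dict(zip(ids, fmol.tolist())),
        standard=standard,
    )


def generate_read_data(
    truth: VenomSystemTruth,
    total_reads: int,
    anomaly_ids: Iterable[str] = (),
    seed: int = 0,
    read_length: int = 100,
) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Multinomial read counts and per-site coverage profiles.

    Counts are multinomial with probabilities proportional to composition x
    CDS length (longer transcripts attract proportionally more reads).
    Coverage is Poisson and near-uniform across sites; transcripts in
    ``anomaly_ids`` get their entire expected coverage concentrated on the
    first 8% of sites, pushing their coverage CV well above 1.
    """
    if total_reads < 1000:
        raise ValueError("total_reads must be >= 1000")
    ids = truth.ids
    anomaly = set(anomaly_ids)
    unknown = anomaly - set(ids)
    if unknown:
        raise ValueError(f"unknown anomaly ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(t.cds) for t in truth.toxins], dtype=float)
    comp = np.array([truth.true_transcript_comp[i] for i in ids])
    p = comp * lengths
    p = p / p.sum()
    counts = rng.multinomial(total_reads, p)

    profiles: dict[str, np.ndarray] = {}
    for tox, count, length in zip(truth.toxins, counts, lengths):
        L = int(length)
        lam = np.zeros(L)
        if tox.id in anomaly:
            k = max(1, int(0.08 * L))
            lam[:k] = count * read_length / k
        else:
            lam[:] = count * read_length / L
        profiles[tox.id] = rng.poisson(lam)
    return dict(zip(ids, (int(c) for c in counts))), profiles


# In ideal mode the three top-ranked peptides of every protein (standard
# included) carry a summed intensity of exactly _IDEAL_TOP3 x fmol, and the
# total over all peptides is exactly fmol x MW. Both response-factor methods
# then recover the true fmol with no error: the top-3 method because the
# standard's and the protein's top-3 sums share the same per-fmol constant,
# the all-peptide method because total intensity plays the role of the fg
# load directly.
_IDEAL_TOP3 = 1000.0  # < MW of any >=30-residue protein, keeping shares positive


def generate_peptide_table(
    truth: VenomSystemTruth,
    cfg: SimConfig,
    ideal: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Peptide intensity tables for ``cfg.n_replicates`` MS replicates.

    Realistic mode: each protein's total intensity (fmol x MW) is split
    across its distinct tryptic peptides by a symmetric Dirichlet(2) share
    profile (heterogeneous ionization efficiency, no zero shares), then each
    peptide intensity receives independent multiplicative lognormal noise
    with CV ``replicate_cv`` per replicate. Peptides whose intensity falls
    below ``detection_threshold`` are omitted from that replicate; the
    internal standard is always reported in full. The ``score`` column ranks
    peptides consistently across replicates (by expected share).

    Ideal mode: noise-free intensities allocated so both quantification
    methods recover the true fmol exactly; see module comments.
    """
    rng = np.random.default_rng(seed)
    std = truth.standard
    std_peps = _unique_peptides(std.sequence)
    if len(std_peps) < 3:
        raise ValueError("standard sequence must digest into at least 3 peptides")

    sigma = float(np.sqrt(np.log1p(cfg.replicate_cv**2)))
    rows: list[tuple] = []

    proteins: list[tuple[str, str, float]] = [
        (t.id, t.protein, truth.true_protein_fmol[t.id]) for t in truth.toxins
    ]
    proteins.append((std.protein_id, std.sequence, std.load_fmol))

    for pid, seq, fmol in proteins:
        peps = _unique_peptides(seq)
        m = len(peps)
        if m == 0:
            raise ValueError(f"{pid}: empty tryptic digest")
        mw = molecular_weight(seq)
        if ideal:
            if m < 4:
                raise ValueError(
                    f"{pid}: ideal mode needs >= 4 distinct peptides, got {m}"
                )
            base = np.empty(m)
            base[:3] = fmol * _IDEAL_TOP3 / 3.0
            base[3:] = fmol * (mw - _IDEAL_TOP3) / (m - 3)
            scores = np.arange(m, 0, -1, dtype=float)
        else:
            share = rng.dirichlet(np.full(m, 2.0))
            base = fmol * mw * share
            scores = share
        for rep in range(1, cfg.n_replicates + 1):
            if ideal or cfg.replicate_cv == 0:
                intens = base
            else:
                eps = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=m)
                intens = base * eps
            for pep, sc, inten in zip(peps, scores, intens):
                if pid != std.protein_id and inten < cfg.detection_threshold:
                    continue
                rows.append((rep, pid, pep, float(sc), float(inten), 0.0))

    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def generate_taxon_pair(
    truth: VenomSystemTruth,
    cfg: SimConfig,
    seed: int = 0,
) -> tuple[VenomSystemTruth, VenomSystemTruth, OrthologMap]:
    """Derive a diverged sister taxon with a known protein-buffering level.

    Per-toxin log transcript shifts d ~ Normal(0, divergence_sigma^2) are
    applied to taxon B. The protein layer receives ``(1 - buffering_beta)*d``
    plus independent Normal(0, protein_noise_sigma^2) noise: beta=0 means
    protein divergence mirrors transcript divergence; beta=1 means protein
    levels are fully buffered toward taxon A. Orthology is the identity map.
    """
    rng = np.random.default_rng(seed)
    ids = truth.ids
    n = len(ids)
    d = rng.normal(0.0, cfg.divergence_sigma, n)
    eta = rng.normal(0.0, cfg.protein_noise_sigma, n)

    comp_a = np.array([truth.true_transcript_comp[i] for i in ids])
    fmol_a = np.array([truth.true_protein_fmol[i] for i in ids])

    raw_b = comp_a * np.exp(d)
    comp_b = raw_b / raw_b.sum()
    fmol_b = fmol_a * np.exp((1.0 - cfg.buffering_beta) * d + eta)

    taxon_b = VenomSystemTruth(
        toxins=truth.toxins,
        true_transcript_comp=dict(zip(ids, comp_b.tolist())),
        true_protein_fmol=dict(zip(ids, fmol_b.tolist())),
        standard=truth.standard,
    )
    omap = OrthologMap(pairs=tuple((i, i) for i in ids), method="simulated-truth")
    return truth, taxon_b, omap
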