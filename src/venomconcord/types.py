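"""Domain types shared across the venomconcord pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "ToxinRecord",
    "StandardSpec",
    "VenomSystemTruth",
    "TranscriptRecord",
    "CoverageProfile",
    "AbundanceEstimate",
    "ProteinQuantResult",
    "ConcordanceResult",
    "DetectionSummary",
    "OrthologMap",
    "BufferingResult",
]


@dataclass(frozen=True)
class ToxinRecord:
    """One toxin: the unit linking transcriptome to proteome.

    ``family`` carries the toxin-family label used for class-based exclusions
    (e.g. bradykinin-potentiating peptides are excluded from quantitative
    comparisons because of extensive proteolytic processing).
    """

    id: str
    protein: str
    cds: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"{self.id}: empty protein sequence")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")


@dataclass(frozen=True)
class StandardSpec:
    """Internal standard spiked at a known molar load to calibrate intensities."""

    protein_id: str
    sequence: str
    load_fmol: float = 50.0

    def __post_init__(self) -> None:
        if self.load_fmol <= 0:
            raise ValueError("standard load must be positive")
        if not self.sequence:
            raise ValueError("standard sequence must be nonempty")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic venom system.

    Defaults describe one venom: a few dozen toxins whose molar abundances are
    log-normally distributed over several orders of magnitude, profiled in
    three MS replicates against a 50-fmol internal standard.
    """

    n_toxins: int = 60
    seq_len_range: tuple[int, int] = (80, 300)
    abundance_sigma: float = 1.5
    transcript_protein_rho: float = 0.9
    n_replicates: int = 3
    replicate_cv: float = 0.2
    detection_threshold: float = 1e3
    standard_load_fmol: float = 50.0
    total_reads: int = 5_000_000
    divergence_sigma: float = 0.5
    buffering_beta: float = 0.0
    protein_noise_sigma: float = 0.1
    fmol_scale: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_toxins < 5:
            raise ValueError("n_toxins must be >= 5")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.buffering_beta <= 1.0:
            raise ValueError("buffering_beta must lie in [0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if abs(self.transcript_protein_rho) > 1:
            raise ValueError("transcript_protein_rho must lie in [-1, 1]")
        if self.divergence_sigma < 0:
            raise ValueError("divergence_sigma must be >= 0")
        if self.seq_len_range[0] < 30:
            raise ValueError(
                "minimum sequence length is 30 residues (shorter proteins "
                "cannot be guaranteed to yield three tryptic peptides)"
            )
        if self.seq_len_range[0] > self.seq_len_range[1]:
            raise ValueError("seq_len_range must be (low, high) with low <= high")


@dataclass
class VenomSystemTruth:
    """Ground truth for one synthetic venom: composition, molar loads, standard."""

    toxins: list[ToxinRecord]
    true_transcript_comp: dict[str, float]
    true_protein_fmol: dict[str, float]
    standard: StandardSpec

    def __post_init__(self) -> None:
        ids = [t.id for t in self.toxins]
        if len(set(ids)) != len(ids):
            raise ValueError("toxin ids must be unique")
        total = sum(self.true_transcript_comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"transcript composition sums to {total}, not 1")
        if any(v <= 0 for v in self.true_protein_fmol.values()):
            raise ValueError("all protein fmol must be positive")

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.toxins]


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    cds: str

    def __post_init__(self) -> None:
        if not self.cds:
            raise ValueError(f"{self.id}: empty CDS")

    @property
    def length(self) -> int:
        return len(self.cds)


@dataclass(frozen=True)
class CoverageProfile:
    """Per-site read depth along one coding sequence."""

    id: str
    depth: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.depth) == 0:
            raise ValueError(f"{self.id}: empty coverage profile")
        if any(d < 0 for d in self.depth):
            raise ValueError(f"{self.id}: negative depth")


@dataclass(frozen=True)
class AbundanceEstimate:
    """Named abundance vector (read counts or TPM) from one estimation method."""

    method: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("abundance values must be nonnegative")


@dataclass
class ProteinQuantResult:
    protein_id: str
    per_replicate_fmol: list[float]
    mean_fmol: float
    cv: float
    n_peptides_per_replicate: list[int] = field(default_factory=list)
    detected_all_replicates: bool = True
    excluded_class: bool = False


@dataclass(frozen=True)
class ConcordanceResult:
    """Transcript-protein concordance on the clr scale over matched ids."""

    n: int
    spearman_rho: float
    pearson_r: float
    r_squared: float
    pearson_ci_95: tuple[float, float]
    matched_ids: tuple[str, ...]


@dataclass(frozen=True)
class DetectionSummary:
    """Detection-threshold (post-transcriptional silencing) analysis output."""

    clr_abundance: dict[str, float]
    detected_flags: dict[str, bool]
    n_detected: int
    n_undetected: int
    rank_sum_p: float | None
    rank_most_expressed_undetected: int | None
    all_top_k_detected: bool
    k: int


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one toxin pairing between two taxa."""

    pairs: tuple[tuple[str, str], ...]
    method: str = "rbh"

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map must be one-to-one")


@dataclass(frozen=True)
class BufferingResult:
    """Cross-taxon correlations on both layers and the CI-exclusion verdict.

    ``buffering_detected`` is true only when the two Pearson estimates are
    mutually outside each other's 95% CI *and* the protein-level correlation
    exceeds the transcript-level one (protein abundances diverged less than
    transcript abundances). ``fisher_z_p`` is a secondary two-sample Fisher-z
    comparison of the two correlations, reported for reference only; the
    verdict uses the CI-exclusion rule.
    """

    n_pairs: int
    r_transcript: float
    ci_transcript: tuple[float, float]
    r_protein: float
    ci_protein: tuple[float, float]
    mutually_exclusive: bool
    buffering_detected: bool
    fisher_z: float | None = None
    fisher_z_p: float | None = None

    def __post_init__(self) -> None:
        if self.buffering_detected and not self.mutually_exclusive:
            raise ValueError("buffering_detected requires mutually_exclusive")
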