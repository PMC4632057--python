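"""Configuration-driven orchestration of the full synthetic-to-statistics run.

Stages communicate only through files in the output directory, so any stage
can be rerun or replaced with real data in the same formats. Reruns with an
identical configuration and seed are bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as vio
from .buffering import _usable_pairs, buffering_test, reciprocal_best_hit
from .concordance import _matched_clr, concordance, detection_threshold_analysis
from . import proteins as prot
from . import synthetic as syn
from . import transcripts as tx
from .types import OrthologMap, SimConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("venomconcord")

ALL_STAGES = (
    "simulate",
    "quantify-transcripts",
    "quantify-proteins",
    "concordance",
    "silencing",
    "buffering",
)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage dependency or input problem."""


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters; thresholds default to the study's values."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    divergence_threshold: float = 0.01
    coverage_max_cv: float = 1.0
    cross_method_fold: float = 10.0
    quant_method: str = "allpeptide"
    exclude_classes: tuple[str, ...] = ("BPP", "CNP")
    top_fraction: float = 0.25
    simulate_pair: bool = True
    use_rbh: bool = True
    orthologs_tsv: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.quant_method not in ("top3", "allpeptide"):
            raise ValueError("quant_method must be 'top3' or 'allpeptide'")
        for name in ("divergence_threshold", "coverage_max_cv", "cross_method_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"]["seq_len_range"] = list(self.sim.seq_len_range)
        d["stages"] = list(self.stages)
        d["exclude_classes"] = list(self.exclude_classes)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    if "seq_len_range" in sim_raw:
        sim_raw["seq_len_range"] = tuple(sim_raw["seq_len_range"])
    for key in ("stages", "exclude_classes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(sim=SimConfig(**sim_raw), **raw)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}' which has not run"
        )
    return path


def _simulate(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    truth_a = syn.generate_abundances(cfg.sim, seed=cfg.sim.seed)
    taxa = {"A": truth_a}
    summary: dict[str, Any] = {"taxa": []}
    if cfg.simulate_pair:
        _, truth_b, omap = syn.generate_taxon_pair(
            truth_a, cfg.sim, seed=cfg.sim.seed + 1
        )
        taxa["B"] = truth_b
        pairs_path = outdir / "orthologs_true.tsv"
        with pairs_path.open("w") as fh:
            fh.write("id_a\tid_b\n")
            for a, b in omap.pairs:
                fh.write(f"{a}\t{b}\n")
    for offset, (label, truth) in enumerate(sorted(taxa.items())):
        tdir = outdir / label
        tdir.mkdir(parents=True, exist_ok=True)
        base_seed = cfg.sim.seed + 100 * (offset + 1)
        counts, profiles = syn.generate_read_data(
            truth, cfg.sim.total_reads, seed=base_seed
        )
        counts2, _ = syn.generate_read_data(
            truth, cfg.sim.total_reads, seed=base_seed + 1
        )
        peptides = syn.generate_peptide_table(truth, cfg.sim, seed=base_seed + 2)
        prots = {t.id: t.protein for t in truth.toxins}
        prots[truth.standard.protein_id] = truth.standard.sequence
        vio.write_fasta(prots, tdir / "proteins.fasta")
        vio.write_fasta({t.id: t.cds for t in truth.toxins}, tdir / "cds.fasta")
        vio.write_counts(counts, tdir / "counts.tsv")
        vio.write_counts(counts2, tdir / "counts_method2.tsv")
        vio.write_coverage(profiles, tdir / "coverage.tsv")
        vio.write_peptide_table(peptides, tdir / "peptides.tsv")
        vio.write_truth(truth, tdir / "truth.json")
        summary["taxa"].append(
            {"label": label, "n_toxins": len(truth.toxins), "n_peptide_rows": len(peptides)}
        )
        log.info("simulated taxon %s: %d toxins, %d peptide rows",
                 label, len(truth.toxins), len(peptides))
    return summary


def quantify_transcripts_dir(tdir: Path, cfg: RunConfig) -> dict[str, Any]:
    records = vio.read_transcript_records(_require(tdir / "cds.fasta", "simulate", "quantify-transcripts"))
    counts = vio.read_counts(_require(tdir / "counts.tsv", "simulate", "quantify-transcripts"))
    counts2 = vio.read_counts(_require(tdir / "counts_method2.tsv", "simulate", "quantify-transcripts"))
    profiles = vio.read_coverage(_require(tdir / "coverage.tsv", "simulate", "quantify-transcripts"))

    clusters, reps = tx.cluster_transcripts(
        records, counts, threshold=cfg.divergence_threshold
    )
    cov_keep = tx.coverage_cv_filter(
        {i: profiles[i] for i in reps}, max_cv=cfg.coverage_max_cv
    )
    xm_keep = tx.cross_method_filter(
        {i: counts[i] for i in reps},
        {i: counts2[i] for i in reps},
        fold=cfg.cross_method_fold,
    )
    retained = sorted(set(reps) & cov_keep & xm_keep)
    nonzero = [i for i in retained if counts[i] > 0]
    lengths = {r.id: r.length for r in records}
    tpm_vals = tx.tpm({i: counts[i] for i in nonzero}, lengths)

    vio.write_abundance(tpm_vals, tdir / "tpm.tsv", col="tpm")
    (tdir / "retained_ids.txt").write_text("\n".join(retained) + "\n")
    summary = {
        "n_input": len(records),
        "n_clusters": len(clusters),
        "n_after_coverage_filter": len(set(reps) & cov_keep),
        "n_after_cross_method_filter": len(set(reps) & xm_keep),
        "n_retained": len(retained),
        "n_tpm": len(tpm_vals),
    }
    log.info(
        "transcripts %s: %d in, %d clusters, coverage filter kept %d, "
        "cross-method filter kept %d, %d retained",
        tdir.name, len(records), len(clusters),
        summary["n_after_coverage_filter"],
        summary["n_after_cross_method_filter"], len(retained),
    )
    return summary


def quantify_proteins_dir(tdir: Path, cfg: RunConfig) -> dict[str, Any]:
    table = vio.read_peptide_table(_require(tdir / "peptides.tsv", "simulate", "quantify-proteins"))
    truth = vio.read_truth(_require(tdir / "truth.json", "simulate", "quantify-proteins"))
    std = truth.standard
    mw = {t.id: prot.molecular_weight(t.protein) for t in truth.toxins}
    families = {t.id: t.family for t in truth.toxins}
    npep = prot.peptide_counts(table)

    qc: dict[str, Any] = {"standard_id": std.protein_id, "load_fmol": std.load_fmol}
    summary: dict[str, Any] = {}
    for method in ("top3", "allpeptide"):
        if method == "top3":
            per_rep = prot.top3_quantify(table, std)
        else:
            per_rep = prot.allpeptide_quantify(table, std, mw)
        results = prot.aggregate_replicates(per_rep, cfg.sim.n_replicates, npep)
        results = prot.apply_class_exclusions(
            results, families, set(cfg.exclude_classes)
        )
        import pandas as pd

        rows = []
        for r in results:
            row = {"protein_id": r.protein_id}
            for k, v in enumerate(r.per_replicate_fmol, start=1):
                row[f"rep{k}_fmol"] = v
            row.update(
                mean_fmol=r.mean_fmol,
                cv=r.cv,
                detected_all=r.detected_all_replicates,
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(tdir / f"quant_{method}.tsv", sep="\t", index=False)
        quantified = [r for r in results if r.detected_all_replicates]
        qc[method] = {
            "per_protein_cv": {r.protein_id: r.cv for r in quantified},
            "n_quantified": len(quantified),
            "n_partial": len(results) - len(quantified),
        }
        summary[method] = {
            "n_quantified": len(quantified),
            "n_partial": len(results) - len(quantified),
        }
        log.info(
            "proteins %s [%s]: %d quantified in all replicates, %d partial",
            tdir.name, method, len(quantified), len(results) - len(quantified),
        )
    (tdir / "quant_qc.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
    return summary


def _read_quant(tdir: Path, method: str, needed_by: str) -> dict[str, float]:
    import pandas as pd

    path = _require(tdir / f"quant_{method}.tsv", "quantify-proteins", needed_by)
    df = pd.read_csv(path, sep="\t")
    df = df[df["detected_all"]]
    return dict(zip(df["protein_id"].astype(str), df["mean_fmol"].astype(float)))


def _concordance(tdir: Path, cfg: RunConfig) -> dict[str, Any]:
    tpm_vals = vio.read_abundance(
        _require(tdir / "tpm.tsv", "quantify-transcripts", "concordance"), "tpm"
    )
    fmol = _read_quant(tdir, cfg.quant_method, "concordance")
    res = concordance(tpm_vals, fmol)
    payload = {
        "n": res.n,
        "spearman_rho": res.spearman_rho,
        "pearson_r": res.pearson_r,
        "r_squared": res.r_squared,
        "pearson_ci_95": list(res.pearson_ci_95),
        "method": cfg.quant_method,
    }
    (tdir / "concordance.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    import pandas as pd

    xv, yv = _matched_clr(tpm_vals, fmol, list(res.matched_ids))
    pd.DataFrame(
        {"id": res.matched_ids, "clr_tpm": xv, "clr_fmol": yv}
    ).to_csv(tdir / "concordance_pairs.tsv", sep="\t", index=False)
    log.info("concordance %s: n=%d rho=%.3f R=%.3f", tdir.name, res.n,
             res.spearman_rho, res.pearson_r)
    return payload


def _silencing(tdir: Path, cfg: RunConfig) -> dict[str, Any]:
    tpm_vals = vio.read_abundance(
        _require(tdir / "tpm.tsv", "quantify-transcripts", "silencing"), "tpm"
    )
    table = vio.read_peptide_table(_require(tdir / "peptides.tsv", "simulate", "silencing"))
    truth = vio.read_truth(tdir / "truth.json")
    detected = prot.detected_set(table) - {truth.standard.protein_id}
    positive = {i: v for i, v in tpm_vals.items() if v > 0}
    summary = detection_threshold_analysis(
        positive, detected & set(positive), top_fraction=cfg.top_fraction
    )
    payload = {
        "n_detected": summary.n_detected,
        "n_undetected": summary.n_undetected,
        "rank_sum_p": summary.rank_sum_p,
        "rank_most_expressed_undetected": summary.rank_most_expressed_undetected,
        "all_top_k_detected": summary.all_top_k_detected,
        "k": summary.k,
    }
    (tdir / "silencing.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    log.info("silencing %s: %d detected / %d undetected, p=%s", tdir.name,
             summary.n_detected, summary.n_undetected, summary.rank_sum_p)
    return payload


def _buffering(outdir: Path, cfg: RunConfig) -> dict[str, Any]:
    for label in ("A", "B"):
        if not (outdir / label).is_dir():
            raise PipelineError(
                "buffering needs two simulated taxa (set simulate_pair: true)"
            )
    if cfg.orthologs_tsv:
        pairs = vio.read_ortholog_tsv(cfg.orthologs_tsv)
        omap = OrthologMap(pairs=tuple(pairs), method="user-supplied")
    elif cfg.use_rbh:
        truth_a = vio.read_truth(outdir / "A" / "truth.json")
        prots_a = vio.read_fasta(outdir / "A" / "proteins.fasta")
        prots_b = vio.read_fasta(outdir / "B" / "proteins.fasta")
        std_id = truth_a.standard.protein_id
        prots_a.pop(std_id, None)
        prots_b.pop(std_id, None)
        omap = reciprocal_best_hit(prots_a, prots_b)
    else:
        pairs = vio.read_ortholog_tsv(
            _require(outdir / "orthologs_true.tsv", "simulate", "buffering")
        )
        omap = OrthologMap(pairs=tuple(pairs), method="simulated-truth")

    tpm_a = vio.read_abundance(_require(outdir / "A" / "tpm.tsv", "quantify-transcripts", "buffering"), "tpm")
    tpm_b = vio.read_abundance(_require(outdir / "B" / "tpm.tsv", "quantify-transcripts", "buffering"), "tpm")
    fmol_a = _read_quant(outdir / "A", cfg.quant_method, "buffering")
    fmol_b = _read_quant(outdir / "B", cfg.quant_method, "buffering")
    res = buffering_test(tpm_a, tpm_b, fmol_a, fmol_b, omap)
    payload = {
        "n_pairs": res.n_pairs,
        "r_transcript": res.r_transcript,
        "ci_transcript": list(res.ci_transcript),
        "r_protein": res.r_protein,
        "ci_protein": list(res.ci_protein),
        "mutually_exclusive": res.mutually_exclusive,
        "buffering_detected": res.buffering_detected,
        "fisher_z": res.fisher_z,
        "fisher_z_p": res.fisher_z_p,
        "ortholog_method": omap.method,
    }
    (outdir / "buffering.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    import pandas as pd

    usable = _usable_pairs(omap, tpm_a, tpm_b, fmol_a, fmol_b)
    rows = [
        {
            "id_a": a, "id_b": b,
            "tpm_a": tpm_a[a], "tpm_b": tpm_b[b],
            "fmol_a": fmol_a[a], "fmol_b": fmol_b[b],
        }
        for a, b in usable
    ]
    pd.DataFrame(rows).to_csv(outdir / "buffering_pairs.tsv", sep="\t", index=False)
    log.info("buffering: n=%d r_t=%.3f r_p=%.3f detected=%s", res.n_pairs,
             res.r_transcript, res.r_protein, res.buffering_detected)
    return payload


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the selected stages; returns (and writes) the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.sim.seed,
        "version": __version__,
        "stages": {},
    }
    taxa = ["A", "B"] if cfg.simulate_pair else ["A"]
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        if stage == "simulate":
            report["stages"][stage] = _simulate(cfg, outdir)
        elif stage == "quantify-transcripts":
            report["stages"][stage] = {
                label: quantify_transcripts_dir(outdir / label, cfg) for label in taxa
                if (outdir / label).is_dir()
            } or _raise_missing(stage)
        elif stage == "quantify-proteins":
            report["stages"][stage] = {
                label: quantify_proteins_dir(outdir / label, cfg) for label in taxa
                if (outdir / label).is_dir()
            } or _raise_missing(stage)
        elif stage == "concordance":
            report["stages"][stage] = {
                label: _concordance(outdir / label, cfg) for label in taxa
                if (outdir / label).is_dir()
            } or _raise_missing(stage)
        elif stage == "silencing":
            report["stages"][stage] = {
                label: _silencing(outdir / label, cfg) for label in taxa
                if (outdir / label).is_dir()
            } or _raise_missing(stage)
        elif stage == "buffering":
            report["stages"][stage] = _buffering(outdir, cfg)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _raise_missing(stage: str) -> None:
    raise PipelineError(f"stage '{stage}' found no simulated taxa; run 'simulate' first")
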