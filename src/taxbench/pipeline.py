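"""End-to-end benchmark orchestration.

``run_pipeline`` wires the stages together: simulate a community with
known per-read taxonomy, obtain a classification for it (the built-in
k-mer classifier, simulated classifier output with injected errors, or an
ingested external Kraken-format file), score it per rank with the five-way
status scheme, and compute abundance concordance.  Every stage's outputs
are persisted under the output directory, and a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceTable,
    ConcordanceResult,
    abundance_table,
    concordance,
    top_n_comparison,
)
from .classifier import build_index, classify_pairs
from .evaluation import (
    DEFAULT_EVAL_RANKS,
    EvaluationSummary,
    ReadStatus,
    TaxonSetComparison,
    evaluate,
    taxon_set_comparison,
)
from .kraken_io import (
    frame_to_records,
    read_kraken_output,
    records_to_frame,
    write_fasta,
    write_fastq,
    write_kraken_output,
    write_kraken_report,
    write_truth,
)
from .synthetic import (
    CommunityConfig,
    ErrorSpec,
    generate_genomes,
    generate_taxonomy,
    simulate_classifier_output,
    simulate_reads,
)
from .taxonomy import write_taxdump

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "BenchmarkReport", "run_pipeline", "load_config"]

_MODES = ("classify", "simulate-errors", "ingest")


@dataclass
class PipelineConfig:
    """Everything one benchmark run needs.

    ``mode`` selects the classification source: "classify" runs the
    built-in k-mer LCA classifier against an index of the community's own
    genomes; "simulate-errors" bypasses the classifier and injects the
    error structure of ``error_spec`` directly; "ingest" scores an
    external Kraken-format output file given by ``kraken_output``.
    """

    outdir: str | Path = "benchmark_out"
    seed: int = 0
    mode: str = "classify"
    community: CommunityConfig = field(default_factory=CommunityConfig)
    error_spec: ErrorSpec | None = None
    kraken_output: str | Path | None = None
    classifier_k: int = 21
    ranks: Sequence[str] = DEFAULT_EVAL_RANKS
    top_n: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "simulate-errors" and self.error_spec is None:
            raise ValueError("mode 'simulate-errors' requires error_spec")
        if self.mode == "ingest" and self.kraken_output is None:
            raise ValueError("mode 'ingest' requires kraken_output")
        for rank in self.ranks:
            if rank not in ("phylum", "class", "order", "family", "genus", "species"):
                raise ValueError(f"unknown evaluation rank {rank!r}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        self.community.validate()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["outdir"] = str(self.outdir)
        if self.kraken_output is not None:
            out["kraken_output"] = str(self.kraken_output)
        out["ranks"] = list(self.ranks)
        if self.error_spec is not None:
            out["error_spec"]["misassignment_frac"] = dict(
                self.error_spec.misassignment_frac
            )
        return out


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML file; unknown keys are a hard
    error at every level."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")

    def check_keys(data: Mapping, allowed: Sequence[str], context: str) -> None:
        unknown = set(data) - set(allowed)
        if unknown:
            raise ValueError(
                f"{path}: unknown {context} keys: {', '.join(sorted(unknown))}"
            )

    top_fields = [f.name for f in dataclasses.fields(PipelineConfig)]
    check_keys(raw, top_fields, "config")
    kwargs = dict(raw)
    if "community" in kwargs and kwargs["community"] is not None:
        community_fields = [f.name for f in dataclasses.fields(CommunityConfig)]
        check_keys(kwargs["community"], community_fields, "community")
        kwargs["community"] = CommunityConfig(**kwargs["community"])
    if "error_spec" in kwargs and kwargs["error_spec"] is not None:
        error_fields = [f.name for f in dataclasses.fields(ErrorSpec)]
        check_keys(kwargs["error_spec"], error_fields, "error_spec")
        kwargs["error_spec"] = ErrorSpec(**kwargs["error_spec"])
    if "ranks" in kwargs and kwargs["ranks"] is not None:
        kwargs["ranks"] = tuple(kwargs["ranks"])
    return PipelineConfig(**kwargs)


@dataclass
class BenchmarkReport:
    """Aggregated results of one benchmark run.

    Serialisable to a plain dict (and back) without loss of any value the
    pipeline computes.
    """

    provenance: dict
    evaluation: EvaluationSummary
    concordance_by_rank: dict[str, ConcordanceResult]
    taxon_sets_by_rank: dict[str, TaxonSetComparison]
    top_taxa_by_rank: dict[str, pd.DataFrame]

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "evaluation": self.evaluation.to_dict(),
            "concordance": {
                rank: res.to_dict()
                for rank, res in self.concordance_by_rank.items()
            },
            "taxon_sets": {
                rank: {
                    "false_positive_taxa": sorted(ts.false_positive_taxa),
                    "false_negative_taxa": sorted(ts.false_negative_taxa),
                    "n_false_positives": ts.n_false_positives,
                    "n_false_negatives": ts.n_false_negatives,
                }
                for rank, ts in self.taxon_sets_by_rank.items()
            },
            "top_taxa": {
                rank: frame.to_dict(orient="records")
                for rank, frame in self.top_taxa_by_rank.items()
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def load(path: str | Path) -> dict:
        """Reload a saved report as the plain dict written by :meth:`save`."""
        with open(path) as fh:
            return json.load(fh)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.1fs", name, elapsed)
            else:
                logger.error("stage %s: FAILED after %.1fs", name, elapsed)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> BenchmarkReport:
    """Execute simulate -> classify -> evaluate -> abundance -> report.

    All intermediate files are written under ``config.outdir``; a stage
    failure aborts with the stage named in the log, retaining the partial
    outputs written so far.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("simulate"):
        db, species = generate_taxonomy(config.community, config.seed)
        write_taxdump(db, outdir / "nodes.dmp", outdir / "names.dmp")
        genomes = generate_genomes(db, species, config.community, config.seed)
        write_fasta(genomes, outdir / "genomes.fasta")
        sim = simulate_reads(genomes, db, config.community, config.seed)
        write_fastq(sim.reads_r1, outdir / "reads_1.fastq")
        write_fastq(sim.reads_r2, outdir / "reads_2.fastq")
        write_truth(sim.truth, outdir / "truth.tsv")

    with _stage("classify"):
        if config.mode == "classify":
            index = build_index(genomes, db, k=config.classifier_k)
            records = classify_pairs(index, db, sim.reads_r1, sim.reads_r2)
        elif config.mode == "simulate-errors":
            assert config.error_spec is not None
            frame = simulate_classifier_output(
                sim.truth, db, config.error_spec, seed=config.seed + 3_000_017
            )
            records = frame_to_records(frame)
        else:  # ingest
            records = read_kraken_output(config.kraken_output)
        write_kraken_output(records, outdir / "kraken_output.tsv")
        write_kraken_report(records, outdir / "kraken_report.tsv", db=db)
        classified = records_to_frame(records)

    with _stage("evaluate"):
        summary = evaluate(sim.truth, classified, db, ranks=config.ranks)
        summary.to_frame().to_csv(
            outdir / "evaluation.tsv", sep="\t", index=False
        )
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    with _stage("abundance"):
        concordance_by_rank: dict[str, ConcordanceResult] = {}
        taxon_sets: dict[str, TaxonSetComparison] = {}
        top_taxa: dict[str, pd.DataFrame] = {}
        for rank in config.ranks:
            truth_tab = abundance_table(sim.truth, db, rank, source="truth")
            class_tab = abundance_table(
                classified, db, rank, source="classified"
            )
            truth_tab.to_frame().to_csv(
                outdir / f"abundance_truth_{rank}.tsv", sep="\t", index=False
            )
            class_tab.to_frame().to_csv(
                outdir / f"abundance_classified_{rank}.tsv",
                sep="\t",
                index=False,
            )
            concordance_by_rank[rank] = concordance(truth_tab, class_tab)
            taxon_sets[rank] = taxon_set_comparison(
                truth_tab.counts, class_tab.counts, rank
            )
            top_taxa[rank] = top_n_comparison(
                truth_tab, class_tab, n=config.top_n, db=db
            )
            top_taxa[rank].to_csv(
                outdir / f"top_taxa_{rank}.tsv", sep="\t", index=False
            )

    with _stage("report"):
        provenance = {
            "config": config.to_dict(),
            "seed": config.seed,
            "taxbench_version": __version__,
            "python_version": platform.python_version(),
        }
        report = BenchmarkReport(
            provenance=provenance,
            evaluation=summary,
            concordance_by_rank=concordance_by_rank,
            taxon_sets_by_rank=taxon_sets,
            top_taxa_by_rank=top_taxa,
        )
        report.save(outdir / "benchmark_report.json")
    return report
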