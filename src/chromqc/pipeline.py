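"""Config-driven orchestration of the QC stages.

The pipeline runs stages in dependency order::

    simulate -> repeats -> qc
                        -> kmersize / errors / nlr -> report

Each stage reads and writes plain text (FASTA, BED, TSV, GFF3) under a
single output directory, so any stage can also be run standalone on
externally produced inputs. Configuration is one TOML or YAML file with a
table per stage; TSVs are the canonical outputs and the whole run is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import density, kmers, nlr, qc, repeats, synthetic, variants
from ._seqio import read_fasta, write_fasta
from .exceptions import ChromQCError, ConfigError, StageError

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "STAGE_ORDER"]

logger = logging.getLogger("chromqc")

STAGE_ORDER = ("simulate", "repeats", "qc", "kmersize", "errors", "nlr", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` lists the enabled stages; ``params`` holds one dict of
    options per stage (see the README for the schema). Explicit input paths
    in a stage's params override the outputs of earlier stages.
    """

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    params: dict[str, dict] = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))


def load_config(path, overrides: dict | None = None) -> PipelineConfig:
    """Load a TOML (default) or YAML pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raw = tomllib.loads(path.read_text())
    top = raw.get("pipeline", {})
    if overrides:
        top.update({k: v for k, v in overrides.items() if v is not None})
    stages = tuple(top.get("stages", STAGE_ORDER))
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}; valid: {STAGE_ORDER}")
    stages = tuple(s for s in STAGE_ORDER if s in stages)  # dependency order
    return PipelineConfig(
        outdir=Path(top.get("outdir", "chromqc_out")),
        seed=int(top.get("seed", 0)),
        stages=stages,
        params={k: v for k, v in raw.items() if k != "pipeline"},
    )


def _require_input(path: Path | None, what: str, stage: str) -> Path:
    if path is None:
        raise ConfigError(f"stage '{stage}' needs {what}: enable the producing stage "
                          f"or set the path in the config")
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"stage '{stage}': {what} not found at {path}")
    return path


def _validate(config: PipelineConfig) -> None:
    """Check, before running anything, that every enabled stage has inputs."""
    enabled = set(config.stages)
    produced = set()
    if "simulate" in enabled:
        produced |= {"fasta", "histogram", "sites", "nlr", "gff"}
    if "repeats" in enabled:
        produced.add("arrays")

    def has(stage, key, kind):
        return config.stage_params(stage).get(key) is not None or kind in produced

    checks = [
        ("repeats", "fasta", "fasta"),
        ("qc", "fasta", "fasta"),
        ("qc", "arrays", "arrays"),
        ("kmersize", "histogram", "histogram"),
        ("errors", "sites", "sites"),
        ("nlr", "nlr", "nlr"),
        ("nlr", "gff", "gff"),
        ("report", "fasta", "fasta"),
    ]
    for stage, key, kind in checks:
        if stage in enabled and not has(stage, key, kind):
            raise ConfigError(
                f"stage '{stage}' is enabled but has no '{key}' input and no "
                f"enabled stage produces it"
            )


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("simulate")
    outdir = config.outdir
    preset = p.get("preset", "benchmark")
    seed = config.seed
    if preset == "benchmark":
        specs = synthetic.benchmark_preset(
            seed=seed,
            scale=int(p.get("scale", 1_600)),
            telomere_copies=int(p.get("telomere_copies", 120)),
            centromere_copies=int(p.get("centromere_copies", 55)),
        )
    elif preset == "fused":
        specs = [synthetic.fused_preset(seed=seed)]
    else:
        raise ConfigError(f"unknown simulate preset {preset!r} (benchmark or fused)")
    assembly = synthetic.build_assembly(specs, seed=seed, outdir=outdir)
    outputs["fasta"] = outdir / "assembly.fasta"
    outputs["gap_truth"] = outdir / "truth_gaps.bed"

    sim = synthetic.simulate_kmer_histogram(
        true_genome_size=int(p.get("true_genome_size", 50_000_000)),
        coverage_peak=float(p.get("coverage_peak", 101)),
        seed=seed + 1,
    )
    kmers.write_kmer_histogram(sim.histogram, outdir / "kmer_histogram.txt")
    outputs["histogram"] = outdir / "kmer_histogram.txt"

    sites_df, _ = synthetic.simulate_variant_sites(
        n_sites=int(p.get("n_sites", 500)),
        fraction_error=float(p.get("fraction_error", 0.05)),
        seed=seed + 2,
    )
    synthetic.write_variant_sites(sites_df, outdir / "variant_sites.tsv")
    outputs["sites"] = outdir / "variant_sites.tsv"
    outputs["total_bases"] = assembly.total_length

    fixture = synthetic.simulate_nlr_fixture(
        n_nlr=int(p.get("n_nlr", 200)),
        n_genes=int(p.get("n_genes", 150)),
        containment_fraction=float(p.get("containment_fraction", 0.5)),
        seed=seed + 3,
    )
    synthetic.write_nlr_tsv(fixture.nlrs, outdir / "nlr_predictions.tsv")
    synthetic.write_genes_gff3(fixture.genes, outdir / "genes.gff3")
    outputs["nlr"] = outdir / "nlr_predictions.tsv"
    outputs["gff"] = outdir / "genes.gff3"


def _stage_repeats(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("repeats")
    outdir = config.outdir
    if p.get("trf_dat"):
        arrays = repeats.read_trf_dat(p["trf_dat"])
        fasta = _require_input(p.get("fasta") or outputs.get("fasta"), "a FASTA", "repeats")
        sequences = read_fasta(fasta)
    else:
        fasta = _require_input(p.get("fasta") or outputs.get("fasta"), "a FASTA", "repeats")
        sequences = read_fasta(fasta)
        arrays = repeats.detect_in_assembly(
            sequences,
            max_unit=int(p.get("max_unit", 500)),
            min_copies=int(p.get("min_copies", 3)),
            max_divergence=float(p.get("max_divergence", 0.2)),
        )
    lengths = {name: len(seq) for name, seq in sequences.items()}
    arrays = repeats.classify_arrays(
        arrays,
        lengths,
        end_window=int(p.get("end_window", 10_000)),
        centromere_unit=int(p.get("centromere_unit", 181)),
        centromere_min_span=int(p.get("centromere_min_span", 5_000)),
    )
    repeats.write_arrays_bed(arrays, outdir / "arrays.bed")
    repeats.write_arrays_tsv(arrays, outdir / "arrays.tsv")
    hist = repeats.unit_length_histogram(arrays)
    with open(outdir / "unit_length_histogram.tsv", "w") as handle:
        handle.write("unit_length\tspan_bp\tis_peak\n")
        for u in sorted(hist.spans):
            handle.write(f"{u}\t{hist.spans[u]}\t{int(u in hist.peaks)}\n")
    outputs["arrays"] = outdir / "arrays.tsv"
    outputs["lengths"] = lengths


def _stage_qc(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("qc")
    outdir = config.outdir
    fasta = _require_input(p.get("fasta") or outputs.get("fasta"), "a FASTA", "qc")
    arrays_path = _require_input(
        p.get("arrays") or outputs.get("arrays"), "a classified arrays TSV", "qc"
    )
    sequences = read_fasta(fasta)
    arrays = repeats.read_arrays_tsv(arrays_path)
    gap_truth = None
    truth_path = p.get("gap_truth") or outputs.get("gap_truth")
    if truth_path and Path(truth_path).exists():
        gap_truth = synthetic.load_truth(Path(truth_path).parent).gaps

    end_window = int(p.get("end_window", 10_000))
    reports = []
    all_gaps = []
    for seqid, seq in sequences.items():
        truth_for = [g for g in gap_truth if g.seqid == seqid] if gap_truth else None
        gaps = qc.find_gaps(seq, seqid=seqid, gap_truth=truth_for)
        all_gaps.extend(gaps)
        reports.append(
            qc.assess_scaffold(
                seqid, len(seq), arrays, gaps,
                end_window=end_window,
                cluster_merge_distance=int(p.get("cluster_merge_distance", 100_000)),
                centromere_separation=int(p.get("centromere_separation", 1_000_000)),
            )
        )
    table, nx = qc.assembly_summary(reports)
    table.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    with open(outdir / "nx.tsv", "w") as handle:
        handle.write("statistic\tvalue\n")
        for name, value in nx.items():
            handle.write(f"{name}\t{value}\n")
    with open(outdir / "flags.tsv", "w") as handle:
        handle.write("seqid\tkind\tevidence\tproposed_split\n")
        for r in reports:
            for f in r.anomalies:
                ev = ";".join(f"{s}-{e}" for s, e in f.evidence)
                split = "" if f.proposed_split is None else f.proposed_split
                handle.write(f"{f.seqid}\t{f.kind}\t{ev}\t{split}\n")

    if p.get("split"):
        pieces: dict[str, str] = {}
        for r in reports:
            flagged = [f for f in r.anomalies if f.proposed_split is not None]
            if flagged:
                left, right = qc.split_scaffold(sequences[r.seqid], flagged[0])
                pieces[left.name] = left.sequence
                pieces[right.name] = right.sequence
            else:
                pieces[r.seqid] = sequences[r.seqid]
        write_fasta(pieces, outdir / "assembly.split.fasta")
    outputs["qc_reports"] = reports


def _stage_kmersize(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("kmersize")
    outdir = config.outdir
    hist_path = _require_input(
        p.get("histogram") or outputs.get("histogram"), "a k-mer histogram", "kmersize"
    )
    hist = kmers.read_kmer_histogram(hist_path, k=int(p.get("k", 31)))
    peaks = kmers.find_coverage_peaks(hist)
    estimate = kmers.estimate_genome_size(
        hist, peaks.primary_peak,
        f_min=int(p.get("f_min", 1)), f_max=int(p.get("f_max", 10_000)),
    )
    with open(outdir / "genome_size.tsv", "w") as handle:
        handle.write("primary_peak\tsecondary_peak\tauc\tsize_bp\tf_min\tf_max\n")
        secondary = "" if peaks.secondary_peak is None else peaks.secondary_peak
        handle.write(
            f"{peaks.primary_peak}\t{secondary}\t{estimate.auc}"
            f"\t{estimate.size_bp:.1f}\t{estimate.f_min}\t{estimate.f_max}\n"
        )


def _stage_errors(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("errors")
    outdir = config.outdir
    sites_path = _require_input(
        p.get("sites") or outputs.get("sites"), "a variant-sites table", "errors"
    )
    total_bases = int(p.get("total_bases") or outputs.get("total_bases") or 0)
    if total_bases <= 0:
        raise ConfigError("stage 'errors' needs total_bases (assembly length)")
    sites = variants.classify_error_sites(variants.read_variant_sites(sites_path))
    summary = variants.summarize_error_rate(sites, total_bases)
    with open(outdir / "error_rate.tsv", "w") as handle:
        handle.write("error_bases\ttotal_bases\terrors_per_10kb\tconsensus_quality_pct\n")
        handle.write(
            f"{summary.error_bases}\t{summary.total_bases}"
            f"\t{summary.errors_per_10kb:.4f}\t{summary.consensus_quality_pct:.4f}\n"
        )


def _stage_nlr(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("nlr")
    outdir = config.outdir
    nlr_path = _require_input(p.get("nlr") or outputs.get("nlr"), "an NLR TSV", "nlr")
    gff_path = _require_input(p.get("gff") or outputs.get("gff"), "a GFF3", "nlr")
    predictions = nlr.read_nlr_predictions(nlr_path)
    genes = nlr.read_gene_models(gff_path)
    consensus = nlr.consensus_intersect(
        predictions, genes, containment=p.get("containment", "gene-in-nlr")
    )
    class_counts, per_seqid = nlr.partition_by_completeness(consensus)
    with open(outdir / "consensus_pairs.tsv", "w") as handle:
        handle.write("nlr_id\tgene_id\tseqid\tgene_start\tgene_end\tcompleteness\n")
        for pred, gene in consensus.pairs:
            handle.write(
                f"{pred.id}\t{gene.id}\t{gene.seqid}\t{gene.start}\t{gene.end}"
                f"\t{pred.completeness}\n"
            )
    with open(outdir / "nlr_class_counts.tsv", "w") as handle:
        handle.write("set\t" + "\t".join(nlr.COMPLETENESS_CLASSES) + "\ttotal\n")
        predicted = nlr.class_tally(predictions)
        handle.write(
            "predicted\t"
            + "\t".join(str(predicted[c]) for c in nlr.COMPLETENESS_CLASSES)
            + f"\t{sum(predicted.values())}\n"
        )
        handle.write(
            "consensus\t"
            + "\t".join(str(class_counts[c]) for c in nlr.COMPLETENESS_CLASSES)
            + f"\t{consensus.n_consensus}\n"
        )
    per_seqid.to_csv(outdir / "nlr_per_scaffold.tsv", sep="\t", index=False)
    outputs["consensus_pairs"] = consensus.pairs

    if p.get("nbarc_aln"):
        result = nlr.filter_alignment_by_missing(
            p["nbarc_aln"], threshold=float(p.get("missing_threshold", 0.5))
        )
        with open(outdir / "nbarc_filter.tsv", "w") as handle:
            handle.write("id\tmissing_fraction\tkept\n")
            for name, frac in result.missing_fraction.items():
                handle.write(f"{name}\t{frac:.4f}\t{int(name in set(result.kept))}\n")
    if p.get("proteins"):
        hits = nlr.scan_motif(p["proteins"], pattern=p.get("motif", nlr.RPW8_MOTIF))
        with open(outdir / "rpw8_hits.tsv", "w") as handle:
            handle.write("id\toffset\n")
            for name, offset in hits:
                handle.write(f"{name}\t{offset}\n")


def _stage_report(config: PipelineConfig, outputs: dict) -> None:
    p = config.stage_params("report")
    outdir = config.outdir
    fasta = _require_input(p.get("fasta") or outputs.get("fasta"), "a FASTA", "report")
    lengths = outputs.get("lengths") or {
        name: len(seq) for name, seq in read_fasta(fasta).items()
    }
    window = int(p.get("window", 1_000_000))

    tracks = {}
    arrays_path = p.get("arrays") or outputs.get("arrays")
    if arrays_path and Path(arrays_path).exists():
        arrays = repeats.read_arrays_tsv(arrays_path)
        tracks["repeat_bp"] = density.windowed_density(arrays, lengths, window=window)
    gff_path = p.get("gff") or outputs.get("gff")
    if gff_path and Path(gff_path).exists():
        # keep only annotations that live on (and within) the assembly scaffolds
        genes = [
            g for g in nlr.read_gene_models(gff_path)
            if g.seqid in lengths and g.end <= lengths[g.seqid]
        ]
        tracks["gene_bp"] = density.windowed_density(genes, lengths, window=window)
    if not tracks:
        tracks["coverage_bp"] = density.windowed_density([], lengths, window=window)

    merged = None
    for name, table in tracks.items():
        table = table.rename(columns={"value": name})
        merged = table if merged is None else merged.merge(
            table, on=["seqid", "window_start", "window_end"]
        )
    merged.to_csv(outdir / "windowed_density.tsv", sep="\t", index=False)

    bundle = {"stages": list(config.stages), "seed": config.seed}
    if "qc_reports" in outputs:
        bundle["scaffolds"] = len(outputs["qc_reports"])
    with open(outdir / "report.json", "w") as handle:
        json.dump(bundle, handle, indent=2, sort_keys=True)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "repeats": _stage_repeats,
    "qc": _stage_qc,
    "kmersize": _stage_kmersize,
    "errors": _stage_errors,
    "nlr": _stage_nlr,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run enabled stages in dependency order; returns stage timings.

    Configuration problems are raised as :class:`ConfigError` before any
    stage executes; a failure inside a stage is wrapped in
    :class:`StageError` naming the stage.
    """
    _validate(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    timings: dict[str, float] = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config, outputs)
        except (ConfigError, StageError):
            raise
        except ChromQCError as exc:
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"stage '{stage}' failed unexpectedly: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s: done in %.2fs", stage, timings[stage])
    return timings
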