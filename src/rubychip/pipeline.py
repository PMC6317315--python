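"""End-to-end orchestration of the synthetic four-factor study.

Runs simulate -> normalize -> call peaks (per replicate) -> blacklist ->
consolidate -> annotate -> profile -> quantify with one config whose
defaults are the analysis parameters used throughout the package
(q 0.05, fragment 150 bp, summit flank 150 bp / width 300 bp, blacklist
score 100 / clustering 500 bp, mappability mask 0.25, promoters 500 bp,
quantification bins 1 kb), and writes deterministic TSV/BED outputs
plus a JSON manifest with parameter and output-hash provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .annotate import (
    AnnotationUniverse,
    build_universe,
    classify_peaks,
    enrichment_matrix,
)
from .consolidate import extend_summits, filter_regions, intersect_replicates
from .normalize import normalize, sum_inputs
from .peaks import build_blacklist, call_peaks
from .pirna import classify_pirna_types, validate_ruby_upstream
from .profiles import aggregate_profile, anchored_profile, quantify_bins
from .synthetic import (
    FactorProfile,
    GenomeSpec,
    demo_factor_profiles,
    demo_genome_spec,
    make_genome,
    simulate_coverage,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "normalize",
    "callpeaks",
    "blacklist",
    "consolidate",
    "annotate",
    "profile",
    "quantify",
)


@dataclass
class PipelineConfig:
    """All stage parameters with the study defaults."""

    seed: int = 0
    q_cutoff: float = 0.05
    fragment_len: int = 150
    summit_flank: int = 150
    peak_width: int = 300
    blacklist_score_min: float = 100.0
    blacklist_cluster_within: int = 500
    mappability_min: float = 0.25
    promoter_upstream: int = 500
    quant_bin: int = 1000
    profile_flank: int = 500
    profile_bin: int = 50
    heatmap_flank: int = 5000
    heatmap_bin: int = 100
    smoothing_bw: int = 500
    pseudocount: float = 1.0
    include_null_control: bool = True
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not (0.0 < self.q_cutoff < 1.0):
            raise ValueError("q_cutoff must be in (0, 1)")
        if self.fragment_len <= 0 or self.peak_width <= 0:
            raise ValueError("lengths must be positive")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        payload["stages"] = tuple(payload.get("stages", STAGES))
        return cls(**payload)


@dataclass
class PipelineResult:
    """In-memory outputs of one run, keyed by stage."""

    config: PipelineConfig
    genome: object = None
    factors: dict = field(default_factory=dict)
    summed_input: object = None
    blacklist: list = field(default_factory=list)
    universe: AnnotationUniverse | None = None
    enrichment: object = None
    ruby_table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _require(result: PipelineResult, attr, stage: str) -> None:
    if not attr:
        raise RuntimeError(
            f"stage '{stage}' requires outputs of an earlier stage that was not run"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    spec: GenomeSpec | None = None,
    profiles: list[FactorProfile] | None = None,
    write_tracks: bool = False,
) -> PipelineResult:
    """Execute the configured stages on the synthetic study.

    ``spec``/``profiles`` default to the bundled four-factor demo (plus
    a fold-1 null control factor used for profile calibration).  When
    ``outdir`` is given, stage outputs are written as TSV/BED/GFF3/FASTA
    plus a ``manifest.json`` recording parameters and sha256 hashes of
    every file; identical seeds give identical hashes.
    """
    t0 = time.time()
    result = PipelineResult(config=config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        files[name] = _sha256(path)

    spec = spec if spec is not None else demo_genome_spec(config.seed)
    profiles = list(profiles) if profiles is not None else demo_factor_profiles()
    if config.include_null_control:
        profiles.append(FactorProfile("null-control"))

    stages = config.stages

    if "simulate" in stages:
        logger.info("stage simulate")
        genome = make_genome(spec)
        result.genome = genome
        input_tracks = []
        for idx, prof in enumerate(profiles):
            reps, inp = simulate_coverage(
                genome, prof, replicate_seed=config.seed * 100 + idx
            )
            result.factors[prof.name] = {"profile": prof, "chip_reps": reps, "input": inp}
            input_tracks.append(inp)
        result.summed_input = sum_inputs(input_tracks)
        emit("genome.fa", lambda p: rio.write_fasta(genome.sequences, p))
        emit("genes.gff3", lambda p: rio.write_gff3(genome.genes, p))
        anchors = [
            (g.interval.chrom, int(g.attributes["first_u"]), g.interval.strand)
            for g in genome.pirna_genes()
        ]
        emit(
            "pirna_first_u.bed",
            lambda p: rio.write_bed6(
                [
                    rio.GenomicInterval(c, u, u + 1, s)
                    for c, u, s in anchors
                ],
                p,
                names=[g.name for g in genome.pirna_genes()],
            ),
        )
        if write_tracks:
            emit("mappability.bedgraph", lambda p: rio.write_bedgraph(genome.mappability, p))

    if "normalize" in stages:
        _require(result, result.factors, "normalize")
        logger.info("stage normalize")
        for name, bundle in result.factors.items():
            pooled = bundle["chip_reps"][0].copy()
            for rep in bundle["chip_reps"][1:]:
                for chrom in pooled.data:
                    pooled.data[chrom] += rep.data[chrom]
            bundle["normalized"] = normalize(
                pooled,
                result.summed_input,
                mappability=result.genome.mappability,
                smoothing_bw=config.smoothing_bw,
                pseudocount=config.pseudocount,
                mask_below=config.mappability_min,
            )
            if write_tracks:
                emit(
                    f"norm_{name}.bedgraph",
                    lambda p, b=bundle: rio.write_bedgraph(b["normalized"], p),
                )

    if "callpeaks" in stages:
        _require(result, result.factors, "callpeaks")
        logger.info("stage callpeaks")
        for name, bundle in result.factors.items():
            bundle["peaks"] = [
                call_peaks(
                    rep,
                    control=result.summed_input,
                    q_cutoff=config.q_cutoff,
                    fragment_len=config.fragment_len,
                )
                for rep in bundle["chip_reps"]
            ]
            if write_tracks:
                for i, pk in enumerate(bundle["peaks"]):
                    emit(
                        f"peaks_{name}_rep{i + 1}.narrowPeak",
                        lambda p, pk=pk: rio.write_narrowpeak(pk, p),
                    )

    if "blacklist" in stages:
        _require(result, result.factors, "blacklist")
        logger.info("stage blacklist")
        inputs = [b["input"] for b in result.factors.values()]
        result.blacklist = build_blacklist(
            inputs,
            score_min=config.blacklist_score_min,
            cluster_within=config.blacklist_cluster_within,
            fragment_len=config.fragment_len,
        )
        emit(
            "blacklist.bed",
            lambda p: rio.write_bed3([b.interval for b in result.blacklist], p),
        )

    if "consolidate" in stages:
        _require(result, result.factors, "consolidate")
        logger.info("stage consolidate")
        for name, bundle in result.factors.items():
            _require(result, bundle.get("peaks"), "consolidate")
            lengths = result.genome.chrom_lengths
            extended = [
                extend_summits(pk, flank=config.summit_flank, chrom_lengths=lengths)
                for pk in bundle["peaks"]
            ]
            consolidated = []
            if len(extended) >= 2:
                consolidated = intersect_replicates(
                    extended[0], extended[1], final_width=config.peak_width,
                    chrom_lengths=lengths,
                )
            kept, report = filter_regions(
                consolidated,
                blacklist=result.blacklist,
                mappability=result.genome.mappability,
                map_min=config.mappability_min,
            )
            bundle["consolidated"] = kept
            bundle["filter_report"] = report
        summary = pd.DataFrame(
            [
                {
                    "factor": name,
                    "n_raw_intersections": b["filter_report"].n_input,
                    "n_blacklisted": b["filter_report"].n_blacklisted,
                    "n_low_mappability": b["filter_report"].n_low_mappability,
                    "n_final": b["filter_report"].n_kept,
                }
                for name, b in result.factors.items()
            ]
        )
        emit(
            "consolidation_summary.tsv",
            lambda p: summary.to_csv(p, sep="\t", index=False),
        )
        for name, bundle in result.factors.items():
            emit(
                f"consolidated_{name}.bed",
                lambda p, b=bundle: rio.write_bed3(
                    [pk.interval for pk in b["consolidated"]], p
                ),
            )

    if "annotate" in stages:
        if not result.factors or any(
            "consolidated" not in b for b in result.factors.values()
        ):
            raise RuntimeError("stage 'annotate' requires 'consolidate' outputs")
        logger.info("stage annotate")
        lengths = result.genome.chrom_lengths
        result.universe = build_universe(
            result.genome.genes,
            lengths,
            promoter_upstream=config.promoter_upstream,
            pseudo_locus_width=config.peak_width,
        )
        assignments = {}
        for name, bundle in result.factors.items():
            table = classify_peaks(
                bundle["consolidated"],
                result.universe,
                exclude_regions=spec.cluster_regions,
            )
            bundle["classified"] = table
            assignments[name] = table
        result.enrichment = enrichment_matrix(assignments, result.universe)
        emit(
            "enrichment_matrix.tsv",
            lambda p: result.enrichment.table.to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            ),
        )

    if "profile" in stages:
        _require(result, result.factors, "profile")
        logger.info("stage profile")
        genome = result.genome
        typed = classify_pirna_types(
            [
                (g.interval.chrom, int(g.attributes["first_u"]), g.interval.strand)
                for g in genome.pirna_genes()
            ],
            [
                (g.interval.chrom, int(g.attributes["first_u"]), g.interval.strand)
                for g in genome.pirna_genes("II")
            ],
            cluster_regions=spec.cluster_regions,
        )
        result.ruby_table = validate_ruby_upstream(typed, genome.sequences)
        emit(
            "ruby_upstream.tsv",
            lambda p: result.ruby_table.to_csv(p, sep="\t", index=False),
        )
        anchors_I = genome.first_u_anchors("I")
        curves = []
        for name, bundle in result.factors.items():
            if "normalized" not in bundle:
                raise RuntimeError("stage 'profile' requires 'normalize' outputs")
            mat = anchored_profile(
                bundle["normalized"],
                anchors_I,
                flank=config.profile_flank,
                bin_size=config.profile_bin,
            )
            bundle["profile_typeI"] = mat
            curve = aggregate_profile(mat)
            curve.insert(0, "factor", name)
            curves.append(curve)
        emit(
            "profile_typeI.tsv",
            lambda p: pd.concat(curves, ignore_index=True).to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            ),
        )

    if "quantify" in stages:
        _require(result, result.factors, "quantify")
        logger.info("stage quantify")
        quant_rows = []
        test_rows = []
        for name, bundle in result.factors.items():
            if "normalized" not in bundle:
                raise RuntimeError("stage 'quantify' requires 'normalize' outputs")
            quant = quantify_bins(
                bundle["normalized"],
                spec.cluster_regions,
                somatic_chromosomes=[
                    c for c, _ in spec.chromosomes if c != spec.cluster_chrom
                ],
                bin_size=config.quant_bin,
            )
            bundle["quant"] = quant
            for group, summ in quant.summaries.items():
                quant_rows.append(
                    {
                        "factor": name,
                        "group": group,
                        "n": summ.n,
                        "median": summ.median,
                        "q1": summ.q1,
                        "q3": summ.q3,
                        "notch_lo": summ.notch_lo,
                        "notch_hi": summ.notch_hi,
                    }
                )
            tests = quant.tests.copy()
            tests.insert(0, "factor", name)
            test_rows.append(tests)
        emit(
            "quantification_summary.tsv",
            lambda p: pd.DataFrame(quant_rows).to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            ),
        )
        emit(
            "quantification_tests.tsv",
            lambda p: pd.concat(test_rows, ignore_index=True).to_csv(
                p, sep="\t", index=False, float_format="%.6g"
            ),
        )

    result.manifest = {
        "config": json.loads(config.to_json()),
        "stages_run": list(stages),
        "files": files,
        "n_factors": len(result.factors),
        "elapsed_s": None,  # filled below; excluded from determinism hash
    }
    elapsed = time.time() - t0
    result.manifest["elapsed_s"] = round(elapsed, 3)
    if out is not None:
        stable = {k: v for k, v in result.manifest.items() if k != "elapsed_s"}
        (out / "manifest.json").write_text(json.dumps(stable, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs", elapsed)
    return result
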