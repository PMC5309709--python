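"""Run configuration, provenance manifest and end-to-end pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .genotype import ThresholdTable, write_genotype_tsv, write_histogram_tsv
from .pipeline import PipelineParams, run_sample
from .records import read_sam, write_fasta, write_sam
from .reference_model import load_panel_dir, write_panel_bundle
from .simulate import (FragmentationModel, StutterModel, build_synthetic_panel,
                       default_allele_freqs, draw_individual_genotypes,
                       generate_read_pairs)
from .snp_phase import SNPCallParams, write_haplotype_tsv, write_vcf


@dataclass
class RunConfig:
    """All tunables of a pipeline run, defaulting to the published parameters."""

    seed: int = 0
    out_dir: str = "strseq_out"
    panel_dir: str | None = None      # load an existing panel; else simulate one
    reads_sam: str | None = None      # load reads; else simulate them
    reference_fasta: str | None = None

    # simulation (used when panel_dir / reads_sam are absent)
    sim_n_loci: int = 20
    sim_coverage: int = 50
    sim_stutter_p: float = 0.032
    sim_stutter_p_del: float = 0.8
    sim_frag_mode: str = "crispr"
    sim_jitter_sd: float = 1.0
    sim_on_target_prob: float = 0.56
    sim_read_len: int = 150
    sim_base_error: float = 0.001

    # pipeline parameters (published defaults)
    probe_tolerance: int = 2
    cut_tolerance: int = 4
    mask_len: int = 40
    thresholds: dict = field(default_factory=lambda: ThresholdTable().as_dict())
    min_total_reads: int = 5
    require_both_strands: bool = False
    pvar: float = 0.05
    min_mapping_quality: int = 25
    min_base_quality: int = 15
    min_coverage: int = 3
    min_supporting_mapping_qsum: int = 90
    min_supporting_allele_qsum: int = 60
    thin: int = 6
    min_avg_alt_qual: float = 8.0
    parent_het_fraction: float = 0.15
    trio_min_cov: int = 10

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def pipeline_params(self) -> PipelineParams:
        return PipelineParams(
            probe_tolerance=self.probe_tolerance,
            cut_tolerance=self.cut_tolerance,
            thresholds=ThresholdTable.from_dict(
                {str(k): v for k, v in self.thresholds.items()}),
            min_total_reads=self.min_total_reads,
            require_both_strands=self.require_both_strands,
            snp_params=SNPCallParams(
                pvar=self.pvar,
                min_mapping_quality=self.min_mapping_quality,
                min_base_quality=self.min_base_quality,
                min_coverage=self.min_coverage,
                min_supporting_mapping_qsum=self.min_supporting_mapping_qsum,
                min_supporting_allele_qsum=self.min_supporting_allele_qsum,
            ),
            thin=self.thin,
            min_avg_alt_qual=self.min_avg_alt_qual,
        )


@dataclass
class RunManifest:
    """Per-stage provenance and attrition; counts never increase downstream."""

    version: str
    config_hash: str
    input_checksums: dict[str, str]
    pairs_in: int = 0
    pairs_tagged: int = 0
    str_spanning: int = 0
    loci_genotyped: int = 0
    on_target_fraction: float | None = None
    spanning_fraction: float | None = None

    def violations(self) -> list[str]:
        v = []
        if not self.pairs_in >= self.pairs_tagged >= self.str_spanning:
            v.append("stage counts are not monotonically non-increasing")
        return v

    def manifest_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({**dataclasses.asdict(self),
                       "manifest_hash": self.manifest_hash()}, fh, indent=2)
            fh.write("\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def read_fasta(path) -> dict[str, str]:
    refs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                refs[name] = []
            elif name is not None:
                refs[name].append(line)
    return {k: "".join(v) for k, v in refs.items()}


def run_pipeline(config: RunConfig):
    """Execute simulate -> index -> genotype -> haplotype and write all outputs.

    Returns ``(manifest, sample_results)``. Output stages are a pure function
    of (inputs, config, seed).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    checksums: dict[str, str] = {}

    try:
        if config.panel_dir is not None:
            panel = load_panel_dir(config.panel_dir)
            refs = read_fasta(config.reference_fasta)
            sp = None
        else:
            sp = build_synthetic_panel(config.sim_n_loci, seed=config.seed)
            panel, refs = sp.bundle, sp.refs
            panel_out = os.path.join(config.out_dir, "panel")
            write_panel_bundle(panel, panel_out)
            write_fasta(refs, os.path.join(config.out_dir, "genome.fa"))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("panel", exc) from exc

    try:
        if config.reads_sam is not None:
            pairs = read_sam(config.reads_sam)
            checksums[config.reads_sam] = _checksum(config.reads_sam)
        else:
            if sp is None:
                raise ValueError("reads_sam is required when panel_dir is given")
            truth = draw_individual_genotypes(
                sp, default_allele_freqs(sp), seed=config.seed + 1)
            pairs, _ = generate_read_pairs(
                truth, sp, coverage=config.sim_coverage,
                stutter=StutterModel(p_stutter=config.sim_stutter_p,
                                     p_deletion_given_stutter=config.sim_stutter_p_del),
                frag=FragmentationModel(mode=config.sim_frag_mode,
                                        jitter_sd=config.sim_jitter_sd,
                                        on_target_prob=config.sim_on_target_prob),
                read_len=config.sim_read_len, seed=config.seed + 2,
                base_error=config.sim_base_error)
            sam_path = os.path.join(config.out_dir, "reads.sam")
            write_sam(pairs, {c: len(s) for c, s in refs.items()}, sam_path)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("reads", exc) from exc

    try:
        results = run_sample(pairs, panel, refs, config.pipeline_params())
    except Exception as exc:
        raise StageError("analysis", exc) from exc

    try:
        write_genotype_tsv(results.genotype_calls, panel,
                           os.path.join(config.out_dir, "calls.tsv"))
        write_histogram_tsv(results.histograms,
                            os.path.join(config.out_dir, "histograms.tsv"))
        write_vcf(results.snp_calls, refs, os.path.join(config.out_dir, "snps.vcf"))
        write_haplotype_tsv(results.haplotype_calls.values(),
                            os.path.join(config.out_dir, "haplotypes.tsv"))
    except Exception as exc:
        raise StageError("outputs", exc) from exc

    tagged = len(results.tag_result.tagged)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        input_checksums=checksums,
        pairs_in=results.tag_result.n_input,
        pairs_tagged=tagged,
        str_spanning=results.filter_stats.accepted,
        loci_genotyped=len(results.genotype_calls),
        on_target_fraction=results.frag_summary.on_target_fraction,
        spanning_fraction=(results.filter_stats.accepted / tagged
                           if tagged else None),
    )
    manifest.write(os.path.join(config.out_dir, "manifest.json"))
    return manifest, results
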