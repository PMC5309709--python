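"""Single-sample orchestration: tag -> call SNPs -> measure repeats -> phase.

Stage order matters: SNP calls are made first (they only need masked Read 2
pileups) so that flank-variant alternates are available when repeat
extraction runs, mirroring the call-then-substitute design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import genotype as gt
from . import indexing, snp_phase
from .genotype import AlleleHistogram, GenotypeCall, ReadSTR, ThresholdTable
from .indexing import FragmentationSummary, TagResult
from .reference_model import PanelBundle
from .snp_phase import HaplotypeCall, PhasedCount, SNPCall, SNPCallParams


@dataclass
class PipelineParams:
    probe_tolerance: int = indexing.DEFAULT_PROBE_TOLERANCE
    cut_tolerance: int = indexing.DEFAULT_CUT_TOLERANCE
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    min_total_reads: int = gt.DEFAULT_MIN_TOTAL_READS
    require_both_strands: bool = False
    snp_params: SNPCallParams = field(default_factory=SNPCallParams)
    thin: int = 6
    min_avg_alt_qual: float = 8.0


@dataclass
class SampleResults:
    """Everything the cohort analyses need for one processed sample."""

    name: str
    tag_result: TagResult
    frag_summary: FragmentationSummary
    read_strs: list[ReadSTR]
    filter_stats: gt.FilterStats
    histograms: dict[str, AlleleHistogram]
    genotype_calls: dict[str, GenotypeCall]
    snp_calls: list[SNPCall]
    phased_counts: dict[tuple[str, int], PhasedCount]
    haplotype_calls: dict[tuple[str, int], HaplotypeCall]

    def haplotype_set(self) -> set[tuple[str, int, str, int]]:
        """All called (locus, snp_pos, base, repeats) tuples for this sample."""
        out = set()
        for (locus, pos), call in self.haplotype_calls.items():
            for base, rep in call.haplotypes:
                out.add((locus, pos, base, rep))
        return out


def run_sample(pairs, panel: PanelBundle, refs: dict[str, str],
               params: PipelineParams | None = None,
               name: str = "sample",
               snp_calls: list[SNPCall] | None = None) -> SampleResults:
    """Run the full per-sample pipeline over raw (untagged) read pairs.

    ``snp_calls`` optionally substitutes externally determined variant sites
    for this sample's own discovery — used when read-counting a mixture at
    sites called from the individual contributors, and when re-evaluating
    parents at a child's variant sites.
    """
    params = params or PipelineParams()

    tag_result = indexing.tag_read_pairs(pairs, panel, params.probe_tolerance)
    frag_summary = indexing.classify_fragmentation(
        tag_result.tagged, panel, params.cut_tolerance)

    raw_snp_calls = snp_phase.call_snps_pileup(
        tag_result.tagged, refs, intervals=None, params=params.snp_params)
    if snp_calls is None:
        snp_calls = snp_phase.filter_snps(
            raw_snp_calls, panel.exclusion_intervals,
            thin=params.thin, min_avg_alt_qual=params.min_avg_alt_qual)

    flank_variants = gt.flank_variant_sets(
        panel, [c for c in raw_snp_calls if c.passed])
    read_strs, filter_stats = gt.measure_reads(
        tag_result.tagged, panel, flank_variants)
    histograms = gt.build_histograms(read_strs)
    genotype_calls = gt.call_all(
        histograms, params.thresholds, params.min_total_reads,
        params.require_both_strands)

    phased_counts = snp_phase.link_reads_to_haplotypes(
        tag_result.tagged, read_strs, snp_calls, panel,
        min_base_quality=params.snp_params.min_base_quality)

    calls_by_pos = {(c.chrom, c.pos): c for c in snp_calls}
    haplotype_calls: dict[tuple[str, int], HaplotypeCall] = {}
    for (locus, pos), phased in phased_counts.items():
        call = calls_by_pos.get((phased.chrom, pos))
        if call is None:
            continue
        if call.genotype == "hom-alt":
            hap = snp_phase.call_haplotypes(phased, "hom", call.alt_base,
                                            params.thresholds)
        else:
            hap = snp_phase.call_haplotypes(phased, "het",
                                            (call.ref_base, call.alt_base),
                                            params.thresholds)
        if hap is not None:
            haplotype_calls[(locus, pos)] = hap

    return SampleResults(
        name=name, tag_result=tag_result, frag_summary=frag_summary,
        read_strs=read_strs, filter_stats=filter_stats, histograms=histograms,
        genotype_calls=genotype_calls, snp_calls=snp_calls,
        phased_counts=phased_counts, haplotype_calls=haplotype_calls,
    )
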