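"""Probe masking, pileup SNP calling, filtering, and STR-SNP haplotyping.

The SNP caller is a deliberate simplification of a Bayesian variant caller:
a frequency-and-quality pileup over probe-masked Read 2 alignments that
honours the filter cascade the method prescribes (pvar 0.05, substitutions
only, mapq >= 25, baseq >= 15, coverage >= 3, supporting mapping-quality sum
>= 90, supporting allele-quality sum >= 60), followed by exclusion-interval,
proximity-thinning and average-alt-quality filters. "PASS" means passing all
internal filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._util import IntervalSet
from .genotype import (DEFAULT_THRESHOLDS, AlleleHistogram, ThresholdTable,
                       call_str_genotype)
from .records import ReadPairRecord

log = logging.getLogger(__name__)

PROBE_MASK_LEN = 40


@dataclass
class SNPCallParams:
    pvar: float = 0.05
    min_mapping_quality: int = 25
    min_base_quality: int = 15
    min_coverage: int = 3
    min_supporting_mapping_qsum: int = 90
    min_supporting_allele_qsum: int = 60


@dataclass
class SNPCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    coverage: int
    ref_count: int
    alt_count: int
    ref_qual_sum: int
    alt_qual_sum: int
    genotype: str  # "het" | "hom-alt"
    passed: bool = True
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def allele_freqs(self) -> dict[str, float]:
        """Called allele frequencies; an absent allele has frequency 0."""
        informative = self.ref_count + self.alt_count
        if informative == 0:
            return {self.ref_base: 0.0, self.alt_base: 0.0}
        if self.genotype == "hom-alt":
            return {self.ref_base: 0.0, self.alt_base: 1.0}
        return {self.ref_base: self.ref_count / informative,
                self.alt_base: self.alt_count / informative}

    @property
    def avg_alt_qual(self) -> float:
        return self.alt_qual_sum / self.alt_count if self.alt_count else 0.0


def mask_probe_bases(record: ReadPairRecord,
                     n: int = PROBE_MASK_LEN) -> tuple[int, int]:
    """Usable aligned-index range [start, end) of Read 2 after probe masking.

    The first ``n`` sequenced bases are masked: for forward reads these are
    the first ``n`` aligned bases, for reverse reads the last ``n``. Reads
    shorter than ``n`` are fully masked.
    """
    length = len(record.r2_seq)
    if length <= n:
        if length < n:
            log.warning("read %s shorter than probe mask; fully masked",
                        record.pair_id)
        return (0, 0)
    if record.r2_strand == "-":
        return (0, length - n)
    return (n, length)


def call_snps_pileup(records, refs: dict[str, str], intervals=None,
                     params: SNPCallParams | None = None,
                     mask_len: int = PROBE_MASK_LEN) -> list[SNPCall]:
    """Biallelic substitution calls from a masked Read 2 pileup.

    ``intervals`` optionally restricts candidate positions (an
    :class:`IntervalSet` or None for everywhere). Sites failing a filter are
    returned with ``passed=False`` and reasons; indel/MNP evidence is never
    generated because only aligned substitution bases are piled up.
    """
    params = params or SNPCallParams()
    pile: dict[tuple[str, int], dict[str, list[int]]] = {}
    for rec in records:
        if rec.r2_mapq < params.min_mapping_quality:
            continue
        ustart, uend = mask_probe_bases(rec, mask_len)
        for i in range(ustart, uend):
            pos = rec.r2_pos + i
            if intervals is not None and not intervals.contains(rec.chrom, pos):
                continue
            base = rec.r2_seq[i]
            qual = ord(rec.r2_qual[i]) - 33
            if qual < params.min_base_quality or base not in "ACGT":
                continue
            site = pile.setdefault((rec.chrom, pos), {})
            entry = site.setdefault(base, [0, 0, 0])  # count, qual sum, mapq sum
            entry[0] += 1
            entry[1] += qual
            entry[2] += rec.r2_mapq

    calls = []
    for (chrom, pos), site in sorted(pile.items()):
        ref_base = refs[chrom][pos]
        alts = {b: v for b, v in site.items() if b != ref_base}
        if not alts:
            continue
        alt_base = max(alts, key=lambda b: alts[b][0])
        alt_count, alt_qsum, alt_mapqsum = alts[alt_base]
        ref_count, ref_qsum, _ = site.get(ref_base, [0, 0, 0])
        coverage = sum(v[0] for v in site.values())
        alt_frac = alt_count / coverage
        ref_frac = ref_count / coverage

        reasons = []
        if coverage < params.min_coverage:
            reasons.append("min_coverage")
        if alt_frac < params.pvar:
            reasons.append("pvar")
        if alt_mapqsum < params.min_supporting_mapping_qsum:
            reasons.append("min_supporting_mapping_qsum")
        if alt_qsum < params.min_supporting_allele_qsum:
            reasons.append("min_supporting_allele_qsum")
        genotype = "hom-alt" if ref_frac < params.pvar else "het"
        calls.append(SNPCall(
            chrom=chrom, pos=pos, ref_base=ref_base, alt_base=alt_base,
            coverage=coverage, ref_count=ref_count, alt_count=alt_count,
            ref_qual_sum=ref_qsum, alt_qual_sum=alt_qsum, genotype=genotype,
            passed=not reasons, fail_reasons=reasons,
        ))
    return calls


def filter_snps(calls, exclusion_intervals: IntervalSet | None = None,
                thin: int = 6, min_avg_alt_qual: float = 8.0) -> list[SNPCall]:
    """Apply the post-call cascade; returns the surviving calls.

    Removes non-PASS calls, calls inside the exclusion intervals (padded
    repeat tracts), any pair of calls closer than ``thin`` bases (both
    removed), and calls whose average alternate base quality is
    <= ``min_avg_alt_qual``.
    """
    kept = [c for c in calls if c.passed]
    if exclusion_intervals is not None:
        kept = [c for c in kept
                if not exclusion_intervals.contains(c.chrom, c.pos)]
    kept = [c for c in kept if c.avg_alt_qual > min_avg_alt_qual]

    kept.sort(key=lambda c: (c.chrom, c.pos))
    too_close = set()
    for a, b in zip(kept, kept[1:]):
        if a.chrom == b.chrom and b.pos - a.pos < thin:
            too_close.add((a.chrom, a.pos))
            too_close.add((b.chrom, b.pos))
    return [c for c in kept if (c.chrom, c.pos) not in too_close]


@dataclass
class PhasedCount:
    """Read counts per (SNP base, repeat count) for one locus/SNP pair."""

    locus: str
    chrom: str
    snp_pos: int
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def add(self, base: str, repeats: int):
        key = (base, repeats)
        self.counts[key] = self.counts.get(key, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def base_histogram(self, base: str) -> dict[int, int]:
        return {rep: n for (b, rep), n in self.counts.items() if b == base}


def link_reads_to_haplotypes(tagged_pairs, read_strs, snp_calls, panel,
                             min_base_quality: int = 15,
                             ) -> dict[tuple[str, int], PhasedCount]:
    """Accumulate (Read 2 SNP base, Read 1 repeat count) over intact-STR pairs.

    Pairs whose Read 2 base at the SNP is neither the called reference nor
    alternate allele, or carries an allele whose called frequency is 0, are
    dropped. Only SNP positions outside the Read 2 probe mask contribute.
    """
    repeats_by_pair = {r.pair_id: r for r in read_strs}
    calls_by_chrom: dict[str, list[SNPCall]] = {}
    for c in snp_calls:
        calls_by_chrom.setdefault(c.chrom, []).append(c)

    phased: dict[tuple[str, int], PhasedCount] = {}
    for pair in tagged_pairs:
        rstr = repeats_by_pair.get(pair.pair_id)
        if rstr is None or pair.zp is None:
            continue
        locus_name = panel.probe(pair.zp).str_name
        if rstr.locus != locus_name:
            continue
        ustart, uend = mask_probe_bases(pair)
        for call in calls_by_chrom.get(pair.chrom, []):
            off = call.pos - pair.r2_pos
            if not (ustart <= off < uend):
                continue
            base = pair.r2_seq[off]
            qual = ord(pair.r2_qual[off]) - 33
            if qual < min_base_quality:
                continue
            if base not in (call.ref_base, call.alt_base):
                continue
            if call.allele_freqs.get(base, 0.0) == 0.0:
                continue
            key = (locus_name, call.pos)
            if key not in phased:
                phased[key] = PhasedCount(locus=locus_name, chrom=pair.chrom,
                                          snp_pos=call.pos)
            phased[key].add(base, rstr.repeats)
    return phased


@dataclass
class HaplotypeCall:
    locus: str
    snp_pos: int
    haplotypes: tuple[tuple[str, int], ...]  # 1-2 (snp base, repeat count)
    support: dict[tuple[str, int], int]
    zygosity: str
    flags: list[str] = field(default_factory=list)

    @property
    def haplotype_set(self) -> frozenset[tuple[str, int]]:
        return frozenset(self.haplotypes)


def call_haplotypes(phased: PhasedCount, snp_genotype: str, snp_bases,
                    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                    ) -> HaplotypeCall | None:
    """Call 1-2 (SNP base, repeat count) haplotypes from phased counts.

    For a homozygous SNP the repeat margin is run through the genotype
    threshold logic (one passing secondary allele gives two haplotypes
    sharing the base). For a heterozygous SNP each base is paired with its
    majority repeat count.
    """
    if not phased.counts:
        return None
    flags: list[str] = []
    if snp_genotype == "hom-alt" or snp_genotype == "hom":
        base = snp_bases if isinstance(snp_bases, str) else snp_bases[0]
        margin = phased.base_histogram(base)
        if not margin:
            return None
        hist = AlleleHistogram(locus=phased.locus, fwd=dict(margin))
        call = call_str_genotype(hist, thresholds, min_total_reads=1)
        haps = tuple((base, a) for a in call.alleles)
        flags.extend(call.flags)
        zygosity = "het" if len(haps) == 2 else "hom"
    else:
        bases = tuple(snp_bases)
        haps_list = []
        for base in bases:
            margin = phased.base_histogram(base)
            if not margin:
                flags.append(f"no_reads_for_base_{base}")
                continue
            top = max(margin.values())
            at_top = sorted(k for k, v in margin.items() if v == top)
            if len(at_top) > 1:
                flags.append("repeat_tie")
            haps_list.append((base, at_top[0]))
        if not haps_list:
            return None
        if len(haps_list) == 1:
            flags.append("incomplete")
        haps = tuple(haps_list)
        zygosity = "het"
    support = {h: phased.counts.get(h, 0) for h in haps}
    return HaplotypeCall(locus=phased.locus, snp_pos=phased.snp_pos,
                         haplotypes=haps, support=support, zygosity=zygosity,
                         flags=flags)


def write_haplotype_tsv(hap_calls, path):
    with open(path, "w") as fh:
        fh.write("locus\tsnp_pos\tsnp_base\trepeats\tsupport\tzygosity\tflags\n")
        for call in sorted(hap_calls, key=lambda c: (c.locus, c.snp_pos)):
            for base, rep in call.haplotypes:
                fh.write(f"{call.locus}\t{call.snp_pos}\t{base}\t{rep}\t"
                         f"{call.support[(base, rep)]}\t{call.zygosity}\t"
                         f"{';'.join(call.flags)}\n")


def write_vcf(snp_calls, refs: dict[str, str], path, sample: str = "sample"):
    """Write passing SNP calls as a minimal uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in refs.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for c in sorted(snp_calls, key=lambda c: (c.chrom, c.pos)):
            gt = "1/1" if c.genotype == "hom-alt" else "0/1"
            filt = "PASS" if c.passed else ";".join(c.fail_reasons)
            fh.write(f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t"
                     f"{c.alt_qual_sum}\t{filt}\tDP={c.coverage}\tGT\t{gt}\n")
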