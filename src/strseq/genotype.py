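"""Flank-anchored repeat counting and stutter-aware diploid genotype calling.

A Read 1 is informative only if it contains the exact 15-base 5' flank,
a variable-length region, and the exact 15-base 3' flank of its indexed
locus. The variable region is divided by the motif length to obtain the
repeat count; per-locus histograms of repeat counts are then reduced to 1-2
allele diploid calls using fraction-of-major-allele thresholds keyed by the
allelic distance between a candidate secondary allele and the major allele:

    distance  -1    +1    <-1   >+1
    threshold 0.35  0.15  0.45  0.02

A candidate secondary allele is accepted iff its read count divided by the
major allele's read count meets the threshold of its distance class. The
``<-1`` threshold exceeding ``-1`` is intentional: multi-unit deletions are
both a common stutter mode and a signature of reads truncating long repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import ReadPairRecord
from .reference_model import PanelBundle, STRLocus

log = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL_READS = 5


@dataclass(frozen=True)
class ThresholdTable:
    """Secondary-allele read fractions keyed by allelic distance class."""

    minus1: float = 0.35
    plus1: float = 0.15
    lt_minus1: float = 0.45
    gt_plus1: float = 0.02

    def __post_init__(self):
        for v in (self.minus1, self.plus1, self.lt_minus1, self.gt_plus1):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")

    @staticmethod
    def distance_class(d: int) -> str:
        if d == -1:
            return "-1"
        if d == 1:
            return "+1"
        if d < -1:
            return "<-1"
        if d > 1:
            return ">+1"
        raise ValueError("allelic distance 0 has no class")

    def threshold(self, d: int) -> float:
        return {"-1": self.minus1, "+1": self.plus1,
                "<-1": self.lt_minus1, ">+1": self.gt_plus1}[self.distance_class(d)]

    def as_dict(self) -> dict[str, float]:
        return {"-1": self.minus1, "+1": self.plus1,
                "<-1": self.lt_minus1, ">+1": self.gt_plus1}

    @classmethod
    def from_dict(cls, d) -> "ThresholdTable":
        return cls(minus1=d["-1"], plus1=d["+1"],
                   lt_minus1=d["<-1"], gt_plus1=d[">+1"])


DEFAULT_THRESHOLDS = ThresholdTable()


@dataclass
class FlankVariants:
    """Accepted flank sequences per locus: reference + SNP-substituted alternates."""

    flank5: dict[str, set[str]] = field(default_factory=dict)
    flank3: dict[str, set[str]] = field(default_factory=dict)

    def for_locus(self, locus: STRLocus) -> tuple[set[str], set[str]]:
        return (self.flank5.get(locus.name, {locus.flank5}) | {locus.flank5},
                self.flank3.get(locus.name, {locus.flank3}) | {locus.flank3})


def flank_variant_sets(panel: PanelBundle, snp_calls) -> FlankVariants:
    """Enumerate single-substitution flank alternates from called flank SNPs.

    Only plain substitutions are applied (complex variants are excluded).
    ``snp_calls`` is an iterable with ``chrom``, ``pos``, ``ref_base`` and
    ``alt_base`` attributes.
    """
    fv = FlankVariants()
    for call in snp_calls:
        if len(call.ref_base) != 1 or len(call.alt_base) != 1:
            continue
        for ivset, table, attr in ((panel.flank5_intervals, fv.flank5, "flank5"),
                                   (panel.flank3_intervals, fv.flank3, "flank3")):
            iv = ivset.at(call.chrom, call.pos)
            if iv is None:
                continue
            locus = panel.locus(iv.name)
            ref_flank = getattr(locus, attr)
            off = call.pos - iv.start
            if ref_flank[off] != call.ref_base:
                log.warning("flank SNP at %s:%d disagrees with panel flank base",
                            call.chrom, call.pos)
                continue
            alt_flank = ref_flank[:off] + call.alt_base + ref_flank[off + 1:]
            table.setdefault(locus.name, set()).add(alt_flank)
    return fv


@dataclass
class FilterStats:
    """Read-level attrition tallies for the repeat-extraction step."""

    n_reads: int = 0
    missing_flank5: int = 0
    missing_flank3: int = 0
    below_min_repeats: int = 0
    non_integral: int = 0  # accepted, but variable region not a motif multiple
    accepted: int = 0


def _first_match(seq: str, variants: set[str], start: int = 0) -> tuple[int, str] | None:
    best = None
    for v in variants:
        i = seq.find(v, start)
        if i >= 0 and (best is None or i < best[0]):
            best = (i, v)
    return best


def extract_variable_region(r1_seq: str, locus: STRLocus,
                            flank_variants: FlankVariants | None = None,
                            stats: FilterStats | None = None) -> str | None:
    """Bases strictly between the first accepted 5' flank and the next 3' flank.

    Returns ``None`` (tallying the reason) if either flank is absent.
    """
    v5, v3 = (flank_variants or FlankVariants()).for_locus(locus)
    m5 = _first_match(r1_seq, v5)
    if m5 is None:
        if stats:
            stats.missing_flank5 += 1
        return None
    region_start = m5[0] + len(m5[1])
    m3 = _first_match(r1_seq, v3, region_start)
    if m3 is None:
        if stats:
            stats.missing_flank3 += 1
        return None
    return r1_seq[region_start:m3[0]]


@dataclass
class RepeatMeasurement:
    repeats: int
    exact: bool  # variable region length was an exact motif multiple


def count_motif_repeats(region: str, motif: str,
                        min_repeats: int) -> RepeatMeasurement | None:
    """floor(len(region)/len(motif)) after verifying min tandem motif copies."""
    if motif * min_repeats not in region:
        return None
    repeats = len(region) // len(motif)
    if repeats < min_repeats:
        return None
    return RepeatMeasurement(repeats=repeats, exact=len(region) % len(motif) == 0)


@dataclass
class AlleleHistogram:
    """Spanning-read counts per repeat count, split by Read 1 strand."""

    locus: str
    fwd: dict[int, int] = field(default_factory=dict)
    rev: dict[int, int] = field(default_factory=dict)

    def add(self, repeats: int, strand: str):
        table = self.fwd if strand != "-" else self.rev
        table[repeats] = table.get(repeats, 0) + 1

    @property
    def counts(self) -> dict[int, int]:
        merged = dict(self.fwd)
        for k, v in self.rev.items():
            merged[k] = merged.get(k, 0) + v
        return merged

    @property
    def total(self) -> int:
        return sum(self.fwd.values()) + sum(self.rev.values())

    def both_strand_support(self, repeats: int) -> bool:
        return self.fwd.get(repeats, 0) > 0 and self.rev.get(repeats, 0) > 0


@dataclass
class ReadSTR:
    """Per-read accepted repeat measurement (consumed by the phasing stage)."""

    pair_id: str
    locus: str
    repeats: int
    strand: str


def measure_reads(tagged_pairs, panel: PanelBundle,
                  flank_variants: FlankVariants | None = None,
                  ) -> tuple[list[ReadSTR], FilterStats]:
    """Run flank extraction + repeat counting over every tagged pair."""
    stats = FilterStats()
    out = []
    for pair in tagged_pairs:
        if pair.zp is None:
            continue
        locus = panel.locus(panel.probe(pair.zp).str_name)
        stats.n_reads += 1
        region = extract_variable_region(pair.r1_seq, locus, flank_variants, stats)
        if region is None:
            continue
        meas = count_motif_repeats(region, locus.motif, locus.min_repeats)
        if meas is None:
            stats.below_min_repeats += 1
            continue
        if not meas.exact:
            stats.non_integral += 1
        stats.accepted += 1
        out.append(ReadSTR(pair.pair_id, locus.name, meas.repeats,
                           pair.r1_strand or "+"))
    return out, stats


def build_histograms(read_strs) -> dict[str, AlleleHistogram]:
    hists: dict[str, AlleleHistogram] = {}
    for r in read_strs:
        hists.setdefault(r.locus, AlleleHistogram(r.locus)).add(r.repeats, r.strand)
    return hists


def build_allele_histogram(tagged_pairs, locus: STRLocus, panel: PanelBundle,
                           flank_variants: FlankVariants | None = None,
                           ) -> AlleleHistogram | None:
    """Histogram for a single locus; ``None`` when no read is accepted."""
    reads, _ = measure_reads(
        (p for p in tagged_pairs
         if p.zp is not None and panel.probe(p.zp).str_name == locus.name),
        panel, flank_variants)
    if not reads:
        return None
    return build_histograms(reads)[locus.name]


@dataclass
class GenotypeCall:
    locus: str
    alleles: tuple[int, ...]  # 1 (hom) or 2 (het) repeat counts
    zygosity: str             # "hom" | "het"
    major_allele: int
    support: dict[int, int]
    total: int
    stutter_fraction: float
    flags: list[str] = field(default_factory=list)

    @property
    def allele_set(self) -> frozenset[int]:
        return frozenset(self.alleles)


def call_str_genotype(hist: AlleleHistogram,
                      thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
                      min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
                      require_both_strands: bool = False,
                      ) -> GenotypeCall | None:
    """Call a 1-2 allele diploid genotype from a repeat-count histogram.

    The most-supported repeat count is the major allele; every other count is
    a candidate secondary allele that passes iff count/major_count meets the
    threshold of its allelic-distance class. The best passing candidate
    (highest count, then smaller |distance|, then shorter allele) joins the
    call as heterozygous. Returns ``None`` below ``min_total_reads``.
    """
    counts = hist.counts
    if require_both_strands:
        counts = {k: v for k, v in counts.items() if hist.both_strand_support(k)}
    total_all = hist.total
    if total_all < min_total_reads or not counts:
        return None

    flags = []
    max_count = max(counts.values())
    at_max = sorted(k for k, v in counts.items() if v == max_count)
    major = at_max[0]  # tie -> shorter repeat (deletion-biased stutter)
    if len(at_max) > 1:
        flags.append("major_tie")

    passing = []
    for allele, count in counts.items():
        if allele == major:
            continue
        d = allele - major
        if count / max_count >= thresholds.threshold(d):
            passing.append((count, -abs(d), -allele, allele))
    if passing:
        passing.sort(reverse=True)
        secondary = passing[0][3]
        alleles = (major, secondary)
        zygosity = "het"
        if len(passing) > 1:
            flags.append("multiple_passing_candidates")
    else:
        alleles = (major,)
        zygosity = "hom"

    called = set(alleles)
    stutter = (total_all - sum(hist.counts.get(a, 0) for a in called)) / total_all
    return GenotypeCall(
        locus=hist.locus, alleles=alleles, zygosity=zygosity, major_allele=major,
        support={a: hist.counts.get(a, 0) for a in alleles}, total=total_all,
        stutter_fraction=stutter, flags=flags,
    )


def stutter_fraction(hist: AlleleHistogram, call: GenotypeCall) -> float:
    """Non-allelic spanning reads over all spanning reads."""
    total = hist.total
    allelic = sum(hist.counts.get(a, 0) for a in set(call.alleles))
    return (total - allelic) / total if total else 0.0


@dataclass
class DosageValue:
    locus: str
    dosage_bp: int


def str_dosage(call: GenotypeCall, locus: STRLocus) -> DosageValue:
    """Signed bp dosage: sum over both allele copies of (allele_bp - ref_bp).

    A homozygous call contributes its single allele twice.
    """
    motif_len = len(locus.motif)
    alleles = call.alleles if len(call.alleles) == 2 else call.alleles * 2
    dosage = sum(a * motif_len - locus.ref_repeat_len_bp for a in alleles)
    return DosageValue(locus=locus.name, dosage_bp=dosage)


@dataclass
class ROCPoint:
    distance_class: str
    threshold: float
    sensitivity: float
    false_call_rate: float


def calibrate_thresholds(cases, controls, max_false_positive: float = 0.01,
                         ) -> tuple[ThresholdTable, list[ROCPoint]]:
    """Calibrate per-distance-class thresholds from labeled histograms.

    ``cases`` are ``(histogram, true_secondary_allele)`` pairs with known
    heterozygous truth; ``controls`` are histograms with known homozygous
    truth. For each class the smallest fraction threshold whose control
    false-call rate is <= ``max_false_positive`` is chosen, which maximizes
    sensitivity subject to that constraint. Classes with no cases are
    omitted (the shipped default is kept) with a warning.
    """
    case_fracs: dict[str, list[float]] = {c: [] for c in ("-1", "+1", "<-1", ">+1")}
    ctrl_fracs: dict[str, list[float]] = {c: [] for c in ("-1", "+1", "<-1", ">+1")}

    for hist, secondary in cases:
        counts = hist.counts
        major = max(sorted(counts), key=lambda k: (counts[k], -k))
        if secondary == major or secondary not in counts:
            continue
        cls = ThresholdTable.distance_class(secondary - major)
        case_fracs[cls].append(counts[secondary] / counts[major])
    for hist in controls:
        counts = hist.counts
        major = max(sorted(counts), key=lambda k: (counts[k], -k))
        best: dict[str, float] = {}
        for allele, count in counts.items():
            if allele == major:
                continue
            cls = ThresholdTable.distance_class(allele - major)
            frac = count / counts[major]
            best[cls] = max(best.get(cls, 0.0), frac)
        for cls, frac in best.items():
            ctrl_fracs[cls].append(frac)

    chosen = dict(DEFAULT_THRESHOLDS.as_dict())
    roc: list[ROCPoint] = []
    for cls in ("-1", "+1", "<-1", ">+1"):
        cf, xf = case_fracs[cls], ctrl_fracs[cls]
        if not cf:
            log.warning("threshold class %s has no cases; keeping default", cls)
            continue
        n_ctrl = len(controls)
        candidates = sorted(set(cf) | set(xf))
        picked = None
        for t in candidates:
            fpr = sum(1 for f in xf if f >= t) / n_ctrl if n_ctrl else 0.0
            sens = sum(1 for f in cf if f >= t) / len(cf)
            roc.append(ROCPoint(cls, t, sens, fpr))
            if picked is None and fpr <= max_false_positive:
                picked = t
        if picked is not None:
            chosen[cls] = min(1.0, picked)
    return ThresholdTable.from_dict(chosen), roc


def call_all(hists: dict[str, AlleleHistogram],
             thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
             min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
             require_both_strands: bool = False) -> dict[str, GenotypeCall]:
    calls = {}
    for name, hist in hists.items():
        call = call_str_genotype(hist, thresholds, min_total_reads,
                                 require_both_strands)
        if call is not None:
            calls[name] = call
    return calls


def write_genotype_tsv(calls: dict[str, GenotypeCall], panel: PanelBundle, path):
    with open(path, "w") as fh:
        fh.write("locus\talleles\tzygosity\tmajor_allele\tsupport\ttotal\t"
                 "stutter_fraction\tdosage_bp\tflags\n")
        for name in sorted(calls):
            call = calls[name]
            locus = panel.locus(name)
            dosage = str_dosage(call, locus).dosage_bp
            alleles = ",".join(str(a) for a in sorted(call.alleles))
            support = ",".join(f"{a}:{c}" for a, c in sorted(call.support.items()))
            fh.write(f"{name}\t{alleles}\t{call.zygosity}\t{call.major_allele}\t"
                     f"{support}\t{call.total}\t{call.stutter_fraction:.4f}\t"
                     f"{dosage}\t{';'.join(call.flags)}\n")


def read_genotype_tsv(path) -> dict[str, GenotypeCall]:
    """Parse a genotype TSV written by :func:`write_genotype_tsv`."""
    calls = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < len(header):
                continue
            alleles = tuple(int(a) for a in p[idx["alleles"]].split(","))
            support = {}
            for item in p[idx["support"]].split(","):
                a, _, c = item.partition(":")
                support[int(a)] = int(c)
            calls[p[idx["locus"]]] = GenotypeCall(
                locus=p[idx["locus"]], alleles=alleles,
                zygosity=p[idx["zygosity"]],
                major_allele=int(p[idx["major_allele"]]), support=support,
                total=int(p[idx["total"]]),
                stutter_fraction=float(p[idx["stutter_fraction"]]),
                flags=[f for f in p[idx["flags"]].split(";") if f],
            )
    return calls


def write_histogram_tsv(hists: dict[str, AlleleHistogram], path):
    with open(path, "w") as fh:
        fh.write("locus\trepeats\tn_fwd\tn_rev\n")
        for name in sorted(hists):
            h = hists[name]
            for rep in sorted(set(h.fwd) | set(h.rev)):
                fh.write(f"{name}\t{rep}\t{h.fwd.get(rep, 0)}\t{h.rev.get(rep, 0)}\n")
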