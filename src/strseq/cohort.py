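"""Cross-sample analyses: CE concordance, trios, informative haplotypes, mixtures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy import stats as sps

from .genotype import GenotypeCall
from .pipeline import SampleResults
from .reference_model import PanelBundle

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# capillary-electrophoresis concordance with per-locus median offset correction

@dataclass
class CEComparison:
    #: locus -> median offset (repeat units) between sequencing and CE calls
    offsets: dict[str, float]
    #: sample -> fraction of compared loci concordant after offset correction
    concordance: dict[str, float]
    #: (ce_dosage_bp, seq_dosage_bp) pairs for regression diagnostics
    dosage_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def overall_concordance(self) -> float:
        total = sum(self._n_compared.values())
        agree = sum(round(f * n) for f, n in
                    zip(self.concordance.values(), self._n_compared.values()))
        return agree / total if total else float("nan")

    _n_compared: dict[str, int] = field(default_factory=dict)


def _sorted_alleles(call: GenotypeCall) -> tuple[int, int]:
    alleles = call.alleles if len(call.alleles) == 2 else call.alleles * 2
    return tuple(sorted(alleles))


def ce_offset_concordance(seq_calls: dict[str, dict[str, GenotypeCall]],
                          ce_calls: dict[str, dict[str, tuple[int, int]]],
                          panel: PanelBundle) -> CEComparison:
    """Compare sequencing genotypes with CE genotypes after offset correction.

    ``seq_calls``: sample -> locus -> call (repeat units).
    ``ce_calls``: sample -> locus -> (allele1_bp, allele2_bp).
    Per locus, the offset is the median over samples of the positional
    differences between ascending-sorted sequencing and CE repeat counts; it
    is subtracted from sequencing alleles before the equality test. Loci
    absent from the CE table are skipped.
    """
    per_locus_offsets: dict[str, list[float]] = {}
    for sample, calls in seq_calls.items():
        ce_sample = ce_calls.get(sample, {})
        for locus_name, call in calls.items():
            if locus_name not in ce_sample:
                continue
            motif_len = len(panel.locus(locus_name).motif)
            ce = tuple(sorted(bp / motif_len for bp in ce_sample[locus_name]))
            seq = _sorted_alleles(call)
            for s, c in zip(seq, ce):
                per_locus_offsets.setdefault(locus_name, []).append(s - c)

    offsets = {name: median(vals) for name, vals in per_locus_offsets.items()}

    concordance: dict[str, float] = {}
    n_compared: dict[str, int] = {}
    dosage_pairs: list[tuple[int, int]] = []
    for sample, calls in seq_calls.items():
        ce_sample = ce_calls.get(sample, {})
        n = agree = 0
        for locus_name, call in calls.items():
            if locus_name not in ce_sample or locus_name not in offsets:
                continue
            locus = panel.locus(locus_name)
            motif_len = len(locus.motif)
            ce = tuple(sorted(bp / motif_len for bp in ce_sample[locus_name]))
            seq = tuple(a - offsets[locus_name] for a in _sorted_alleles(call))
            n += 1
            if all(abs(s - c) < 1e-9 for s, c in zip(seq, ce)):
                agree += 1
            ce_dosage = sum(int(round(c * motif_len)) - locus.ref_repeat_len_bp
                            for c in ce)
            seq_dosage = sum(a * motif_len - locus.ref_repeat_len_bp
                             for a in _sorted_alleles(call))
            dosage_pairs.append((ce_dosage, seq_dosage))
        if n:
            concordance[sample] = agree / n
            n_compared[sample] = n

    cmp_ = CEComparison(offsets=offsets, concordance=concordance,
                        dosage_pairs=dosage_pairs)
    cmp_._n_compared = n_compared
    return cmp_


def read_ce_table(path) -> dict[str, dict[str, tuple[int, int]]]:
    """TSV columns: sample, locus, allele1_bp, allele2_bp."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            p = line.rstrip("\n").split("\t")
            if len(p) < 4:
                continue
            out.setdefault(p[idx["sample"]], {})[p[idx["locus"]]] = (
                int(p[idx["allele1_bp"]]), int(p[idx["allele2_bp"]]))
    return out


# ---------------------------------------------------------------------------
# trio Mendelian concordance

@dataclass
class TrioReport:
    genotype_status: dict[str, bool]                    # locus -> explained
    haplotype_status: dict[tuple[str, int], bool]       # (locus, snp) -> explained
    genotype_concordance: float
    haplotype_concordance: float


def _genotype_explained(child: GenotypeCall, father: GenotypeCall,
                        mother: GenotypeCall) -> bool:
    ca = child.alleles if len(child.alleles) == 2 else child.alleles * 2
    fa, ma = set(father.alleles), set(mother.alleles)
    return ((ca[0] in fa and ca[1] in ma) or (ca[1] in fa and ca[0] in ma))


def _parent_haplotypes(parent: SampleResults, locus: str, pos: int,
                       child_snp, parent_het_fraction: float,
                       ) -> set[tuple[str, int]] | None:
    """Parent haplotype set re-evaluated at the child's variant site.

    The parent is considered to carry a SNP base if that base accounts for at
    least ``parent_het_fraction`` of its phased reads at the position; each
    carried base is paired with its majority repeat count.
    """
    from .genotype import AlleleHistogram, call_str_genotype

    phased = parent.phased_counts.get((locus, pos))
    if phased is None or phased.total == 0:
        return None
    total = phased.total
    present = []
    for base in (child_snp.ref_base, child_snp.alt_base):
        margin = phased.base_histogram(base)
        if margin and sum(margin.values()) / total >= parent_het_fraction:
            present.append((base, margin))
    haps = set()
    if len(present) == 2:
        # SNP-heterozygous parent: majority repeat per base
        for base, margin in present:
            top = max(margin.values())
            haps.add((base, min(k for k, v in margin.items() if v == top)))
    elif len(present) == 1:
        # SNP-homozygous parent: repeat margin through the threshold logic
        base, margin = present[0]
        call = call_str_genotype(AlleleHistogram(locus=locus, fwd=dict(margin)),
                                 min_total_reads=1)
        haps = {(base, a) for a in call.alleles}
    return haps or None


def trio_concordance(child: SampleResults, father: SampleResults,
                     mother: SampleResults,
                     parent_het_fraction: float = 0.15,
                     min_cov: int = 10) -> TrioReport:
    """Mendelian concordance of genotypes and STR-SNP haplotypes.

    Haplotype loci qualify only when all three members have >= ``min_cov``
    phased reads at the SNP. A child's 1-2 haplotypes are concordant iff they
    partition into one explained by each parent; a homozygous child haplotype
    must be present in both parents.
    """
    genotype_status: dict[str, bool] = {}
    for locus, call in child.genotype_calls.items():
        f = father.genotype_calls.get(locus)
        m = mother.genotype_calls.get(locus)
        if f is None or m is None:
            continue
        genotype_status[locus] = _genotype_explained(call, f, m)

    calls_by_pos = {(c.chrom, c.pos): c for c in child.snp_calls}
    haplotype_status: dict[tuple[str, int], bool] = {}
    for (locus, pos), hap_call in child.haplotype_calls.items():
        phased_child = child.phased_counts.get((locus, pos))
        child_snp = calls_by_pos.get((phased_child.chrom, pos)) if phased_child else None
        if child_snp is None:
            continue
        covs = [phased_child.total]
        for parent in (father, mother):
            pc = parent.phased_counts.get((locus, pos))
            covs.append(pc.total if pc else 0)
        if min(covs) < min_cov:
            continue
        fh = _parent_haplotypes(father, locus, pos, child_snp, parent_het_fraction)
        mh = _parent_haplotypes(mother, locus, pos, child_snp, parent_het_fraction)
        if fh is None or mh is None:
            haplotype_status[(locus, pos)] = False
            continue
        haps = hap_call.haplotypes
        if len(haps) == 1:
            ok = haps[0] in fh and haps[0] in mh
        else:
            ok = ((haps[0] in fh and haps[1] in mh)
                  or (haps[1] in fh and haps[0] in mh))
        haplotype_status[(locus, pos)] = ok

    def _frac(status):
        return (sum(status.values()) / len(status)) if status else float("nan")

    return TrioReport(
        genotype_status=genotype_status, haplotype_status=haplotype_status,
        genotype_concordance=_frac(genotype_status),
        haplotype_concordance=_frac(haplotype_status),
    )


# ---------------------------------------------------------------------------
# informative haplotypes and mixture quantification

def union_snp_calls(call_sets) -> list:
    """Union of per-contributor SNP calls (one per site, heterozygous wins).

    Mixture read-counting uses sites determined from the individual samples,
    so alleles carried only by a small minor component are not lost to the
    mixture's own discovery thresholds. A heterozygous call is preferred so
    both alleles keep a nonzero called frequency.
    """
    merged = {}
    for calls in call_sets:
        for c in calls:
            key = (c.chrom, c.pos)
            prev = merged.get(key)
            if prev is None or (prev.genotype != "het" and c.genotype == "het"):
                merged[key] = c
    return sorted(merged.values(), key=lambda c: (c.chrom, c.pos))


def informative_haplotypes(minor: SampleResults,
                           majors) -> set[tuple[str, int, str, int]]:
    """Haplotypes present in the minor sample and absent from every major one."""
    if isinstance(majors, SampleResults):
        majors = [majors]
    minor_set = minor.haplotype_set()
    major_union = set()
    for m in majors:
        major_union |= m.haplotype_set()
    return minor_set - major_union


@dataclass
class HaplotypeObservation:
    locus: str
    snp_pos: int
    base: str
    repeats: int
    support: int
    locus_total: int
    observed_fraction: float | None
    expected_fraction: float | None
    detected: bool


@dataclass
class MixtureReport:
    observations: list[HaplotypeObservation]
    #: slope/intercept/r2 of log10(observed) ~ log10(expected), if computable
    regression: dict[str, float] | None = None

    @property
    def n_detected(self) -> int:
        return sum(1 for o in self.observations if o.detected)

    def mean_observed_fraction(self) -> float:
        fracs = [o.observed_fraction for o in self.observations
                 if o.observed_fraction is not None]
        return float(np.mean(fracs)) if fracs else float("nan")


def mixture_quantification(mixture: SampleResults,
                           informative: set[tuple[str, int, str, int]],
                           minor_fraction: float | None = None,
                           minor_zygosity: dict | None = None,
                           min_reads: int = 2) -> MixtureReport:
    """Quantify minor-unique haplotypes in a processed mixture sample.

    The observed fraction of an informative haplotype is its supporting read
    count over all phased reads at its (locus, SNP). When ``minor_fraction``
    is given, the expected fraction is ``minor_fraction/2`` for haplotypes
    the minor contributor carries heterozygously and ``minor_fraction`` for
    homozygous ones (``minor_zygosity`` maps haplotype tuples to "hom"/"het";
    default heterozygous). A haplotype is detected iff support >=
    ``min_reads``.
    """
    observations = []
    for (locus, pos, base, rep) in sorted(informative):
        phased = mixture.phased_counts.get((locus, pos))
        total = phased.total if phased else 0
        support = phased.counts.get((base, rep), 0) if phased else 0
        observed = support / total if total else None
        expected = None
        if minor_fraction is not None:
            zyg = (minor_zygosity or {}).get((locus, pos, base, rep), "het")
            expected = minor_fraction if zyg == "hom" else minor_fraction / 2.0
        observations.append(HaplotypeObservation(
            locus=locus, snp_pos=pos, base=base, repeats=rep, support=support,
            locus_total=total, observed_fraction=observed,
            expected_fraction=expected,
            detected=support >= min_reads,
        ))

    regression = None
    pts = [(o.expected_fraction, o.observed_fraction) for o in observations
           if o.expected_fraction and o.observed_fraction]
    if len(pts) >= 3 and len({p[0] for p in pts}) >= 2:
        x = np.log10([p[0] for p in pts])
        y = np.log10([p[1] for p in pts])
        fit = sps.linregress(x, y)
        regression = {"slope": fit.slope, "intercept": fit.intercept,
                      "r2": fit.rvalue ** 2}
    return MixtureReport(observations=observations, regression=regression)


def heterozygous_allele_fractions(sample: SampleResults) -> list[float]:
    """Observed major-allele read fraction of each heterozygous genotype call."""
    fracs = []
    for call in sample.genotype_calls.values():
        if call.zygosity != "het":
            continue
        a, b = call.alleles
        na, nb = call.support[a], call.support[b]
        if na + nb:
            fracs.append(max(na, nb) / (na + nb))
    return fracs
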