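"""Synthetic panels, individuals, trios, mixtures and paired-end reads.

The simulator generates data with the statistical structure the pipeline
assumes: Read 2 starts with a 40-mer primer probe at its expected alignment
position, Read 1 spans (when the fragment allows) the 15-base 5' flank, the
repeat tract and the 15-base 3' flank, stutter is deletion-biased, and
fragment ends cluster at guide-RNA cut sites under CRISPR fragmentation or
scatter uniformly under random fragmentation. Emitted alignment records are
truth-placed, so no external aligner is needed.

Synthetic locus geometry (one contig per locus, all coordinates 0-based):

    [0,30)  pad | [30,70) plus probe | SNP | [S-15,S) flank5 | [S,E) tract |
    [E,E+15) flank3 | cut/SNP gap | minus probe | pad

with an upstream cut site at 40, a downstream cut site at E+25, one SNP
upstream of the tract (covered by plus-probe Read 2s) and one downstream
(covered by minus-probe Read 2s). Probes sit entirely outside the region a
Read 2 shares with the tract, so truth-placed records need only match-only
CIGARs. Allele lengths are capped at MAX_ALLELE_BP so every on-target
fragment spans the full repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import DNA_ALPHABET, Interval, IntervalSet, revcomp
from .records import ReadPairRecord
from .reference_model import (FLANK_LEN, PROBE_LEN, GRNACutSite, PanelBundle,
                              ProbeDef, STRLocus)

log = logging.getLogger(__name__)

# contig layout constants (see module docstring)
_PAD5 = 30
_PLUS_PROBE_AT = 30
_CUT5_AT = 40
_SNP5_OFF = 8        # snp5 = plus probe end + 8
_GAP1 = 10           # probe end -> flank5 start
_CUT3_OFF = 25       # cut3 = tract flank3 start + 25 (10 b past flank3 end)
_SNP3_OFF = 30
_MINUS_PROBE_OFF = 45
_PAD3 = 20

MAX_ALLELE_BP = 40
DEFAULT_READ_LEN = 150
DEFAULT_R2_LEN = 60
DEFAULT_BASE_QUAL = 35
DEFAULT_BASE_ERROR = 0.001

#: per-read stutter probability defaults echoing the PCR vs amplification-free
#: median stutter fractions (3.2% vs 0.9%); stand-ins, fully configurable.
PCR_STUTTER_P = 0.032
PCR_FREE_STUTTER_P = 0.009


@dataclass
class StutterModel:
    """Deletion-biased, geometric-tailed repeat-count slippage noise."""

    p_stutter: float = PCR_STUTTER_P
    p_deletion_given_stutter: float = 0.8
    step_decay: float = 0.1  # P(|step| = k) ~ (1 - step_decay) * step_decay**(k-1)

    def __post_init__(self):
        for p in (self.p_stutter, self.p_deletion_given_stutter):
            if not 0.0 <= p <= 1.0:
                raise ValueError("stutter probabilities must lie in [0, 1]")
        if not 0.0 <= self.step_decay < 1.0:
            raise ValueError("step_decay must lie in [0, 1)")

    def perturb(self, n: int, rng: np.random.Generator) -> int:
        """Observed repeat count for a template with ``n`` true repeats."""
        if rng.random() >= self.p_stutter:
            return n
        sign = -1 if rng.random() < self.p_deletion_given_stutter else 1
        mag = int(rng.geometric(1.0 - self.step_decay)) if self.step_decay > 0 else 1
        return max(1, n + sign * mag)

    @classmethod
    def off(cls) -> "StutterModel":
        return cls(p_stutter=0.0)


@dataclass
class FragmentationModel:
    """CRISPR (cut-site-anchored) or random fragment-end placement."""

    mode: str = "crispr"  # crispr | random
    jitter_sd: float = 1.0
    on_target_prob: float = 0.56

    def __post_init__(self):
        if self.mode not in ("crispr", "random"):
            raise ValueError(f"unknown fragmentation mode {self.mode!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.on_target_prob <= 1.0:
            raise ValueError("on_target_prob must lie in [0, 1]")


@dataclass
class SyntheticPanel:
    """A generated panel bundle plus its reference sequences and SNP truth."""

    bundle: PanelBundle
    refs: dict[str, str]
    #: (locus_name, pos) -> (ref_base, alt_base) for every designed SNP
    snp_defs: dict[tuple[str, int], tuple[str, str]]

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.refs.items()}


@dataclass
class IndividualTruth:
    """Phased diploid truth for one individual: repeat counts and SNP bases."""

    name: str
    #: locus -> (repeats on haplotype 0, repeats on haplotype 1)
    genotypes: dict[str, tuple[int, int]]
    #: (locus, pos) -> (base on haplotype 0, base on haplotype 1)
    snp_bases: dict[tuple[str, int], tuple[str, str]]

    def haplotypes(self, locus: str) -> list[dict]:
        """The two phased haplotypes of ``locus`` as {repeats, snps} dicts."""
        out = []
        for h in (0, 1):
            snps = {key: bases[h] for key, bases in self.snp_bases.items()
                    if key[0] == locus}
            out.append({"repeats": self.genotypes[locus][h], "snps": snps})
        return out


@dataclass
class ReadTruth:
    """Per-read simulation provenance."""

    pair_id: str
    individual: str
    locus: str
    hap: int
    true_repeats: int
    obs_repeats: int
    probe_id: int
    spans: bool
    frag_pos: int
    stuttered: bool


@dataclass
class MixtureTruth:
    fractions: dict[str, float]
    reads: list[ReadTruth] = field(default_factory=list)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=n))


def _motif_ok(motif: str) -> bool:
    # reject motifs that are a repetition of a shorter unit (e.g. ATAT)
    for k in range(1, len(motif)):
        if len(motif) % k == 0 and motif[:k] * (len(motif) // k) == motif:
            return False
    return True


def _flanks_clean(flank5: str, flank3: str, motif: str, pre: str, post: str) -> bool:
    """Flank occurrences must be unambiguous in any read built from this locus."""
    tract = motif * (MAX_ALLELE_BP // len(motif) + 12)
    if flank5 in pre or flank5 in tract + flank3 + post:
        return False
    if flank3 in pre + flank5 + tract or flank3 in post:
        return False
    # a flank5 suffix must not combine with tract bases to re-create flank5 etc.
    read_space = pre + flank5 + tract + flank3 + post
    if read_space.count(flank5) != 1 or read_space.count(flank3) != 1:
        return False
    return True


def build_synthetic_panel(n_loci: int, motif_length_distribution=None, seed=0,
                          max_attempts: int = 200) -> SyntheticPanel:
    """Generate ``n_loci`` synthetic loci, two probes and two cut sites each.

    ``motif_length_distribution`` maps motif length (1-6) to probability;
    default is uniform over 2-5. Deterministic under ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if motif_length_distribution is None:
        motif_length_distribution = {2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25}
    lens = sorted(motif_length_distribution)
    probs = np.array([motif_length_distribution[k] for k in lens], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    loci, probes, cut_sites = [], [], []
    refs: dict[str, str] = {}
    snp_defs: dict[tuple[str, int], tuple[str, str]] = {}
    f5_ivs, f3_ivs, excl_ivs = [], [], []
    seen_flanks: set[str] = set()
    probe_id = 1

    for i in range(n_loci):
        name = f"trf{i + 1:06d}"
        chrom = f"ctg{i + 1:06d}"
        for attempt in range(max_attempts):
            m = int(rng.choice(lens, p=probs))
            motif = _rand_seq(rng, m)
            if not _motif_ok(motif):
                continue
            r0 = int(rng.integers(5, max(6, min(24, MAX_ALLELE_BP // m) + 1)))
            tract = motif * r0
            flank5, flank3 = _rand_seq(rng, FLANK_LEN), _rand_seq(rng, FLANK_LEN)
            pre = _rand_seq(rng, _PAD5) + _rand_seq(rng, PROBE_LEN) + _rand_seq(rng, _GAP1)
            gap3 = _rand_seq(rng, _MINUS_PROBE_OFF - FLANK_LEN)
            post = gap3 + _rand_seq(rng, PROBE_LEN) + _rand_seq(rng, _PAD3)
            if flank5 in seen_flanks or flank3 in seen_flanks or flank5 == flank3:
                continue
            if not _flanks_clean(flank5, flank3, motif, pre, post):
                continue
            contig = pre + flank5 + tract + flank3 + post
            S = len(pre) + FLANK_LEN
            E = S + len(tract)
            snp5 = _PLUS_PROBE_AT + PROBE_LEN + _SNP5_OFF
            snp3 = E + _SNP3_OFF
            locus = STRLocus(name=name, motif=motif, chrom=chrom, start=S, end=E,
                             min_repeats=min(3, r0), flank5=flank5, flank3=flank3,
                             snp_positions=[snp5, snp3])
            break
        else:
            raise RuntimeError(
                f"could not draw unambiguous flanks for locus {i + 1} after "
                f"{max_attempts} attempts; use a longer synthetic genome")
        seen_flanks.update((flank5, flank3))

        refs[chrom] = contig
        loci.append(locus)
        for pos in (snp5, snp3):
            ref_base = contig[pos]
            alt_base = str(rng.choice([b for b in DNA_ALPHABET if b != ref_base]))
            snp_defs[(name, pos)] = (ref_base, alt_base)
        probes.append(ProbeDef(probe_id, chrom, _PLUS_PROBE_AT, "+", name,
                               contig[_PLUS_PROBE_AT:_PLUS_PROBE_AT + PROBE_LEN]))
        p3 = E + _MINUS_PROBE_OFF
        probes.append(ProbeDef(probe_id + 1, chrom, p3 + PROBE_LEN, "-", name,
                               revcomp(contig[p3:p3 + PROBE_LEN])))
        probe_id += 2
        cut_sites.append(GRNACutSite(name, chrom, _CUT5_AT, "upstream"))
        cut_sites.append(GRNACutSite(name, chrom, E + _CUT3_OFF, "downstream"))
        f5_ivs.append(Interval(chrom, S - FLANK_LEN, S, name))
        f3_ivs.append(Interval(chrom, E, E + FLANK_LEN, name))
        excl_ivs.append(Interval(chrom, S - 5, E + 5, name))

    bundle = PanelBundle(loci=loci, probes=probes,
                         flank5_intervals=IntervalSet(f5_ivs),
                         flank3_intervals=IntervalSet(f3_ivs),
                         exclusion_intervals=IntervalSet(excl_ivs),
                         cut_sites=cut_sites)
    return SyntheticPanel(bundle=bundle, refs=refs, snp_defs=snp_defs)


def default_allele_freqs(panel: SyntheticPanel, spread: float = 0.3) -> dict[str, dict[int, float]]:
    """Per-locus repeat-count frequencies centred on the reference count."""
    freqs = {}
    for locus in panel.bundle.loci:
        r0 = locus.ref_repeat_len_bp // len(locus.motif)
        cap = MAX_ALLELE_BP // len(locus.motif)
        table = {}
        for d, w in ((0, 1.0 - spread), (-1, spread / 2), (1, spread / 4), (2, spread / 4)):
            n = r0 + d
            if locus.min_repeats <= n <= cap:
                table[n] = table.get(n, 0.0) + w
        total = sum(table.values())
        freqs[locus.name] = {n: w / total for n, w in table.items()}
    return freqs


def draw_individual_genotypes(panel: SyntheticPanel, allele_freqs, seed=0,
                              snp_alt_freq: float = 0.5,
                              name: str = "S1") -> IndividualTruth:
    """Draw a phased diploid individual: two independent draws per locus.

    ``allele_freqs`` maps locus name to a repeat-count frequency table
    (values summing to 1); the SNP allele drawn for each chromosome is phased
    with the repeat allele drawn on that chromosome.
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[str, tuple[int, int]] = {}
    snp_bases: dict[tuple[str, int], tuple[str, str]] = {}
    for locus in panel.bundle.loci:
        table = allele_freqs.get(locus.name)
        if not table:
            raise ValueError(f"empty allele frequency table for locus {locus.name}")
        alleles = sorted(table)
        p = np.array([table[a] for a in alleles], dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"allele frequencies for {locus.name} do not sum to 1")
        draw = rng.choice(alleles, size=2, p=p)
        genotypes[locus.name] = (int(draw[0]), int(draw[1]))
        for pos in locus.snp_positions:
            ref_base, alt_base = panel.snp_defs[(locus.name, pos)]
            picks = tuple(alt_base if rng.random() < snp_alt_freq else ref_base
                          for _ in range(2))
            snp_bases[(locus.name, pos)] = picks
    return IndividualTruth(name=name, genotypes=genotypes, snp_bases=snp_bases)


def make_trio(father: IndividualTruth, mother: IndividualTruth, seed=0,
              mutation_rate: float = 0.0, name: str = "child") -> IndividualTruth:
    """Child truth: one phased (STR, SNP) haplotype inherited per parent per locus."""
    if set(father.genotypes) != set(mother.genotypes):
        raise ValueError("parents were simulated on different panels")
    rng = np.random.default_rng(seed)
    genotypes, snp_bases = {}, {}
    for locus in father.genotypes:
        hf, hm = int(rng.integers(2)), int(rng.integers(2))
        nf = father.genotypes[locus][hf]
        nm = mother.genotypes[locus][hm]
        if mutation_rate > 0 and rng.random() < mutation_rate:
            nf = max(1, nf + (1 if rng.random() < 0.5 else -1))
        if mutation_rate > 0 and rng.random() < mutation_rate:
            nm = max(1, nm + (1 if rng.random() < 0.5 else -1))
        genotypes[locus] = (nf, nm)
        keys = [k for k in father.snp_bases if k[0] == locus]
        for key in keys:
            snp_bases[key] = (father.snp_bases[key][hf], mother.snp_bases[key][hm])
    return IndividualTruth(name=name, genotypes=genotypes, snp_bases=snp_bases)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.integers(0, len(seq), size=k):
        old = out[pos]
        out[pos] = DNA_ALPHABET[(DNA_ALPHABET.index(old) + int(rng.integers(1, 4))) % 4] \
            if old in DNA_ALPHABET else "N"
    return "".join(out)


def generate_read_pairs(truth: IndividualTruth, panel: SyntheticPanel,
                        coverage: int, stutter: StutterModel | None = None,
                        frag: FragmentationModel | None = None,
                        read_len: int = DEFAULT_READ_LEN, seed=0,
                        r2_len: int = DEFAULT_R2_LEN,
                        base_error: float = DEFAULT_BASE_ERROR,
                        base_qual: int = DEFAULT_BASE_QUAL,
                        id_prefix: str | None = None,
                        ) -> tuple[list[ReadPairRecord], list[ReadTruth]]:
    """Simulate ``coverage`` read pairs per locus for one individual.

    Each pair draws a haplotype and a probe uniformly; Read 2 starts with the
    probe 40-mer at its expected position, Read 1 derives from the opposite
    fragment end (cut-site-anchored under CRISPR mode, uniform otherwise).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    stutter = stutter or StutterModel.off()
    frag = frag or FragmentationModel(mode="random")
    for locus in panel.bundle.loci:
        if read_len < 31 + len(locus.motif) * locus.min_repeats:
            raise ValueError(f"read_len {read_len} too short to span locus {locus.name}")

    rng = np.random.default_rng(seed)
    qual1 = chr(33 + base_qual) * read_len
    prefix = id_prefix if id_prefix is not None else truth.name
    out: list[ReadPairRecord] = []
    truths: list[ReadTruth] = []
    pair_no = 0

    for locus in panel.bundle.loci:
        ref = panel.refs[locus.chrom]
        S, E = locus.start, locus.end
        ref_len = E - S
        m = len(locus.motif)
        pair_probes = panel.bundle.probes_for(locus.name)
        plus_probe = next(p for p in pair_probes if p.strand == "+")
        minus_probe = next(p for p in pair_probes if p.strand == "-")
        cut_up = panel.bundle.cut_site(locus.name, "upstream")
        cut_down = panel.bundle.cut_site(locus.name, "downstream")

        # phased pre/post context with this individual's SNP bases substituted
        pre_h, post_h = [], []
        for h in (0, 1):
            pre = list(ref[:S])
            post = list(ref[E:])
            for (lname, pos), bases in truth.snp_bases.items():
                if lname != locus.name:
                    continue
                if pos < S:
                    pre[pos] = bases[h]
                else:
                    post[pos - E] = bases[h]
            pre_h.append("".join(pre))
            post_h.append("".join(post))

        hap_cache: dict[tuple[int, int], str] = {}

        def hap_seq(h: int, n: int) -> str:
            key = (h, n)
            if key not in hap_cache:
                hap_cache[key] = pre_h[h] + locus.motif * n + post_h[h]
            return hap_cache[key]

        for _ in range(coverage):
            pair_no += 1
            pair_id = f"{prefix}:{pair_no:08d}"
            h = int(rng.integers(2))
            n_true = truth.genotypes[locus.name][h]
            n_obs = stutter.perturb(n_true, rng)
            hseq = hap_seq(h, n_obs)
            delta = n_obs * m - ref_len
            e_hap = E + delta
            use_plus = bool(rng.integers(2))
            probe = plus_probe if use_plus else minus_probe

            if use_plus:
                # Read 2 forward from the plus probe; fragment end downstream
                r2_seq = hseq[probe.expected_pos:probe.expected_pos + r2_len]
                r2_pos, r2_strand = probe.expected_pos, "+"
                cut = cut_down
                on_target = (frag.mode == "crispr" and cut is not None
                             and rng.random() < frag.on_target_prob)
                if on_target:
                    f_hap = cut.cut_pos + delta + int(round(rng.normal(0, frag.jitter_sd))) \
                        if frag.jitter_sd > 0 else cut.cut_pos + delta
                else:
                    # anywhere past the probe binding site (capture requirement)
                    lo = probe.expected_pos + PROBE_LEN + 10
                    f_hap = int(rng.integers(lo, len(hseq) + 1))
                f_hap = min(f_hap, len(hseq))
                r1_aln = hseq[max(0, f_hap - read_len):f_hap]
                if f_hap >= e_hap:
                    f_ref = f_hap - delta
                elif f_hap <= S:
                    f_ref = f_hap
                else:
                    f_ref = min(f_hap, E)
                r1_pos, r1_strand = f_ref - len(r1_aln), "-"
                if r1_pos < 0:  # clip at the contig edge (3' sequenced end)
                    r1_aln = r1_aln[-r1_pos:]
                    r1_pos = 0
                spans = (f_hap >= e_hap + FLANK_LEN
                         and f_hap - read_len <= S - FLANK_LEN)
                frag_pos = f_ref
            else:
                # Read 2 reverse from the minus probe; fragment end upstream
                hi = probe.expected_pos + delta
                r2_seq = hseq[hi - r2_len:hi]
                r2_pos, r2_strand = probe.expected_pos - r2_len, "-"
                cut = cut_up
                on_target = (frag.mode == "crispr" and cut is not None
                             and rng.random() < frag.on_target_prob)
                if on_target:
                    f2 = cut.cut_pos + int(round(rng.normal(0, frag.jitter_sd))) \
                        if frag.jitter_sd > 0 else cut.cut_pos
                    f2 = max(0, min(f2, S - 5))
                else:
                    # anywhere upstream of the probe binding site
                    hi_hap = probe.expected_pos + delta - PROBE_LEN - 10
                    f2 = int(rng.integers(0, max(1, hi_hap)))
                r1_aln = hseq[f2:f2 + read_len]
                if f2 >= e_hap:
                    f2_ref = f2 - delta
                elif f2 <= S:
                    f2_ref = f2
                else:
                    f2_ref = min(f2, E)
                r1_pos, r1_strand = f2_ref, "+"
                spans = (f2 <= S - FLANK_LEN and f2 + read_len >= e_hap + FLANK_LEN)
                frag_pos = f2_ref

            r1_seq = _apply_errors(r1_aln, rng, base_error)
            r2_seq = _apply_errors(r2_seq, rng, base_error)
            out.append(ReadPairRecord(
                pair_id=pair_id, chrom=locus.chrom,
                r1_seq=r1_seq, r1_qual=qual1[:len(r1_seq)],
                r1_pos=r1_pos, r1_strand=r1_strand,
                r2_seq=r2_seq, r2_qual=chr(33 + base_qual) * len(r2_seq),
                r2_pos=r2_pos, r2_strand=r2_strand,
            ))
            truths.append(ReadTruth(
                pair_id=pair_id, individual=truth.name, locus=locus.name, hap=h,
                true_repeats=n_true, obs_repeats=n_obs, probe_id=probe.probe_id,
                spans=spans, frag_pos=frag_pos, stuttered=n_obs != n_true,
            ))
    return out, truths


def mix_read_sets(read_sets, fractions, seed=0, truths=None,
                  n_out: int | None = None) -> tuple[list[ReadPairRecord], MixtureTruth]:
    """Merge per-individual read sets, sampling reads by mixture fraction.

    Each output read originates from set ``i`` with probability
    ``fractions[i]`` (multinomial split, sampled without replacement within a
    set). ``n_out`` defaults to the largest total that cannot exhaust any set.
    """
    fractions = [float(f) for f in fractions]
    if len(read_sets) != len(fractions):
        raise ValueError("one fraction per read set required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    chrom_sets = [{r.chrom for r in rs} for rs in read_sets if rs]
    if chrom_sets and any(cs != chrom_sets[0] for cs in chrom_sets):
        raise ValueError("read sets were simulated on different panels")

    if n_out is None:
        n_out = min(int(len(rs) / f) for rs, f in zip(read_sets, fractions) if f > 0)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_out, fractions)
    counts = [min(int(c), len(rs)) for c, rs in zip(counts, read_sets)]

    truth_by_id = {}
    if truths is not None:
        for tlist in truths:
            for t in tlist:
                truth_by_id[t.pair_id] = t

    merged, merged_truth = [], []
    for rs, c in zip(read_sets, counts):
        idx = rng.choice(len(rs), size=c, replace=False)
        for j in idx:
            merged.append(rs[int(j)])
            if truth_by_id:
                merged_truth.append(truth_by_id.get(rs[int(j)].pair_id))
    order = rng.permutation(len(merged))
    merged = [merged[int(i)] for i in order]
    if merged_truth:
        merged_truth = [merged_truth[int(i)] for i in order]
    names = [ts[0].individual if ts else f"set{i}" for i, ts in
             enumerate(truths)] if truths else [f"set{i}" for i in range(len(read_sets))]
    return merged, MixtureTruth(
        fractions=dict(zip(names, fractions)),
        reads=[t for t in merged_truth if t is not None],
    )
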