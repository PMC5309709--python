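"""Panel design filters: candidate STR selection, microsatellite criteria,
probe uniqueness screening and guide-RNA candidate generation.

All filters are pure functions of their inputs. Uniqueness screening is an
exhaustive substitution-distance scan suitable for synthetic genomes up to a
few megabases; genome-scale screening is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp
from .reference_model import PROBE_LEN, STRLocus

#: minimum repeat-annotation alignment score per motif unit size
SCORE_MINIMUMS = {2: 22, 3: 28, 4: 28, 5: 32, 6: 34}


@dataclass
class RepeatAnnotation:
    """A tandem-repeat-finder-style annotation row."""

    chrom: str
    start: int
    end: int
    motif: str
    unit_size: int
    pct_match: float
    pct_indel: float
    alignment_score: float

    @property
    def tract_len(self) -> int:
        return self.end - self.start


@dataclass
class SNPAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    #: population -> (hom_ref_freq, het_freq, hom_alt_freq)
    pop_genotype_freqs: dict[str, tuple[float, float, float]] = field(
        default_factory=dict)

    def additive_genotype_frequency(self) -> float:
        """Sum across populations of heterozygote + minor-homozygote frequency."""
        total = 0.0
        for hom_ref, het, hom_alt in self.pop_genotype_freqs.values():
            total += het + min(hom_ref, hom_alt)
        return total


def select_candidate_strs(repeats, snps, max_repeat_len: int = 100,
                          snp_window: int = 100,
                          min_additive_freq: float = 1.0,
                          ) -> list[RepeatAnnotation]:
    """Short repeats with a high-frequency SNP nearby.

    Keeps repeats whose tract is <= ``max_repeat_len`` bases and that have at
    least one SNP within ``snp_window`` bases of the tract whose additive
    genotype frequency exceeds ``min_additive_freq``.
    """
    eligible = [s for s in snps
                if s.additive_genotype_frequency() > min_additive_freq]
    by_chrom: dict[str, list[SNPAnnotation]] = {}
    for s in eligible:
        by_chrom.setdefault(s.chrom, []).append(s)

    out = []
    for rep in repeats:
        if rep.tract_len > max_repeat_len:
            continue
        lo, hi = rep.start - snp_window, rep.end + snp_window
        if any(lo <= s.pos < hi for s in by_chrom.get(rep.chrom, [])):
            out.append(rep)
    return out


def willems_microsatellite_filter(repeat: RepeatAnnotation,
                                  allowed_units=(2, 3, 4, 5, 6)) -> bool:
    """Published microsatellite definition: unit size, match/indel %, score.

    True iff the unit size is supported, percent match >= 80, percent indel
    <= 10 and the alignment score meets the size-specific minimum
    (2:22, 3:28, 4:28, 5:32, 6:34). Homopolymers (unit 1) never qualify.
    """
    if repeat.unit_size not in allowed_units or repeat.unit_size not in SCORE_MINIMUMS:
        return False
    return (repeat.pct_match >= 80.0
            and repeat.pct_indel <= 10.0
            and repeat.alignment_score >= SCORE_MINIMUMS[repeat.unit_size])


def _scan_min_mismatches(query: str, refs: dict[str, str], min_edits: int,
                         skip: set[tuple[str, int, str]] | None = None) -> int:
    """Smallest substitution distance of ``query`` to any genome window.

    Early-exits at 0. ``skip`` excludes (chrom, start, strand) self hits.
    """
    k = len(query)
    best = k + 1
    queries = {"+": query, "-": revcomp(query)}
    for chrom, seq in refs.items():
        for strand, q in queries.items():
            for i in range(len(seq) - k + 1):
                if skip and (chrom, i, strand) in skip:
                    continue
                window = seq[i:i + k]
                mism = 0
                for a, b in zip(q, window):
                    if a != b:
                        mism += 1
                        if mism >= best:
                            break
                best = min(best, mism)
                if best == 0:
                    return 0
    return best


def screen_probe_uniqueness(probe_seq: str, refs: dict[str, str],
                            min_edits: int = 2,
                            expected_location: tuple[str, int, str] | None = None,
                            ) -> bool:
    """True iff every off-target match needs >= ``min_edits`` substitutions.

    ``expected_location`` is the probe's own (chrom, start, strand) footprint,
    excluded from the scan; if omitted, exact self hits are located first and
    a single exact hit is treated as the self location.
    """
    if len(probe_seq) != PROBE_LEN:
        raise ValueError(f"probe must be {PROBE_LEN} bases, got {len(probe_seq)}")
    skip: set[tuple[str, int, str]] = set()
    if expected_location is not None:
        skip.add(expected_location)
    else:
        hits = []
        for chrom, seq in refs.items():
            for strand, q in (("+", probe_seq), ("-", revcomp(probe_seq))):
                start = 0
                while True:
                    i = seq.find(q, start)
                    if i < 0:
                        break
                    hits.append((chrom, i, strand))
                    start = i + 1
        if len(hits) > 1:
            return False  # present verbatim somewhere else
        if hits:
            skip.add(hits[0])
    return _scan_min_mismatches(probe_seq, refs, min_edits, skip) >= min_edits


@dataclass
class GRNACandidate:
    str_name: str
    chrom: str
    protospacer: str
    cut_pos: int
    side: str  # upstream | downstream
    overlap_bp: int
    unique: bool


def design_grnas(locus: STRLocus, refs: dict[str, str], read_len: int = 100,
                 max_overlap: int = 6, protospacer_len: int = 20,
                 pam: str = "GG", cut_offset: int = 3,
                 uniqueness_min_edits: int = 2) -> list[GRNACandidate]:
    """Enumerate guide-RNA candidates for a locus under the three criteria.

    A candidate protospacer lies immediately 5' of an N-``pam`` site on
    either strand; the blunt cut falls ``cut_offset`` bases 5' of the PAM.
    Accepted candidates (i) place the entire repeat within ``read_len`` bases
    of the cut, (ii) have a protospacer uniquely represented in the reference
    (>= ``uniqueness_min_edits`` substitutions to any other location) and
    (iii) overlap the repeat tract by at most ``max_overlap`` bases.
    Candidates on both sides of the repeat are returned.
    """
    seq = refs[locus.chrom]
    S, E = locus.start, locus.end
    lo = max(0, S - read_len - protospacer_len)
    hi = min(len(seq), E + read_len + protospacer_len)

    out = []
    for i in range(lo, hi - len(pam)):
        # plus strand: protospacer ends right before N-PAM at i; cut 5' of PAM
        if seq[i + 1:i + 1 + len(pam)] == pam:
            proto_end = i  # PAM is seq[i:i+3] as N+pam
            proto_start = proto_end - protospacer_len
            cut = proto_end - cut_offset
            if proto_start >= 0:
                out.extend(_grna_candidate(locus, seq, refs, proto_start,
                                           proto_end, cut, "+", read_len,
                                           max_overlap, uniqueness_min_edits))
        # minus strand: PAM is revcomp downstream; protospacer to the right
        if seq[i:i + len(pam)] == revcomp(pam):
            proto_start = i + len(pam) + 1
            proto_end = proto_start + protospacer_len
            cut = proto_start + cut_offset
            if proto_end <= len(seq):
                out.extend(_grna_candidate(locus, seq, refs, proto_start,
                                           proto_end, cut, "-", read_len,
                                           max_overlap, uniqueness_min_edits))
    return out


def _grna_candidate(locus, seq, refs, proto_start, proto_end, cut, strand,
                    read_len, max_overlap, min_edits):
    S, E = locus.start, locus.end
    overlap = max(0, min(proto_end, E) - max(proto_start, S))
    if overlap > max_overlap:
        return []
    # criterion (i): the cut must put the whole repeat within one read length
    if cut <= S:
        side, far = "upstream", E - cut
    elif cut >= E:
        side, far = "downstream", cut - S
    else:
        return []
    if far > read_len:
        return []
    proto = seq[proto_start:proto_end]
    if strand == "-":
        proto = revcomp(proto)
    unique = _protospacer_unique(seq[proto_start:proto_end], refs,
                                 (locus.chrom, proto_start), min_edits)
    if not unique:
        return []
    return [GRNACandidate(str_name=locus.name, chrom=locus.chrom,
                          protospacer=proto, cut_pos=cut, side=side,
                          overlap_bp=overlap, unique=True)]


def _protospacer_unique(fwd_window: str, refs, self_loc, min_edits) -> bool:
    chrom0, start0 = self_loc
    skip = {(chrom0, start0, "+"), (chrom0, start0, "-")}
    return _scan_min_mismatches(fwd_window, refs, min_edits, skip) >= min_edits
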