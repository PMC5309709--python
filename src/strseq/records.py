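"""Paired-end read records and SAM/FASTQ serialization.

Sequences are stored in aligned (genome-forward) orientation, matching the
SAM convention; ``*_strand`` records which strand was sequenced. Positions are
0-based leftmost alignment coordinates. The 5' (first sequenced) coordinate of
a read is therefore ``pos`` on the plus strand and ``pos + len(seq)`` on the
minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from ._util import revcomp


@dataclass
class ReadPairRecord:
    """One tagged paired-end read: Read 2 anchors a probe, Read 1 spans the STR."""

    pair_id: str
    chrom: str
    r1_seq: str
    r1_qual: str
    r1_pos: int | None
    r1_strand: str | None
    r2_seq: str
    r2_qual: str
    r2_pos: int
    r2_strand: str
    r1_mapq: int = 60
    r2_mapq: int = 60
    zp: int | None = None
    frag_offset: int | None = None

    @property
    def r2_start5(self) -> int:
        """Strand-aware 5' alignment start of Read 2 (probe anchor coordinate)."""
        if self.r2_strand == "+":
            return self.r2_pos
        return self.r2_pos + len(self.r2_seq)

    @property
    def r1_frag_end(self) -> int | None:
        """Fragmentation-derived fragment end: the 5' coordinate of Read 1."""
        if self.r1_pos is None:
            return None
        if self.r1_strand == "+":
            return self.r1_pos
        return self.r1_pos + len(self.r1_seq)

    @property
    def r2_end(self) -> int:
        return self.r2_pos + len(self.r2_seq)

    def r2_base_at(self, pos: int) -> tuple[str, int] | None:
        """(base, quality) of the aligned Read 2 base covering reference ``pos``."""
        off = pos - self.r2_pos
        if 0 <= off < len(self.r2_seq):
            return self.r2_seq[off], ord(self.r2_qual[off]) - 33
        return None


def write_sam(records: list[ReadPairRecord], ref_lengths: dict[str, int], path):
    """Write pairs as an uncompressed, coordinate-agnostic SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            tid = out.get_tid(rec.chrom)
            for which in (1, 2):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec.pair_id
                seq = rec.r1_seq if which == 1 else rec.r2_seq
                qual = rec.r1_qual if which == 1 else rec.r2_qual
                pos = rec.r1_pos if which == 1 else rec.r2_pos
                strand = rec.r1_strand if which == 1 else rec.r2_strand
                mapq = rec.r1_mapq if which == 1 else rec.r2_mapq
                flag = 0x1 | (0x40 if which == 1 else 0x80)
                if pos is None:
                    flag |= 0x4
                    a.reference_id = -1
                    a.reference_start = -1
                    # unaligned reads carry the sequenced-orientation bases
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                else:
                    if strand == "-":
                        flag |= 0x10
                    a.reference_id = tid
                    a.reference_start = pos
                    a.mapping_quality = mapq
                    a.cigarstring = f"{len(seq)}M"
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                a.flag = flag
                if rec.zp is not None:
                    a.set_tag("ZP", rec.zp)
                out.write(a)


def read_sam(path) -> list[ReadPairRecord]:
    """Read a SAM/BAM file of read pairs back into records (pairs by query name)."""
    firsts: dict[str, pysam.AlignedSegment] = {}
    seconds: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            (firsts if aln.is_read1 else seconds)[aln.query_name] = aln

    def _fields(aln):
        if aln is None or aln.is_unmapped:
            pos, strand, mapq = None, None, 0
        else:
            pos = aln.reference_start
            strand = "-" if aln.is_reverse else "+"
            mapq = aln.mapping_quality
        seq = aln.query_sequence or ""
        qual = pysam.qualities_to_qualitystring(aln.query_qualities or [])
        chrom = aln.reference_name if (aln is not None and not aln.is_unmapped) else None
        return chrom, seq, qual, pos, strand, mapq

    records = []
    for name, r2 in seconds.items():
        r1 = firsts.get(name)
        c2, s2, q2, p2, st2, mq2 = _fields(r2)
        if p2 is None:
            continue  # an unaligned Read 2 can never be probe-indexed
        if r1 is not None:
            c1, s1, q1, p1, st1, mq1 = _fields(r1)
        else:
            s1, q1, p1, st1, mq1 = "", "", None, None, 0
        zp = r2.get_tag("ZP") if r2.has_tag("ZP") else None
        records.append(ReadPairRecord(
            pair_id=name, chrom=c2, r1_seq=s1, r1_qual=q1, r1_pos=p1,
            r1_strand=st1, r2_seq=s2, r2_qual=q2, r2_pos=p2, r2_strand=st2,
            r1_mapq=mq1, r2_mapq=mq2, zp=zp,
        ))
    records.sort(key=lambda r: r.pair_id)
    return records


def write_fastq_pair(records: list[ReadPairRecord], path_r1, path_r2):
    """Emit raw reads in sequenced orientation as an uncompressed FASTQ pair."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rec in records:
            s1, q1 = rec.r1_seq, rec.r1_qual
            if rec.r1_strand == "-":
                s1, q1 = revcomp(s1), q1[::-1]
            s2, q2 = rec.r2_seq, rec.r2_qual
            if rec.r2_strand == "-":
                s2, q2 = revcomp(s2), q2[::-1]
            f1.write(f"@{rec.pair_id}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rec.pair_id}/2\n{s2}\n+\n{q2}\n")


def write_fasta(refs: dict[str, str], path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
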