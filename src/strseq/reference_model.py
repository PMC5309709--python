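"""Panel metadata bundle: targeted loci, primer probes, flank/exclusion intervals.

The bundle mirrors five tab-delimited resource files plus an optional guide-RNA
cut-site table:

* ``str_probes.txt``  — probe_id, chrom, expected_pos, strand, str_name, probe_seq
* ``str_info.txt``    — str_name, motif, chrom, start, end, min_repeats, flank5, flank3
* ``5prflank.bed``    — 4-column BED of 5' flank intervals (name = locus)
* ``3prflank.bed``    — 4-column BED of 3' flank intervals (name = locus)
* ``noSTR_plus5b.bed``— 4-column BED of repeat tracts padded by 5 b; SNP calls
  inside these intervals are excluded from phasing
* ``cut_sites.txt``   — str_name, chrom, cut_pos, side (optional)

All coordinates are 0-based half-open. ``expected_pos`` is the coordinate of
the 5' (first sequenced) base of a correctly primed Read 2 alignment: the
leftmost aligned base for plus-strand probes, the past-the-end coordinate for
minus-strand probes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from ._util import Interval, IntervalSet, read_bed, write_bed

log = logging.getLogger(__name__)

FLANK_LEN = 15
PROBE_LEN = 40
SNP_PROXIMITY_BP = 100

_STRANDS = ("+", "-")
_SIDES = ("upstream", "downstream")


@dataclass
class STRLocus:
    """One targeted tandem repeat."""

    name: str
    motif: str
    chrom: str
    start: int
    end: int
    min_repeats: int
    flank5: str
    flank3: str
    snp_positions: list[int] = field(default_factory=list)

    @property
    def ref_repeat_len_bp(self) -> int:
        """Reference tract length in bases (``end - start`` by convention)."""
        return self.end - self.start

    def violations(self) -> list[str]:
        v = []
        if not (1 <= len(self.motif) <= 6):
            v.append(f"locus {self.name}: motif length {len(self.motif)} outside [1,6]")
        if set(self.motif) - set("ACGT"):
            v.append(f"locus {self.name}: motif has non-ACGT characters")
        for label, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(flank) != FLANK_LEN:
                v.append(f"locus {self.name}: {label} length {len(flank)} != {FLANK_LEN}")
            elif set(flank) - set("ACGT"):
                v.append(f"locus {self.name}: {label} has non-ACGT characters")
        if not self.start < self.end:
            v.append(f"locus {self.name}: start {self.start} >= end {self.end}")
        if self.min_repeats < 1:
            v.append(f"locus {self.name}: min_repeats {self.min_repeats} < 1")
        for pos in self.snp_positions:
            if min(abs(pos - self.start), abs(pos - self.end)) > SNP_PROXIMITY_BP:
                v.append(f"locus {self.name}: SNP at {pos} farther than "
                         f"{SNP_PROXIMITY_BP} b from the tract")
        return v


@dataclass
class ProbeDef:
    """One 40-mer primer probe anchoring Read 2 of a pair to a locus."""

    probe_id: int
    chrom: str
    expected_pos: int
    strand: str
    str_name: str
    probe_seq: str

    def violations(self) -> list[str]:
        v = []
        if len(self.probe_seq) != PROBE_LEN:
            v.append(f"probe {self.probe_id}: probe_seq length {len(self.probe_seq)} != {PROBE_LEN}")
        if self.strand not in _STRANDS:
            v.append(f"probe {self.probe_id}: strand {self.strand!r} not in {_STRANDS}")
        return v


@dataclass
class GRNACutSite:
    """Expected blunt double-strand break coordinate for one locus side."""

    str_name: str
    chrom: str
    cut_pos: int
    side: str  # upstream | downstream of the repeat

    def violations(self, locus: STRLocus | None = None) -> list[str]:
        v = []
        if self.side not in _SIDES:
            v.append(f"cut site {self.str_name}/{self.side}: side not in {_SIDES}")
        if locus is not None:
            far = max(abs(self.cut_pos - locus.start), abs(self.cut_pos - locus.end))
            if far > SNP_PROXIMITY_BP:
                v.append(f"cut site {self.str_name}/{self.side}: repeat not fully "
                         f"within {SNP_PROXIMITY_BP} b of cut ({far})")
        return v


@dataclass
class PanelBundle:
    """Fully cross-linked panel metadata consumed by every pipeline stage."""

    loci: list[STRLocus]
    probes: list[ProbeDef]
    flank5_intervals: IntervalSet
    flank3_intervals: IntervalSet
    exclusion_intervals: IntervalSet
    cut_sites: list[GRNACutSite] = field(default_factory=list)

    def __post_init__(self):
        self._locus_by_name = {l.name: l for l in self.loci}
        self._probe_by_id = {p.probe_id: p for p in self.probes}

    def locus(self, name: str) -> STRLocus:
        return self._locus_by_name[name]

    def probe(self, probe_id: int) -> ProbeDef:
        return self._probe_by_id[probe_id]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def probes_for(self, str_name: str) -> list[ProbeDef]:
        return [p for p in self.probes if p.str_name == str_name]

    def cut_site(self, str_name: str, side: str) -> GRNACutSite | None:
        for cs in self.cut_sites:
            if cs.str_name == str_name and cs.side == side:
                return cs
        return None


class PanelError(ValueError):
    """Fatal panel loading problem (missing file, dangling reference, bad flank)."""


def _read_tsv(path, required: list[str]) -> list[dict[str, str]]:
    if not os.path.exists(path):
        raise PanelError(f"missing panel file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise PanelError(f"{path}: missing required columns {missing}")
        extra = [c for c in header if c not in required]
        if extra:
            log.warning("%s: ignoring unknown columns %s", path, extra)
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(dict(zip(header, line.split("\t"))))
    return rows


def load_panel_bundle(str_probes_path, str_info_path, flank5_bed_path,
                      flank3_bed_path, nostr_bed_path,
                      cut_sites_path=None) -> PanelBundle:
    """Load and cross-link the five metadata files (+ optional cut sites).

    Raises :class:`PanelError` on a missing file, a probe referencing an
    unknown locus, or a malformed (non-15-base) flank.
    """
    loci = []
    for row in _read_tsv(str_info_path, ["str_name", "motif", "chrom", "start",
                                         "end", "min_repeats", "flank5", "flank3"]):
        snps = [int(x) for x in row.get("snp_positions", "").split(",") if x]
        locus = STRLocus(
            name=row["str_name"], motif=row["motif"], chrom=row["chrom"],
            start=int(row["start"]), end=int(row["end"]),
            min_repeats=int(row["min_repeats"]),
            flank5=row["flank5"], flank3=row["flank3"], snp_positions=snps,
        )
        if len(locus.flank5) != FLANK_LEN or len(locus.flank3) != FLANK_LEN:
            raise PanelError(f"locus {locus.name}: flanks must be exactly "
                             f"{FLANK_LEN} bases")
        loci.append(locus)
    known = {l.name for l in loci}

    probes = []
    for row in _read_tsv(str_probes_path, ["probe_id", "chrom", "expected_pos",
                                           "strand", "str_name", "probe_seq"]):
        probe = ProbeDef(
            probe_id=int(row["probe_id"]), chrom=row["chrom"],
            expected_pos=int(row["expected_pos"]), strand=row["strand"],
            str_name=row["str_name"], probe_seq=row["probe_seq"],
        )
        if probe.str_name not in known:
            raise PanelError(f"probe {probe.probe_id} references unknown STR "
                             f"{probe.str_name!r}")
        probes.append(probe)
    if len({p.probe_id for p in probes}) != len(probes):
        raise PanelError("duplicate probe_id values in probe table")

    cut_sites = []
    if cut_sites_path is not None:
        for row in _read_tsv(cut_sites_path, ["str_name", "chrom", "cut_pos", "side"]):
            if row["str_name"] not in known:
                raise PanelError(f"cut site references unknown STR {row['str_name']!r}")
            cut_sites.append(GRNACutSite(row["str_name"], row["chrom"],
                                         int(row["cut_pos"]), row["side"]))

    return PanelBundle(
        loci=loci,
        probes=probes,
        flank5_intervals=read_bed(flank5_bed_path),
        flank3_intervals=read_bed(flank3_bed_path),
        exclusion_intervals=read_bed(nostr_bed_path),
        cut_sites=cut_sites,
    )


_FILES = {
    "str_probes": "str_probes.txt",
    "str_info": "str_info.txt",
    "flank5_bed": "5prflank.bed",
    "flank3_bed": "3prflank.bed",
    "nostr_bed": "noSTR_plus5b.bed",
    "cut_sites": "cut_sites.txt",
}


def load_panel_dir(panel_dir) -> PanelBundle:
    """Convenience loader for a directory laid out with the standard file names."""
    cuts = os.path.join(panel_dir, _FILES["cut_sites"])
    return load_panel_bundle(
        os.path.join(panel_dir, _FILES["str_probes"]),
        os.path.join(panel_dir, _FILES["str_info"]),
        os.path.join(panel_dir, _FILES["flank5_bed"]),
        os.path.join(panel_dir, _FILES["flank3_bed"]),
        os.path.join(panel_dir, _FILES["nostr_bed"]),
        cut_sites_path=cuts if os.path.exists(cuts) else None,
    )


def write_panel_bundle(bundle: PanelBundle, panel_dir):
    """Serialize a bundle back to the standard file layout (load/write round-trips)."""
    os.makedirs(panel_dir, exist_ok=True)
    with open(os.path.join(panel_dir, _FILES["str_info"]), "w") as fh:
        fh.write("str_name\tmotif\tchrom\tstart\tend\tmin_repeats\tflank5\tflank3"
                 "\tsnp_positions\n")
        for l in bundle.loci:
            snps = ",".join(str(p) for p in l.snp_positions)
            fh.write(f"{l.name}\t{l.motif}\t{l.chrom}\t{l.start}\t{l.end}\t"
                     f"{l.min_repeats}\t{l.flank5}\t{l.flank3}\t{snps}\n")
    with open(os.path.join(panel_dir, _FILES["str_probes"]), "w") as fh:
        fh.write("probe_id\tchrom\texpected_pos\tstrand\tstr_name\tprobe_seq\n")
        for p in bundle.probes:
            fh.write(f"{p.probe_id}\t{p.chrom}\t{p.expected_pos}\t{p.strand}\t"
                     f"{p.str_name}\t{p.probe_seq}\n")
    write_bed(bundle.flank5_intervals, os.path.join(panel_dir, _FILES["flank5_bed"]))
    write_bed(bundle.flank3_intervals, os.path.join(panel_dir, _FILES["flank3_bed"]))
    write_bed(bundle.exclusion_intervals, os.path.join(panel_dir, _FILES["nostr_bed"]))
    if bundle.cut_sites:
        with open(os.path.join(panel_dir, _FILES["cut_sites"]), "w") as fh:
            fh.write("str_name\tchrom\tcut_pos\tside\n")
            for cs in bundle.cut_sites:
                fh.write(f"{cs.str_name}\t{cs.chrom}\t{cs.cut_pos}\t{cs.side}\n")


def validate_panel(bundle: PanelBundle) -> list[str]:
    """Report invariant violations; an empty list means the bundle is well formed."""
    report: list[str] = []
    for locus in bundle.loci:
        report.extend(locus.violations())
    known = {l.name for l in bundle.loci}
    seen_probe_ids = set()
    for probe in bundle.probes:
        report.extend(probe.violations())
        if probe.str_name not in known:
            report.append(f"probe {probe.probe_id}: unknown STR {probe.str_name!r}")
        if probe.probe_id in seen_probe_ids:
            report.append(f"probe {probe.probe_id}: duplicate probe_id")
        seen_probe_ids.add(probe.probe_id)
    with_probe = {p.str_name for p in bundle.probes}
    for locus in bundle.loci:
        if locus.name not in with_probe:
            report.append(f"locus {locus.name}: has no probe")
    for ivset, label in ((bundle.flank5_intervals, "5' flank"),
                         (bundle.flank3_intervals, "3' flank")):
        for iv in ivset:
            if iv.name not in known:
                report.append(f"{label} interval {iv.name!r}: unknown locus")
        for a, b in ivset.self_overlaps():
            report.append(f"{label} intervals overlap for locus {a.name}")
    for cs in bundle.cut_sites:
        locus = bundle._locus_by_name.get(cs.str_name)
        report.extend(cs.violations(locus))
    return report
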