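"""Probe-indexing of read pairs (ZP tag) and CRISPR fragmentation QC.

A read pair is assigned to a target STR purely from the Read 2 alignment
position: if the strand-aware 5' start of Read 2 lies within ``tolerance``
bases of a probe's expected position (same chromosome and strand), the pair
is tagged with that probe id; otherwise it is discarded. Read 1 inherits the
tag and is never required to align.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

from .records import ReadPairRecord
from .reference_model import PanelBundle

log = logging.getLogger(__name__)

DEFAULT_PROBE_TOLERANCE = 2
DEFAULT_CUT_TOLERANCE = 4


@dataclass
class TagResult:
    tagged: list[ReadPairRecord]
    n_input: int
    n_discarded: int
    n_ambiguous: int
    per_probe: dict[int, int] = field(default_factory=dict)


@dataclass
class FragmentationSummary:
    """On-/off-target fragment-end counts per cut site and overall."""

    per_site: dict[tuple[str, str], tuple[int, int]]  # (locus, side) -> (on, off)
    n_on_target: int
    n_off_target: int

    @property
    def on_target_fraction(self) -> float | None:
        total = self.n_on_target + self.n_off_target
        return self.n_on_target / total if total else None

    def site_fraction(self, str_name: str, side: str) -> float | None:
        on, off = self.per_site.get((str_name, side), (0, 0))
        return on / (on + off) if on + off else None


class _ProbeIndex:
    """Sorted expected positions keyed by (chrom, strand) for nearest lookup."""

    def __init__(self, bundle: PanelBundle):
        self._by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for p in bundle.probes:
            self._by_key.setdefault((p.chrom, p.strand), []).append(
                (p.expected_pos, p.probe_id))
        for v in self._by_key.values():
            v.sort()

    def match(self, chrom: str, strand: str, pos: int,
              tolerance: int) -> tuple[int | None, bool]:
        """(probe_id or None, ambiguous_tie) for the nearest in-tolerance probe."""
        entries = self._by_key.get((chrom, strand))
        if not entries:
            return None, False
        i = bisect_left(entries, (pos, -1))
        best, best_dist, tie = None, None, False
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(entries):
                dist = abs(entries[j][0] - pos)
                if dist <= tolerance:
                    if best_dist is None or dist < best_dist:
                        best, best_dist, tie = entries[j][1], dist, False
                    elif dist == best_dist and entries[j][1] != best:
                        tie = True
        if tie:
            return None, True
        return best, False


def tag_read_pairs(pairs, panel: PanelBundle,
                   tolerance: int = DEFAULT_PROBE_TOLERANCE) -> TagResult:
    """Set the ZP tag on every pair whose Read 2 matches a probe position.

    Pairs with no in-tolerance probe are discarded (counted). An exact-tie
    between two probes is ambiguous and discarded with a warning.
    """
    index = _ProbeIndex(panel)
    tagged, per_probe = [], {}
    n_input = n_discarded = n_ambiguous = 0
    for pair in pairs:
        n_input += 1
        probe_id, tie = index.match(pair.chrom, pair.r2_strand,
                                    pair.r2_start5, tolerance)
        if probe_id is None:
            n_discarded += 1
            if tie:
                n_ambiguous += 1
            continue
        pair.zp = probe_id
        per_probe[probe_id] = per_probe.get(probe_id, 0) + 1
        tagged.append(pair)
    if n_ambiguous:
        log.warning("%d pairs discarded due to ambiguous probe ties", n_ambiguous)
    return TagResult(tagged=tagged, n_input=n_input, n_discarded=n_discarded,
                     n_ambiguous=n_ambiguous, per_probe=per_probe)


def classify_fragmentation(tagged_pairs, panel: PanelBundle,
                           tolerance: int = DEFAULT_CUT_TOLERANCE,
                           ) -> FragmentationSummary:
    """Classify Read 1 fragment ends as on-/off-target per cut site.

    The fragment end compared against the cut site is the 5' coordinate of
    Read 1 (the fragmentation-derived end). Plus-strand probes produce
    reverse Read 1s whose fragment end falls downstream of the repeat, so
    they are scored against the downstream cut site; minus-strand probes
    against the upstream one. Pairs at loci without the relevant cut site are
    excluded from the denominator.
    """
    per_site: dict[tuple[str, str], list[int]] = {}
    n_on = n_off = 0
    for pair in tagged_pairs:
        if pair.zp is None or pair.r1_pos is None:
            continue
        probe = panel.probe(pair.zp)
        side = "downstream" if probe.strand == "+" else "upstream"
        site = panel.cut_site(probe.str_name, side)
        if site is None:
            continue
        offset = pair.r1_frag_end - site.cut_pos
        pair.frag_offset = offset
        key = (probe.str_name, side)
        counts = per_site.setdefault(key, [0, 0])
        if abs(offset) <= tolerance:
            counts[0] += 1
            n_on += 1
        else:
            counts[1] += 1
            n_off += 1
    return FragmentationSummary(
        per_site={k: (v[0], v[1]) for k, v in per_site.items()},
        n_on_target=n_on, n_off_target=n_off,
    )


def write_index_summary(result: TagResult, path):
    with open(path, "w") as fh:
        fh.write("probe_id\tn_pairs\n")
        for probe_id in sorted(result.per_probe):
            fh.write(f"{probe_id}\t{result.per_probe[probe_id]}\n")
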