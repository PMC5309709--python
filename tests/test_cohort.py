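import numpy as np
import pytest

from strseq import cohort
from strseq.genotype import GenotypeCall
from strseq.pipeline import run_sample
from strseq.simulate import (build_synthetic_panel, default_allele_freqs,
                             draw_individual_genotypes, make_trio,
                             mix_read_sets)

from conftest import make_reads


def _call(locus, alleles, total=100):
    alleles = tuple(alleles)
    support = {a: total // len(set(alleles)) for a in set(alleles)}
    major = max(support, key=lambda a: (support[a], -a))
    return GenotypeCall(locus=locus, alleles=tuple(sorted(set(alleles))),
                        zygosity="het" if len(set(alleles)) == 2 else "hom",
                        major_allele=major, support=support, total=total,
                        stutter_fraction=0.0)


class TestCEComparison:
    def _panel(self):
        return build_synthetic_panel(5, seed=70)

    def test_median_offset_applied(self):
        sp = self._panel()
        locus = sp.bundle.loci[0]
        m = len(locus.motif)
        # five samples; four shifted by +1 repeat, one not
        seq_calls, ce_calls = {}, {}
        for i, off in enumerate([1, 1, 0, 1, 1]):
            sample = f"s{i}"
            seq_calls[sample] = {locus.name: _call(locus.name, (8 + off, 10 + off))}
            ce_calls[sample] = {locus.name: (8 * m, 10 * m)}
        cmp_ = cohort.ce_offset_concordance(seq_calls, ce_calls, sp.bundle)
        assert cmp_.offsets[locus.name] == 1
        # after correcting by +1, the four shifted samples agree
        assert cmp_.concordance == {f"s{i}": (1.0 if off == 1 else 0.0)
                                    for i, off in enumerate([1, 1, 0, 1, 1])}

    def test_identical_calls_concordance_1(self):
        sp = self._panel()
        seq_calls, ce_calls = {"s": {}}, {"s": {}}
        for locus in sp.bundle.loci:
            m = len(locus.motif)
            seq_calls["s"][locus.name] = _call(locus.name, (7, 9))
            ce_calls["s"][locus.name] = (7 * m, 9 * m)
        cmp_ = cohort.ce_offset_concordance(seq_calls, ce_calls, sp.bundle)
        assert cmp_.concordance["s"] == 1.0
        assert all(off == 0 for off in cmp_.offsets.values())
        assert cmp_.overall_concordance == 1.0

    @pytest.mark.parametrize("shift", [-2, -1, 1, 3])
    def test_constant_annotation_shift_invariance(self, shift):
        sp = self._panel()
        seq_calls, ce_calls = {}, {}
        rng = np.random.default_rng(1)
        for i in range(4):
            sample = f"s{i}"
            seq_calls[sample], ce_calls[sample] = {}, {}
            for locus in sp.bundle.loci:
                m = len(locus.motif)
                a, b = sorted(rng.integers(5, 12, size=2))
                seq_calls[sample][locus.name] = _call(locus.name, (a, b))
                ce_calls[sample][locus.name] = ((a + shift) * m, (b + shift) * m)
        cmp_ = cohort.ce_offset_concordance(seq_calls, ce_calls, sp.bundle)
        assert all(f == 1.0 for f in cmp_.concordance.values())
        assert all(off == -shift for off in cmp_.offsets.values())

    def test_locus_absent_from_ce_skipped(self):
        sp = self._panel()
        locus = sp.bundle.loci[0]
        seq_calls = {"s": {locus.name: _call(locus.name, (7, 9)),
                           sp.bundle.loci[1].name: _call(sp.bundle.loci[1].name,
                                                         (5, 5))}}
        m = len(locus.motif)
        ce_calls = {"s": {locus.name: (7 * m, 9 * m)}}
        cmp_ = cohort.ce_offset_concordance(seq_calls, ce_calls, sp.bundle)
        assert set(cmp_.offsets) == {locus.name}


class TestTrioSetLogic:
    def _results(self, haps_by_key, genotypes=None, name="x"):
        """Bare-bones SampleResults stand-in for the set-logic tests."""
        from strseq.pipeline import SampleResults
        from strseq.snp_phase import HaplotypeCall, PhasedCount

        hap_calls, phased = {}, {}
        for (locus, pos), haps in haps_by_key.items():
            hap_calls[(locus, pos)] = HaplotypeCall(
                locus=locus, snp_pos=pos, haplotypes=tuple(haps),
                support={h: 50 for h in haps},
                zygosity="het" if len(set(haps)) == 2 else "hom")
            pc = PhasedCount(locus=locus, chrom="c", snp_pos=pos)
            pc.counts = {h: 50 for h in set(haps)}
            phased[(locus, pos)] = pc
        return SampleResults(
            name=name, tag_result=None, frag_summary=None, read_strs=[],
            filter_stats=None, histograms={}, genotype_calls=genotypes or {},
            snp_calls=[], phased_counts=phased, haplotype_calls=hap_calls)

    def test_concordant_example(self):
        from strseq.snp_phase import SNPCall
        child = self._results({("L", 5): [("A", 11), ("C", 13)]})
        child.snp_calls = [SNPCall(chrom="c", pos=5, ref_base="A", alt_base="C",
                                   coverage=100, ref_count=50, alt_count=50,
                                   ref_qual_sum=1750, alt_qual_sum=1750,
                                   genotype="het")]
        father = self._results({("L", 5): [("A", 11), ("A", 12)]})
        mother = self._results({("L", 5): [("C", 13), ("C", 9)]})
        report = cohort.trio_concordance(child, father, mother)
        assert report.haplotype_status == {("L", 5): True}

    def test_discordant_example(self):
        from strseq.snp_phase import SNPCall
        child = self._results({("L", 5): [("A", 11), ("C", 13)]})
        child.snp_calls = [SNPCall(chrom="c", pos=5, ref_base="A", alt_base="C",
                                   coverage=100, ref_count=50, alt_count=50,
                                   ref_qual_sum=1750, alt_qual_sum=1750,
                                   genotype="het")]
        father = self._results({("L", 5): [("C", 8), ("C", 9)]})
        mother = self._results({("L", 5): [("C", 13), ("C", 13)]})
        report = cohort.trio_concordance(child, father, mother)
        assert report.haplotype_status == {("L", 5): False}

    def test_genotype_partition(self):
        child = self._results({}, genotypes={"L": _call("L", (8, 11))})
        father = self._results({}, genotypes={"L": _call("L", (8, 8))})
        mother = self._results({}, genotypes={"L": _call("L", (11, 13))})
        report = cohort.trio_concordance(child, father, mother)
        assert report.genotype_status == {"L": True}
        mother2 = self._results({}, genotypes={"L": _call("L", (9, 13))})
        report2 = cohort.trio_concordance(child, father, mother2)
        assert report2.genotype_status == {"L": False}


class TestInformative:
    def test_set_difference(self):
        t = TestTrioSetLogic()
        minor = t._results({("L", 5): [("A", 11), ("C", 13)]})
        major = t._results({("L", 5): [("A", 11), ("A", 11)]})
        inf = cohort.informative_haplotypes(minor, [major])
        assert inf == {("L", 5, "C", 13)}

    def test_identical_samples_empty(self):
        t = TestTrioSetLogic()
        a = t._results({("L", 5): [("A", 11), ("C", 13)]})
        b = t._results({("L", 5): [("A", 11), ("C", 13)]})
        assert cohort.informative_haplotypes(a, [b]) == set()

    def test_multi_contributor_equals_brute_force(self):
        t = TestTrioSetLogic()
        rng = np.random.default_rng(3)
        samples = []
        for i in range(6):
            haps = {}
            for L in "ABCD":
                picks = [(b, int(r)) for b, r in
                         zip(rng.choice(list("ACGT"), 2), rng.integers(6, 12, 2))]
                haps[(L, 5)] = picks
            samples.append(t._results(haps, name=f"s{i}"))
        minor, majors = samples[0], samples[1:]
        inf = cohort.informative_haplotypes(minor, majors)
        brute = minor.haplotype_set()
        for m in majors:
            brute -= m.haplotype_set()
        assert inf == brute


class TestMixtureQuantification:
    def test_observed_fraction_arithmetic(self):
        t = TestTrioSetLogic()
        mix = t._results({("L", 5): [("A", 11), ("C", 13)]})
        mix.phased_counts[("L", 5)].counts = {("A", 11): 995, ("C", 13): 5}
        report = cohort.mixture_quantification(
            mix, {("L", 5, "C", 13)}, minor_fraction=0.10)
        obs = report.observations[0]
        assert obs.observed_fraction == pytest.approx(0.005)
        assert obs.expected_fraction == pytest.approx(0.05)
        assert obs.detected

    def test_hom_minor_expected_fraction(self):
        t = TestTrioSetLogic()
        mix = t._results({("L", 5): [("A", 11)]})
        report = cohort.mixture_quantification(
            mix, {("L", 5, "A", 11)}, minor_fraction=0.10,
            minor_zygosity={("L", 5, "A", 11): "hom"})
        assert report.observations[0].expected_fraction == pytest.approx(0.10)

    def test_zero_coverage_reported_undetectable(self):
        t = TestTrioSetLogic()
        mix = t._results({})
        report = cohort.mixture_quantification(mix, {("L", 5, "C", 13)})
        obs = report.observations[0]
        assert obs.locus_total == 0 and obs.observed_fraction is None
        assert not obs.detected

    def test_simulated_one_percent_minor_fraction(self):
        """End-to-end: 1% het minor at high coverage -> mean observed ~0.5%."""
        sp = build_synthetic_panel(12, seed=80)
        freqs = default_allele_freqs(sp)
        minor_t = draw_individual_genotypes(sp, freqs, seed=81, name="minor")
        major_t = draw_individual_genotypes(sp, freqs, seed=82, name="major")
        cov = 2500
        minor_p, minor_rt = make_reads(sp, minor_t, coverage=cov, seed=83)
        major_p, major_rt = make_reads(sp, major_t, coverage=cov, seed=84)
        merged, _ = mix_read_sets([minor_p, major_p], [0.01, 0.99], seed=85,
                                  truths=[minor_rt, major_rt])
        minor_res = run_sample(minor_p, sp.bundle, sp.refs, name="minor")
        major_res = run_sample(major_p, sp.bundle, sp.refs, name="major")
        mix_res = run_sample(merged, sp.bundle, sp.refs, name="mix")
        informative = cohort.informative_haplotypes(minor_res, [major_res])
        het_inf = set()
        for (locus, pos, base, rep) in informative:
            haps = minor_t.haplotypes(locus)
            pair = {(h["snps"][(locus, pos)], h["repeats"]) for h in haps}
            if len(pair) == 2 and (base, rep) in pair:
                het_inf.add((locus, pos, base, rep))
        assert het_inf, "simulation produced no informative het haplotypes"
        report = cohort.mixture_quantification(mix_res, het_inf,
                                               minor_fraction=0.01)
        obs = [o.observed_fraction for o in report.observations
               if o.observed_fraction is not None]
        mean_obs = float(np.mean(obs))
        n_reads = sum(o.locus_total for o in report.observations)
        sd = (0.005 * 0.995 / max(n_reads, 1)) ** 0.5
        assert abs(mean_obs - 0.005) < max(5 * sd, 0.002)


class TestSimulatedTrioPipeline:
    def test_mutation_free_trio_fully_concordant(self):
        sp = build_synthetic_panel(10, seed=90)
        freqs = default_allele_freqs(sp)
        father_t = draw_individual_genotypes(sp, freqs, seed=91, name="F")
        mother_t = draw_individual_genotypes(sp, freqs, seed=92, name="M")
        child_t = make_trio(father_t, mother_t, seed=93)
        results = {}
        for i, (label, t) in enumerate([("child", child_t), ("father", father_t),
                                        ("mother", mother_t)]):
            pairs, _ = make_reads(sp, t, coverage=50, seed=94 + i)
            results[label] = run_sample(pairs, sp.bundle, sp.refs, name=label)
        report = cohort.trio_concordance(results["child"], results["father"],
                                         results["mother"])
        assert report.genotype_concordance == 1.0
        assert report.haplotype_concordance == 1.0
        assert len(report.genotype_status) == 10
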