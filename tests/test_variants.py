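"""Read QC, cost-based alignment, dedup, pileup, consensus, calling rules,
classification, susceptibility densities and variant load."""

import numpy as np
import pytest

import mthap
from mthap import (AlignParams, CallThresholds, MthapError, QCParams,
                   ReadRecord, VariantCall)
from mthap.simulate import AnnotationSpec
from mthap.variants import ReferenceIndex, build_pileup


def _read(bases, qual=30, rid="r"):
    return ReadRecord(rid, bases, [qual] * len(bases))


@pytest.fixture(scope="module")
def mini_genome():
    """A small annotated genome for fast caller tests."""
    spec = AnnotationSpec(features=[
        mthap.Feature("geneA", "CDS", 101, 1000, "+", complex="I"),
        mthap.Feature("geneB", "CDS", 1001, 1600, "+", complex="III"),
        mthap.Feature("ctrl", "control", 1601, 2000, "+"),
    ])
    return mthap.build_reference(seed=3, length=2000, annotation_spec=spec)


class TestQC:
    def test_short_read_dropped(self):
        kept, rep = mthap.qc_reads([_read("A" * 14)])
        assert kept == [] and rep.n_too_short == 1

    def test_trim_precedes_length_check(self):
        # a 16 bp read trims to 14 bp and is then dropped
        kept, rep = mthap.qc_reads([_read("A" * 16)])
        assert kept == [] and rep.n_too_short == 1

    def test_low_mean_phred_dropped(self):
        kept, rep = mthap.qc_reads([_read("A" * 30, qual=14)])
        assert kept == [] and rep.n_low_quality == 1

    def test_passing_read_trimmed(self):
        kept, rep = mthap.qc_reads([_read("C" + "A" * 20 + "G")])
        assert rep.n_kept == 1
        assert kept[0].bases == "A" * 20

    def test_report_partitions_input(self):
        reads = [_read("A" * 14), _read("A" * 30, qual=5), _read("A" * 30)]
        _, rep = mthap.qc_reads(reads)
        assert rep.n_input == rep.n_kept + rep.n_too_short + rep.n_low_quality


class TestAlignRead:
    def test_exact_substring_cost_zero(self, mini_genome):
        ref = mini_genome.sequence
        a = mthap.align_read(_read(ref[200:260]), ref, AlignParams())
        assert a is not None
        assert a.cost == 0 and a.identity == 1.0
        assert (a.ref_start, a.ref_end, a.strand) == (201, 260, "+")

    def test_reverse_orientation_detected(self, mini_genome):
        ref = mini_genome.sequence
        a = mthap.align_read(_read(mthap.revcomp(ref[300:380])), ref,
                             AlignParams())
        assert a is not None and a.strand == "-"
        assert (a.ref_start, a.ref_end) == (301, 380)

    def test_one_mismatch_cost_two(self, mini_genome):
        ref = mini_genome.sequence
        bases = list(ref[500:520])
        bases[10] = "A" if bases[10] != "A" else "C"
        a = mthap.align_read(_read("".join(bases)), ref, AlignParams())
        assert a is not None
        assert a.cost == 2 and a.identity == pytest.approx(0.95)

    def test_identity_below_floor_rejected(self):
        # short fixture so no spurious second locus reaches 80% identity
        ref = "ATGACCTTAGGCTAACCGTTAGCATCAGGATCGATTACGTGCAATTGCCAGTCAGATCAA"
        bases = list(ref[20:30])
        for i in (2, 5, 8):
            bases[i] = "A" if bases[i] != "A" else "C"
        a = mthap.align_read(_read("".join(bases)), ref, AlignParams())
        assert a is None  # identity 0.70 < 0.80

    def test_deletion_recovered_by_dp(self, mini_genome):
        ref = mini_genome.sequence
        bases = ref[400:430] + ref[431:461]  # 60 bp spanning a 1 bp deletion
        a = mthap.align_read(_read(bases), ref, AlignParams())
        assert a is not None
        assert ("D", 1) in a.ops
        assert a.cost == 3

    def test_multimapping_excluded(self):
        unit = "ACGTAGCTTGCAAGCTACGGATCGTACGGTCA"  # 32 bp, repeated twice
        ref = unit + "T" * 40 + unit + "G" * 40
        a = mthap.align_read(_read(unit), ref, AlignParams())
        assert a is None


class TestDedup:
    def test_identical_reads_collapse(self, mini_genome):
        ref = mini_genome.sequence
        reads = [_read(ref[100:160], rid="a"), _read(ref[100:160], rid="b")]
        aligned = mthap.align_reads(reads, ref)
        kept, removed = mthap.dedup(aligned)
        assert len(kept) == 1 and removed == 1
        assert kept[0].id == "a"  # first seen survives

    def test_opposite_strands_both_kept(self, mini_genome):
        ref = mini_genome.sequence
        reads = [_read(ref[100:160], rid="f"),
                 _read(mthap.revcomp(ref[100:160]), rid="r")]
        kept, removed = mthap.dedup(mthap.align_reads(reads, ref))
        assert len(kept) == 2 and removed == 0

    def test_empty_input(self):
        kept, removed = mthap.dedup([])
        assert kept == [] and removed == 0


class TestPileup:
    def test_counts_split_by_strand(self, mini_genome):
        ref = mini_genome.sequence
        reads = [_read(ref[0:50], rid="f"),
                 _read(mthap.revcomp(ref[10:60]), rid="r")]
        pileup = build_pileup(mthap.align_reads(reads, ref), len(ref))
        assert pileup.depth[20] == 2
        counts = pileup.allele_counts(21)
        (allele, (fwd, rev)), = counts.items()
        assert allele == ref[20] and fwd == 1 and rev == 1

    def test_depth_is_count_sum(self, mini_genome):
        ref = mini_genome.sequence
        reads = [_read(ref[i: i + 40], rid=f"x{i}") for i in range(0, 200, 7)]
        pileup = build_pileup(mthap.align_reads(reads, ref), len(ref))
        assert np.array_equal(pileup.depth, pileup.counts.sum(axis=(0, 1)))


class TestConsensus:
    def _pileup_with_alt(self, genome, pos, alt, alt_frac, depth=100):
        ref = genome.sequence
        reads = []
        window = ref[pos - 30: pos + 30]
        alt_window = window[:29] + alt + window[30:]
        for i in range(depth):
            bases = alt_window if (i % 20) < alt_frac * 20 else window
            rid = f"p{i}"
            # vary spans so dedup keeps them
            reads.append(_read(bases[: 40 + i % 20], rid=rid))
        aligned, _ = mthap.dedup(mthap.align_reads(reads, ref))
        return build_pileup(aligned, len(ref))

    def test_majority_alt_adopted(self, mini_genome):
        pos = 900
        alt = "A" if mini_genome.base(pos) != "A" else "C"
        pileup = self._pileup_with_alt(mini_genome, pos, alt, 0.95)
        cons = mthap.build_consensus(pileup, mini_genome)
        assert cons.sequence[pos - 1] == alt

    def test_minority_alt_keeps_reference(self, mini_genome):
        pos = 900
        alt = "A" if mini_genome.base(pos) != "A" else "C"
        pileup = self._pileup_with_alt(mini_genome, pos, alt, 0.30)
        cons = mthap.build_consensus(pileup, mini_genome)
        assert cons.sequence[pos - 1] == mini_genome.base(pos)

    def test_low_depth_keeps_reference(self, mini_genome):
        pileup = build_pileup([], len(mini_genome.sequence))
        cons = mthap.build_consensus(pileup, mini_genome)
        assert cons.sequence == mini_genome.sequence


@pytest.fixture(scope="module")
def calls(mini_genome):
    ref = mini_genome
    spec = mthap.HeteroplasmySpec([
        mthap.HetVariant(400, ref.base(400),
                         "A" if ref.base(400) != "A" else "C", "SNV",
                         0.30),
        mthap.HetVariant(800, ref.base(800),
                         "G" if ref.base(800) != "G" else "T", "SNV",
                         0.02),
        mthap.HetVariant(1200, ref.base(1200),
                         "A" if ref.base(1200) != "A" else "C", "SNV",
                         0.30, strand_restrict="+"),
        mthap.HetVariant(1500, ref.base(1500), "", "deletion", 0.25),
    ])
    reads, truth = mthap.simulate_reads(
        ref, spec, mthap.ReadSimParams(depth=600, read_length=80,
                                       seed=21))
    calls, _, _ = mthap.call_variants(reads, ref)
    return {c.name: c for c in calls}, truth.set_index("position")



class TestCallingRules:
    """Threshold rules on a fast mini-genome at 600x."""

    def test_30pct_snv_called_accurately(self, calls):
        byname, truth = calls
        name = [n for n in byname if n.startswith("400")]
        assert len(name) == 1
        c = byname[name[0]]
        assert abs(c.frequency - truth.loc[400, "frequency"]) <= 0.015
        assert c.fwd_count >= 1 and c.rev_count >= 1
        assert c.fwd_count + c.rev_count >= 50

    def test_2pct_snv_not_called(self, calls):
        byname, _ = calls
        assert not any(n.startswith("800") for n in byname)

    def test_forward_only_variant_not_called(self, calls):
        byname, _ = calls
        assert not any(n.startswith("1200") for n in byname)

    def test_deletion_called(self, calls):
        byname, truth = calls
        name = [n for n in byname if "del" in n and n.startswith("1500")]
        assert len(name) == 1
        # short 80 bp reads absorb end-adjacent deletions into soft ends, so
        # the tolerance here is looser than at the production read length
        assert abs(byname[name[0]].frequency
                   - truth.loc[1500, "frequency"]) <= 0.035


def _call(pos, freq, alt="T", kind="SNV", ref="C"):
    support = max(1, int(round(freq * 1000)))
    return VariantCall(position=pos, ref=ref, alt=alt, kind=kind,
                       frequency=freq, fwd_count=support // 2 + 1,
                       rev_count=support // 2 + 1, depth=1000,
                       name=f"{pos}{ref}>{alt}")


class TestClassification:
    def test_snp_unique_to_one_haplotype(self):
        inds = {f"A{i}": [_call(100, 0.95)] for i in range(5)}
        inds.update({f"B{i}": [] for i in range(3)})
        haps = {k: k[0] for k in inds}
        out = mthap.classify_polymorphisms(inds, haps)
        assert all(c.cls == "haplotype_SNP" for c in out)

    def test_not_all_replicates_is_unclassified(self):
        inds = {"A1": [_call(100, 0.95)], "A2": [], "B1": []}
        haps = {"A1": "A", "A2": "A", "B1": "B"}
        out = mthap.classify_polymorphisms(inds, haps)
        assert [c.cls for c in out] == ["unclassified"]

    def test_heteroplasmic_band(self):
        out = mthap.classify_polymorphisms(
            {"A1": [_call(100, 0.30)]}, {"A1": "A"})
        assert out[0].cls == "heteroplasmic_variant"

    def test_70pct_unclassified(self):
        out = mthap.classify_polymorphisms(
            {"A1": [_call(100, 0.70)]}, {"A1": "A"})
        assert out[0].cls == "unclassified"

    def test_partition_is_total(self):
        rng = np.random.default_rng(0)
        inds = {f"i{k}": [_call(100 + j, float(rng.uniform(0.03, 0.99)))
                          for j in range(5)] for k in range(4)}
        haps = {k: "AB"[i % 2] for i, k in enumerate(inds)}
        out = mthap.classify_polymorphisms(inds, haps)
        assert len(out) == sum(len(v) for v in inds.values())
        assert {c.cls for c in out} <= {"haplotype_SNP",
                                        "heteroplasmic_variant",
                                        "unclassified"}

    def test_missing_individual_errors(self):
        with pytest.raises(MthapError):
            mthap.classify_polymorphisms({"A1": []}, {})


class TestSusceptibility:
    def test_density_normalized_to_length(self, mini_genome):
        variants = [_call(150, 0.2), _call(300, 0.2)]
        df = mthap.susceptibility_profile(variants, mini_genome)
        row = df[df.region == "geneA"].iloc[0]
        assert row.variant_count == 2 and row.length_bp == 900
        assert row.density == pytest.approx(2 / 900)

    def test_zero_variants_zero_density(self, mini_genome):
        df = mthap.susceptibility_profile([], mini_genome)
        assert (df.density == 0).all()

    def test_overlap_counted_in_both(self, reference):
        variants = [_call(7945, 0.2)]  # inside the ATPase8/ATPase6 overlap
        df = mthap.susceptibility_profile(variants, reference)
        a8 = df[df.region == "ATPase8"].iloc[0]
        a6 = df[df.region == "ATPase6"].iloc[0]
        assert a8.variant_count == 1 and a6.variant_count == 1
        # the complex V tally sums its member genes
        v = df[(df.level == "complex") & (df.region == "V")].iloc[0]
        assert v.variant_count == 2

    def test_complex_sums_members(self, reference):
        rng = np.random.default_rng(5)
        variants = [_call(int(p), 0.2)
                    for p in rng.integers(1, reference.length, size=60)]
        df = mthap.susceptibility_profile(variants, reference)
        for cplx in "I III IV V".split():
            members = df[(df.level == "feature") & (df["complex"] == cplx)
                         & (df.kind == "CDS")]
            total = df[(df.level == "complex") & (df.region == cplx)]
            assert total.iloc[0].variant_count == members.variant_count.sum()
            assert total.iloc[0].length_bp == members.length_bp.sum()

    def test_intergenic_tallied(self, reference):
        df = mthap.susceptibility_profile([_call(6879, 0.2)], reference)
        assert df[df.region == "intergenic"].iloc[0].variant_count == 1


class TestVariantLoad:
    def test_arithmetic_mean(self):
        inds = {f"s{i}": [_call(100 + j, 0.10) for j in range(n)]
                for i, n in enumerate([10, 14, 12])}
        load = mthap.variant_load(inds, {k: "A" for k in inds})
        assert load == {"A": 12.0}

    def test_frequency_floor(self):
        inds = {"s": [_call(1, 0.10), _call(2, 0.30), _call(3, 0.40)]}
        load = mthap.variant_load(inds, {"s": "A"}, frequency_floor=0.25)
        assert load == {"A": 2.0}

    def test_single_sample(self):
        load = mthap.variant_load({"s": [_call(1, 0.2)]}, {"s": "B"})
        assert load == {"B": 1.0}

    def test_snps_not_counted(self):
        load = mthap.variant_load({"s": [_call(1, 0.99)]}, {"s": "A"})
        assert load == {"A": 0.0}
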