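"""Determinism, noise calibration and truth consistency of the generator."""

import math

import numpy as np
import pytest

from cisphase import io_core
from cisphase.synthetic_data import (
    SimulationConfig,
    simulate_allele_counts,
    simulate_cohort,
    simulate_linked_reads,
    simulate_long_reads,
    simulate_region,
    emit_fixture,
    read_tss_tags,
)


def _consistent_with_one_haplotype(mol, haplotypes):
    return any(
        all(hap[p] == base for p, (base, _) in mol.observations.items())
        for hap in haplotypes
    )


class TestSimulateRegion:
    def test_diploid_haplotypes_differ_at_every_site(self):
        cfg = SimulationConfig(seed=1, ploidy=2, n_het_sites=10)
        t = simulate_region(cfg)
        assert len(t.het_positions) == 10
        h1, h2 = t.haplotypes
        assert all(h1[p] != h2[p] for p in t.het_positions)

    def test_haploid_emits_no_het_sites(self):
        t = simulate_region(SimulationConfig(seed=1, ploidy=1))
        assert t.snvs == [] and t.het_positions == ()

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=3, ploidy=3)
        a, b = simulate_region(cfg), simulate_region(cfg)
        assert a.reference == b.reference
        assert a.haplotypes == b.haplotypes
        assert [s.key for s in a.snvs] == [s.key for s in b.snvs]
        ma = simulate_linked_reads(a, cfg)
        mb = simulate_linked_reads(b, cfg)
        assert [(m.molecule_id, m.observations) for m in ma] == [
            (m.molecule_id, m.observations) for m in mb
        ]

    def test_every_het_site_has_two_alleles(self):
        t = simulate_region(SimulationConfig(seed=2, ploidy=4, indel_fraction=0.3))
        for p in t.het_positions:
            assert len({h[p] for h in t.haplotypes}) >= 2

    def test_min_spacing(self):
        t = simulate_region(SimulationConfig(seed=4, ploidy=2, n_het_sites=30))
        pos = t.het_positions
        assert all(b - a >= 2 for a, b in zip(pos, pos[1:]))

    def test_too_dense_raises(self):
        with pytest.raises(ValueError):
            simulate_region(SimulationConfig(seed=0, region_length=60_000,
                                             n_het_sites=40_000))


class TestLinkedReads:
    def test_noiseless_molecules_consistent_with_truth(self):
        cfg = SimulationConfig(seed=5, ploidy=3, base_error_rate=0.0)
        t = simulate_region(cfg)
        for mol in simulate_linked_reads(t, cfg):
            assert _consistent_with_one_haplotype(mol, t.haplotypes)

    def test_short_molecules_cover_single_sites(self):
        cfg = SimulationConfig(seed=6, ploidy=2, molecule_length_mean=50,
                               molecules_per_haplotype=200)
        t = simulate_region(cfg)
        mols = simulate_linked_reads(t, cfg)
        multi = sum(1 for m in mols if len(m.observations) > 1)
        assert multi <= 0.05 * len(mols)

    def test_error_rate_matches_binomial_expectation(self):
        cfg = SimulationConfig(seed=7, ploidy=2, base_error_rate=0.5,
                               molecules_per_haplotype=2500,
                               molecule_length_mean=30_000, n_het_sites=8)
        t = simulate_region(cfg)
        mols = simulate_linked_reads(t, cfg)
        total = mismatch = 0
        hap_of = {}  # recover source haplotype by majority vote is unsafe at
        # 50% error; instead count mismatches against the closest haplotype
        # complement: with error 0.5, each observed base is wrong w.p. 0.5
        for m in mols:
            for p, (base, _) in m.observations.items():
                total += 1
                if all(base != h[p] for h in t.haplotypes):
                    mismatch += 1
        # a wrong base lands outside {hap bases} with prob >= 1/3 of errors;
        # exact accounting: error draws uniformly among 3 non-truth bases,
        # bases of the other haplotype included, so P(outside both alleles)
        # = 0.5 * 2/3 = 1/3 at biallelic SNP sites
        snp_sites = {s.pos for s in t.snvs if not s.is_indel}
        total_snp = mismatch_snp = 0
        for m in mols:
            for p, (base, _) in m.observations.items():
                if p not in snp_sites:
                    continue
                total_snp += 1
                if all(base != h[p] for h in t.haplotypes):
                    mismatch_snp += 1
        p_expected = 0.5 * (2 / 3)
        sigma = math.sqrt(p_expected * (1 - p_expected) / total_snp)
        assert abs(mismatch_snp / total_snp - p_expected) < 3 * sigma

    def test_adjacent_coverage_guarantee(self):
        cfg = SimulationConfig(seed=8, ploidy=3, molecules_per_haplotype=2,
                               molecule_length_mean=5_000,
                               ensure_adjacent_coverage=True)
        t = simulate_region(cfg)
        mols = simulate_linked_reads(t, cfg)
        pos = t.het_positions
        for hap in t.haplotypes:
            for a, b in zip(pos, pos[1:]):
                assert any(
                    a in m.observations and b in m.observations
                    and m.observations[a][0] == hap[a]
                    and m.observations[b][0] == hap[b]
                    for m in mols
                )


class TestLongReads:
    def test_identity_one_reads_match_truth(self):
        cfg = SimulationConfig(seed=9, ploidy=2, long_read_identity=1.0)
        t = simulate_region(cfg)
        for read in simulate_long_reads(t, cfg):
            assert any(
                all(hap[p] == b for p, (b, _) in read.observations.items())
                for hap in t.haplotypes
            )

    def test_identity_09_error_rate(self):
        cfg = SimulationConfig(seed=10, ploidy=2, long_read_identity=0.9,
                               long_reads_per_haplotype=800, n_het_sites=10)
        t = simulate_region(cfg)
        reads = simulate_long_reads(t, cfg)
        snp_sites = {s.pos for s in t.snvs if not s.is_indel}
        total = wrong = 0
        for r in reads:
            for p, (b, _) in r.observations.items():
                if p not in snp_sites:
                    continue
                total += 1
                if all(b != h[p] for h in t.haplotypes):
                    wrong += 1
        p_expected = 0.1 * (2 / 3)  # errors landing outside both alleles
        sigma = math.sqrt(p_expected * (1 - p_expected) / total)
        assert abs(wrong / total - p_expected) < 3 * sigma


class TestAlleleCounts:
    def test_null_effect_matches_wgs_ratio_in_expectation(self):
        cfg = SimulationConfig(seed=11, ploidy=2, effect_haplotype=None,
                               assay_depth=4000, wgs_depth=4000)
        t = simulate_region(cfg)
        counts = simulate_allele_counts(t, cfg)
        by_assay = {}
        for c in counts:
            by_assay.setdefault(c.key, {})[c.assay] = c
        for key, assays in by_assay.items():
            if "RNA" not in assays:
                continue
            wgs, rna = assays["WGS"], assays["RNA"]
            assert abs(wgs.alt_tags / wgs.total - rna.alt_tags / rna.total) < 0.05

    def test_infinite_silencing_zeroes_silenced_allele(self):
        cfg = SimulationConfig(seed=12, ploidy=2, effect_haplotype=0,
                               effect_fold=float("inf"), assay_depth=300)
        t = simulate_region(cfg)
        counts = simulate_allele_counts(t, cfg)
        hap0 = t.haplotypes[0]
        target = t.regulatory_effects[0][1]
        for c in counts:
            if c.assay != "RNA" or t.transcript_of((c.chrom, c.pos)) != target:
                continue
            if hap0[c.pos] == c.alt:
                assert c.alt_tags == 0
            else:
                assert c.ref_tags == 0

    def test_tenfold_silencing_recovered_within_3_sigma(self):
        """Aggregated over seeds, the RNA/WGS allele odds ratio at affected
        sites estimates the injected 10-fold silencing."""
        a = b = c = d = 0  # pooled RNA alt/ref, WGS alt/ref
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, ploidy=2, effect_haplotype=0,
                                   effect_fold=10.0, assay_depth=200,
                                   wgs_depth=200)
            t = simulate_region(cfg)
            target = t.regulatory_effects[0][1]
            hap0 = t.haplotypes[0]
            by_key = {}
            for cnt in simulate_allele_counts(t, cfg):
                by_key.setdefault(cnt.key, {})[cnt.assay] = cnt
            for key, assays in by_key.items():
                if "RNA" not in assays:
                    continue
                if t.transcript_of((key[0], key[1])) != target:
                    continue
                rna, wgs = assays["RNA"], assays["WGS"]
                # orient so the silenced haplotype carries the "alt" side
                if hap0[key[1]] == key[3]:
                    a += rna.alt_tags; b += rna.ref_tags
                    c += wgs.alt_tags; d += wgs.ref_tags
                else:
                    a += rna.ref_tags; b += rna.alt_tags
                    c += wgs.ref_tags; d += wgs.alt_tags
        log_or = math.log((c / d) / (a / b))
        sigma = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or - math.log(10.0)) < 3 * sigma


class TestCohort:
    def test_imprinted_transcript_silenced_in_expected_fraction(self):
        cfg = SimulationConfig(seed=13, ploidy=2, n_samples=20, assay_depth=200)
        cohort = simulate_cohort(cfg, imprinted_sample_fraction=0.4)
        assert cohort.imprinted_transcripts == {"TX2"}
        hap0 = cohort.truth.haplotypes[0]
        tx2_sites = [
            s.pos for s in cohort.truth.snvs
            if cohort.truth.transcript_of((s.chrom, s.pos)) == "TX2"
        ]
        assert tx2_sites
        silenced_samples = set()
        for c in cohort.counts:
            if c.assay != "RNA" or c.pos not in tx2_sites:
                continue
            silenced_count = c.alt_tags if hap0[c.pos] == c.alt else c.ref_tags
            if silenced_count == 0:
                silenced_samples.add(c.sample_id)
        assert len(silenced_samples) == 8  # 40% of 20


def test_fixture_round_trips_through_readers(tmp_path):
    cfg = SimulationConfig(seed=14, ploidy=3, effect_haplotype=0)
    paths = emit_fixture(tmp_path, cfg)
    truth = simulate_region(cfg)

    snvs = io_core.read_vcf(paths["vcf"])
    assert [r.key for r in snvs] == [s.key for s in truth.snvs]

    mols = io_core.read_molecule_table(paths["molecules"])
    expected = simulate_linked_reads(truth, cfg)
    assert [(m.molecule_id, m.observations) for m in mols] == [
        (m.molecule_id, m.observations) for m in expected
    ]

    reads = io_core.read_long_read_table(paths["long_reads"])
    assert len(reads) == len(simulate_long_reads(truth, cfg))

    counts = io_core.read_allele_counts(paths["counts"])
    assert counts == simulate_allele_counts(truth, cfg)

    assert io_core.read_bed(paths["peaks"]) == truth.peaks
    assert io_core.read_bed(paths["tads"]) == truth.tads
    assert read_tss_tags(paths["tss_tags"]) == truth.tss_tags
    assert io_core.read_fasta(paths["reference"])[cfg.chrom] == truth.reference


@pytest.mark.parametrize("field,value", [
    ("ploidy", 0), ("ploidy", 6), ("base_error_rate", 1.5),
    ("indel_fraction", -0.1), ("effect_fold", 0.5), ("effect_haplotype", 5),
])
def test_config_validation(field, value):
    with pytest.raises(ValueError):
        SimulationConfig(**{field: value})
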