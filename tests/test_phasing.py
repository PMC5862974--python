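"""Unit and property tests for the non-diploid phasing scheme."""

import random

import pytest

from cisphase import phasing
from cisphase.records import Haplotype, PhaseBlock, PreliminaryHaplotype
from cisphase.synthetic_data import (
    SimulationConfig,
    simulate_linked_reads,
    simulate_region,
)

from conftest import (
    UnionFind,
    brute_force_maximal_groups,
    make_het_snv,
    make_index,
    make_molecule,
    random_molecule_instance,
)


class TestIndex:
    def test_molecule_observing_three_candidate_sites(self):
        snvs = [make_het_snv(p) for p in (100, 200, 300)]
        mol = make_molecule("MI1", {100: "A", 200: "C", 300: "A"})
        idx = phasing.build_snv_molecule_index(snvs, [mol])
        assert sorted(idx.mi_to_obs["MI1"]) == [100, 200, 300]

    def test_read_quality_threshold_is_strict(self):
        snvs = [make_het_snv(100)]
        mol = make_molecule("MI1", {100: "A"}, read_quality=20.0)
        idx = phasing.build_snv_molecule_index(snvs, [mol])
        assert "MI1" not in idx.mi_to_obs

    def test_base_quality_threshold_is_strict(self):
        snvs = [make_het_snv(100), make_het_snv(200)]
        mol = make_molecule("MI1", {100: "A", 200: "C"})
        mol.observations[200] = ("C", 20.0)
        idx = phasing.build_snv_molecule_index(snvs, [mol])
        assert sorted(idx.mi_to_obs["MI1"]) == [100]

    def test_non_candidate_positions_dropped(self):
        snvs = [make_het_snv(100)]
        mol = make_molecule("MI1", {500: "A"})
        idx = phasing.build_snv_molecule_index(snvs, [mol])
        assert idx.mi_to_obs == {}


class TestMergeMolecules:
    def test_compatible_merge(self):
        idx = make_index({"MI1": {100: "A"}, "MI2": {100: "A", 200: "G"}})
        (h,) = phasing.merge_molecules(idx)
        assert h.alleles == {100: "A", 200: "G"}
        assert h.member_mis == {"MI1", "MI2"}

    def test_conflict_split(self):
        idx = make_index({"MI1": {100: "A"}, "MI2": {100: "C"}})
        haps = phasing.merge_molecules(idx)
        assert [h.alleles for h in haps] == [{100: "A"}, {100: "C"}]

    def test_triploid_noiseless_molecules_match_brute_force(self):
        rng = random.Random(7)
        truth = [
            {p: hap[i] for i, p in enumerate((100, 200, 300, 400, 500, 600))}
            for hap in ("AAAAAA", "CCCCCC", "ACACAC")
        ]
        obs = {}
        for i in range(12):  # small enough for the exponential oracle
            hap = truth[i % 3]
            start = rng.randint(0, 4)
            span = sorted(hap)[start : start + rng.randint(2, 3)]
            obs[f"M{i:02d}"] = {p: hap[p] for p in span}
        idx = make_index(obs)
        got = {tuple(sorted(h.alleles.items())) for h in phasing.merge_molecules(idx)}
        assert got == brute_force_maximal_groups(obs)
        for truth_hap in truth:  # every truth haplotype is represented
            assert any(
                all(h_items.get(p) == b for p, b in truth_hap.items() if p in h_items)
                for h_items in (dict(t) for t in got)
            )

    @pytest.mark.parametrize("trial_seed", range(60))
    def test_random_instances_match_brute_force(self, trial_seed):
        rng = random.Random(trial_seed)
        obs = random_molecule_instance(rng, max_molecules=9, max_sites=5)
        idx = make_index(obs)
        got = {tuple(sorted(h.alleles.items())) for h in phasing.merge_molecules(idx)}
        assert got == brute_force_maximal_groups(obs)

    def test_input_order_invariance(self):
        rng = random.Random(3)
        obs = random_molecule_instance(rng, max_molecules=10, max_sites=5)
        base = phasing.merge_molecules(make_index(obs))
        shuffled_ids = list(obs)
        rng.shuffle(shuffled_ids)
        shuffled = phasing.merge_molecules(make_index({m: obs[m] for m in shuffled_ids}))
        assert [h.alleles for h in base] == [h.alleles for h in shuffled]


class TestPhaseBlocks:
    def test_isolated_site_discarded(self):
        idx = make_index({"MI1": {100: "A", 200: "G"}, "MI2": {900: "C"}})
        (block,) = phasing.define_phase_blocks(idx)
        assert block.positions == (100, 200)

    def test_transitive_chain(self):
        idx = make_index({"MI1": {100: "A", 200: "G"}, "MI2": {200: "G", 300: "T"}})
        (block,) = phasing.define_phase_blocks(idx)
        assert block.positions == (100, 200, 300)

    @pytest.mark.parametrize("trial_seed", range(40))
    def test_matches_union_find_oracle(self, trial_seed):
        rng = random.Random(1000 + trial_seed)
        obs = random_molecule_instance(rng)
        uf = UnionFind()
        for mol in obs.values():
            positions = sorted(mol)
            uf.find(positions[0])
            for a, b in zip(positions, positions[1:]):
                uf.union(a, b)
        expected = {c for c in uf.components() if len(c) >= 2}
        blocks = phasing.define_phase_blocks(make_index(obs))
        assert {frozenset(b.positions) for b in blocks} == expected


class TestSimilarity:
    @pytest.mark.parametrize(
        "h1,h2,expected",
        [
            ({100: "A", 200: "G"}, {100: "A", 200: "G"}, 2),
            ({100: "A", 200: "G"}, {100: "A", 200: "T"}, 0),
            ({100: "A"}, {200: "G"}, 0),  # disjoint pairs score 0
            ({100: "A", 200: "G", 300: "C"}, {200: "G", 300: "T"}, 0),
            ({100: "A", 200: "G", 300: "C"}, {100: "A", 300: "C"}, 2),
        ],
    )
    def test_compatible_minus_incompatible(self, h1, h2, expected):
        assert phasing.haplotype_similarity(h1, h2) == expected
        assert phasing.haplotype_similarity(h2, h1) == expected


class TestGreedyCompletion:
    def _prelim(self, alleles, mid):
        return PreliminaryHaplotype(alleles=alleles, member_mis=frozenset([mid]))

    def test_full_coverage_identity(self):
        block = PhaseBlock("b", "chr1", (100, 200))
        prelim = self._prelim({100: "A", 200: "G"}, "MI1")
        (h,) = phasing.greedy_complete_haplotypes(block, [prelim])
        assert h.alleles == {100: "A", 200: "G"}
        assert set(h.provenance.values()) == {"direct"}

    def test_zero_similarity_fill_and_conflict_exclusion(self):
        # A can only be completed by the disjoint B (similarity 0); C
        # conflicts with A and completes on its own.
        block = PhaseBlock("b", "chr1", (100, 200, 300))
        a = self._prelim({100: "A", 200: "G"}, "a")
        b = self._prelim({300: "T"}, "b")
        c = self._prelim({100: "C", 200: "T", 300: "C"}, "c")
        haps = phasing.greedy_complete_haplotypes(block, [a, b, c])
        maps = {tuple(sorted(h.alleles.items())) for h in haps}
        assert maps == {
            ((100, "A"), (200, "G"), (300, "T")),
            ((100, "C"), (200, "T"), (300, "C")),
        }
        # A is completed by B's disjoint fill; B's own completion duplicates
        # that allele map and is removed by deduplication.
        gap_filled = [h for h in haps if "gap_filled" in h.provenance.values()]
        assert len(gap_filled) == 1
        assert gap_filled[0].provenance[300] == "gap_filled"

    def test_incomplete_haplotypes_excluded_but_reported(self):
        block = PhaseBlock("b", "chr1", (100, 200, 300))
        a = self._prelim({100: "A"}, "a")
        b = self._prelim({200: "G"}, "b")
        incomplete = []
        haps = phasing.greedy_complete_haplotypes(block, [a, b], incomplete_out=incomplete)
        assert haps == []
        assert len(incomplete) == 2
        assert all(300 not in h.alleles for h in incomplete)


def test_regulatory_indel_phases_to_transcript_alleles():
    """A regulatory C/CA indel linked by molecules to three transcript SNPs
    resolves into exactly the two haplotypes C~T-A-C and CA~C-G-G."""
    reg, s1, s2, s3 = 38070511, 38080000, 38090000, 38100000
    snvs = [
        make_het_snv(reg, "C", "CA"),
        make_het_snv(s1, "T", "C"),
        make_het_snv(s2, "A", "G"),
        make_het_snv(s3, "C", "G"),
    ]
    molecules = [
        make_molecule("MI1", {reg: "C", s1: "T"}),
        make_molecule("MI2", {s1: "T", s2: "A"}),
        make_molecule("MI3", {s2: "A", s3: "C"}),
        make_molecule("MI4", {reg: "CA", s1: "C"}),
        make_molecule("MI5", {s1: "C", s2: "G"}),
        make_molecule("MI6", {s2: "G", s3: "G"}),
    ]
    result = phasing.phase(snvs, molecules)
    (block,) = result.blocks
    maps = {tuple(h.alleles[p] for p in block.positions) for h in block.haplotypes}
    assert maps == {("C", "T", "A", "C"), ("CA", "C", "G", "G")}


class TestPhaseStatistics:
    def test_single_block_span(self):
        b = PhaseBlock("b", "chr1", tuple(range(100, 1100, 100)))
        assert b.span_length == 901
        b2 = PhaseBlock("b2", "chr1", (100, 1099))
        stats = phasing.phase_statistics([b2])
        assert stats["longest_span"] == 1000

    def test_n50(self):
        blocks = [
            PhaseBlock("a", "chr1", (1, 100)),
            PhaseBlock("b", "chr1", (1000, 1199)),
            PhaseBlock("c", "chr1", (5000, 5699)),
        ]
        assert phasing.phase_statistics(blocks)["n50_span"] == 700

    def test_empty(self):
        stats = phasing.phase_statistics([])
        assert stats["n_blocks"] == 0
        assert stats["fraction_het_phased"] == 0.0

    def test_fraction_phased(self):
        blocks = [PhaseBlock("a", "chr1", (1, 100, 200))]
        stats = phasing.phase_statistics(blocks, n_eligible_het=12)
        assert stats["fraction_het_phased"] == pytest.approx(3 / 12)


class TestEndToEndProperties:
    @pytest.mark.parametrize("ploidy", [1, 2, 3, 4])
    def test_noiseless_sufficiency(self, ploidy):
        """With no errors and guaranteed adjacent co-coverage, the final
        haplotype set equals the truth set."""
        failures = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, ploidy=ploidy,
                                   ensure_adjacent_coverage=True)
            truth = simulate_region(cfg)
            molecules = simulate_linked_reads(truth, cfg)
            result = phasing.phase(truth.snvs, molecules)
            if ploidy == 1:
                assert result.blocks == []
                continue
            for block in result.blocks:
                expected = truth.haplotype_allele_sets(block.positions)
                got = {tuple(sorted(h.alleles.items())) for h in block.haplotypes}
                if got != expected:
                    failures += 1
        assert failures <= max(1, n_seeds // 10)

    def test_diploid_exactly_two_haplotypes(self):
        cfg = SimulationConfig(seed=5, ploidy=2, ensure_adjacent_coverage=True)
        truth = simulate_region(cfg)
        result = phasing.phase(truth.snvs, simulate_linked_reads(truth, cfg))
        for block in result.blocks:
            assert len(block.haplotypes) == 2

    def test_conflict_freedom_and_count_bound(self):
        cfg = SimulationConfig(seed=8, ploidy=3, ensure_adjacent_coverage=True)
        truth = simulate_region(cfg)
        molecules = simulate_linked_reads(truth, cfg)
        result = phasing.phase(truth.snvs, molecules)
        obs = {m.molecule_id: {p: b for p, (b, _) in m.observations.items()}
               for m in molecules}
        for block in result.blocks:
            assert len(block.haplotypes) <= len(result.preliminary)
            for mol in obs.values():
                # every molecule is explained by >= 1 reported haplotype
                assert any(
                    all(h.alleles.get(p) == b for p, b in mol.items()
                        if p in set(block.positions))
                    for h in block.haplotypes
                )

    def test_molecule_order_invariance(self):
        cfg = SimulationConfig(seed=9, ploidy=3, ensure_adjacent_coverage=True)
        truth = simulate_region(cfg)
        molecules = simulate_linked_reads(truth, cfg)
        base = phasing.phase(truth.snvs, molecules)
        shuffled = list(molecules)
        random.Random(0).shuffle(shuffled)
        other = phasing.phase(truth.snvs, shuffled)
        for b1, b2 in zip(base.blocks, other.blocks):
            assert b1.positions == b2.positions
            assert [h.alleles for h in b1.haplotypes] == [h.alleles for h in b2.haplotypes]
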