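"""Non-diploid haplotype phasing from barcoded linked-read molecules.

Diploid phasers force every variant into one of two haplotypes; aneuploid
cancer genomes break that assumption. The scheme implemented here makes no
ploidy assumption:

1. Index heterozygous candidate SNVs against molecules (molecular indexes,
   MIs), dropping low-quality reads and base calls (score must exceed 20).
2. Exhaustively merge compatible molecules into *preliminary haplotypes*.
   Two molecules are compatible when they share at least one SNV position
   and agree at every shared position; a molecule may belong to several
   preliminary haplotypes. The merge enumerates every maximal conflict-free
   group of molecules connected through shared positions, so the result is
   independent of input order.
3. Define *phase blocks* as connected components of the position graph in
   which two SNV positions are joined when some molecule observes both.
4. Complete each preliminary haplotype over its block by greedy gap
   filling: repeatedly merge in the most similar conflict-free preliminary
   haplotype that covers at least one missing position, where similarity is
   (#agreeing shared positions) - (#disagreeing shared positions) and 0 for
   disjoint pairs. Haplotypes that cannot be completed are reported but
   excluded from final counts.

Indels participate as biallelic markers keyed by their anchor position,
with the full allele string as the "base".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .records import (
    HETEROZYGOUS,
    PROV_DIRECT,
    PROV_GAP_FILLED,
    Haplotype,
    MoleculeObservation,
    PhaseBlock,
    PreliminaryHaplotype,
    SNVRecord,
)

logger = logging.getLogger(__name__)

#: strict lower bound on read and base-call scores ("score > 20")
DEFAULT_MIN_SCORE = 20.0


@dataclass
class SNVMoleculeIndex:
    """Bidirectional index between candidate het SNVs and molecules.

    Only quality-passing observations at candidate positions survive:
    molecules with read score <= min_score are dropped entirely, individual
    base calls with score <= min_score are dropped, and molecules left with
    no observations disappear from the index.
    """

    chrom: str
    snv_to_mis: dict[int, set[str]]
    mi_to_obs: dict[str, dict[int, str]]  # molecule -> pos -> base
    candidate_positions: frozenset[int]

    @property
    def molecules(self) -> list[str]:
        return sorted(
            self.mi_to_obs, key=lambda m: (min(self.mi_to_obs[m]), m)
        )


def build_snv_molecule_index(
    snvs: Sequence[SNVRecord],
    molecules: Iterable[MoleculeObservation],
    min_score: float = DEFAULT_MIN_SCORE,
) -> SNVMoleculeIndex:
    """Cross-reference heterozygous SNVs with molecule observations.

    Observations at non-candidate positions are discarded; quality filters
    are strict (score must be > ``min_score``).
    """
    het = [s for s in snvs if s.genotype_class == HETEROZYGOUS]
    chroms = {s.chrom for s in het}
    if len(chroms) > 1:
        raise ValueError(f"index is per-chromosome; got {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""
    candidates = frozenset(s.pos for s in het)

    snv_to_mis: dict[int, set[str]] = {p: set() for p in candidates}
    mi_to_obs: dict[str, dict[int, str]] = {}
    for mol in molecules:
        if mol.read_quality <= min_score:
            continue
        if chrom and mol.chrom != chrom:
            continue
        obs = {
            pos: base
            for pos, (base, bq) in mol.observations.items()
            if pos in candidates and bq > min_score
        }
        if not obs:
            continue
        mi_to_obs[mol.molecule_id] = obs
        for pos in obs:
            snv_to_mis[pos].add(mol.molecule_id)
    return SNVMoleculeIndex(
        chrom=chrom, snv_to_mis=snv_to_mis, mi_to_obs=mi_to_obs,
        candidate_positions=candidates,
    )


# ---------------------------------------------------------------------------
# Exhaustive merge into preliminary haplotypes
# ---------------------------------------------------------------------------

def _pair_relation(a: Mapping[int, str], b: Mapping[int, str]) -> str:
    """'agree' (overlap, no mismatch), 'conflict' (mismatch), or 'disjoint'."""
    shared = a.keys() & b.keys()
    if not shared:
        return "disjoint"
    for p in shared:
        if a[p] != b[p]:
            return "conflict"
    return "agree"


#: safety valve on the number of distinct partial-haplotype maps explored
MAX_MERGE_STATES = 200_000


def _maximal_consistent_groups(
    obs: dict[str, Mapping[int, str]]
) -> list[tuple[dict[int, str], frozenset[str]]]:
    """Unions of all maximal conflict-free, overlap-connected groups.

    A group is *consistent* when no two members disagree at a shared
    position (joint consistency equals pairwise consistency because every
    conflict involves exactly two molecules at one position) and
    *connected* when its members chain through shared, matching positions.
    Distinct maximal groups with identical allele-map unions are the same
    preliminary haplotype, so the search enumerates the *maps* directly: a
    breadth-first walk grows each map by every compatible overlapping
    molecule that contributes a new position, memoised on the map itself.
    A map no molecule can extend is the union of a maximal group; its
    member set is every molecule that overlaps it conflict-free.

    Returns (allele map, member molecule ids) pairs, deduplicated.
    """
    ids = sorted(obs, key=lambda m: (min(obs[m]), m))
    # collapse molecules with identical observation maps for the search
    reps: list[str] = []
    seen_sig: set[tuple] = set()
    for m in ids:
        sig = tuple(sorted(obs[m].items()))
        if sig not in seen_sig:
            seen_sig.add(sig)
            reps.append(m)

    from collections import deque

    visited: set[tuple] = set()
    maximal: set[tuple] = set()
    work: deque[tuple] = deque()
    for m in reps:
        sig = tuple(sorted(obs[m].items()))
        if sig not in visited:
            visited.add(sig)
            work.append(sig)
    while work:
        sig = work.popleft()
        current = dict(sig)
        extended = False
        for m in reps:
            om = obs[m]
            shared = om.keys() & current.keys()
            if not shared or len(shared) == len(om):
                new_positions = False
            else:
                new_positions = True
            if not shared:
                continue
            if any(current[p] != om[p] for p in shared):
                continue
            if not new_positions:
                continue
            extended = True
            new_sig = tuple(sorted((current | dict(om)).items()))
            if new_sig not in visited:
                if len(visited) > MAX_MERGE_STATES:
                    raise RuntimeError(
                        "molecule merge state space exceeded "
                        f"{MAX_MERGE_STATES}; data too ambiguous to phase"
                    )
                visited.add(new_sig)
                work.append(new_sig)
        if not extended:
            maximal.add(sig)

    out = []
    for sig in sorted(maximal):
        amap = dict(sig)
        members = frozenset(
            m for m in ids
            if (obs[m].keys() & amap.keys())
            and all(amap[p] == b for p, b in obs[m].items() if p in amap)
        )
        out.append((amap, members))
    out.sort(key=lambda pair: (min(pair[0]), _allele_string(pair[0])))
    return out


def merge_molecules(index: SNVMoleculeIndex) -> list[PreliminaryHaplotype]:
    """Exhaustively merge compatible molecules into preliminary haplotypes.

    Output is deduplicated on the allele map (identical maps merge their
    member molecule sets) and canonically ordered, so it is invariant to
    the input order of molecules.
    """
    if not index.mi_to_obs:
        return []
    prelims = [
        PreliminaryHaplotype(alleles=amap, member_mis=members)
        for amap, members in _maximal_consistent_groups(index.mi_to_obs)
    ]
    prelims.sort(key=lambda h: (h.start, _allele_string(h.alleles)))
    return prelims


def _allele_string(alleles: Mapping[int, str]) -> str:
    return ",".join(f"{p}:{alleles[p]}" for p in sorted(alleles))


# ---------------------------------------------------------------------------
# Phase blocks
# ---------------------------------------------------------------------------

def define_phase_blocks(index: SNVMoleculeIndex) -> list[PhaseBlock]:
    """Connected components of positions co-observed by >= 1 molecule.

    Singleton components (positions never co-observed with another) are
    discarded: a block needs at least two positions to phase anything.
    """
    g = nx.Graph()
    g.add_nodes_from(
        p for obs in index.mi_to_obs.values() for p in obs
    )
    for obs in index.mi_to_obs.values():
        pos = sorted(obs)
        for a, b in zip(pos, pos[1:]):
            g.add_edge(a, b)
    blocks = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        positions = tuple(sorted(comp))
        blocks.append(
            PhaseBlock(
                block_id=f"{index.chrom}:{positions[0]}",
                chrom=index.chrom,
                positions=positions,
            )
        )
    blocks.sort(key=lambda b: b.positions[0])
    return blocks


def assign_blocks(
    blocks: Sequence[PhaseBlock], prelims: Iterable[PreliminaryHaplotype]
) -> dict[str, list[PreliminaryHaplotype]]:
    """Attach each preliminary haplotype to the block containing it."""
    pos_to_block = {p: b.block_id for b in blocks for p in b.positions}
    grouped: dict[str, list[PreliminaryHaplotype]] = {b.block_id: [] for b in blocks}
    for h in prelims:
        bid = pos_to_block.get(h.start)
        if bid is None:
            continue  # singleton component, not reportable
        h.block_id = bid
        grouped[bid].append(h)
    return grouped


# ---------------------------------------------------------------------------
# Similarity and greedy completion
# ---------------------------------------------------------------------------

def haplotype_similarity(h1: Mapping[int, str], h2: Mapping[int, str]) -> int:
    """#(shared positions agreeing) - #(shared positions disagreeing).

    Pairs with no shared position score 0.
    """
    shared = h1.keys() & h2.keys()
    agree = sum(1 for p in shared if h1[p] == h2[p])
    return agree - (len(shared) - agree)


def _conflicts(a: Mapping[int, str], b: Mapping[int, str]) -> bool:
    return any(a[p] != b[p] for p in a.keys() & b.keys())


def greedy_complete_haplotypes(
    block: PhaseBlock,
    prelims: Sequence[PreliminaryHaplotype],
    incomplete_out: Optional[list[Haplotype]] = None,
) -> list[Haplotype]:
    """Complete each preliminary haplotype over all block positions.

    Starting from the preliminary haplotypes with the fewest missing
    positions, repeatedly merge in the most similar conflict-free
    preliminary haplotype covering >= 1 missing position. Ties go to the
    candidate with more filled positions, then canonical order (leftmost
    start, lexicographic allele string). Completed haplotypes are
    deduplicated; incompletable ones are appended to ``incomplete_out``
    (with gap positions absent from their allele maps) and excluded.
    """
    block_positions = set(block.positions)

    def canon(h: PreliminaryHaplotype):
        return (h.start, _allele_string(h.alleles))

    ordered = sorted(
        prelims,
        key=lambda h: (len(block_positions - h.alleles.keys()),) + canon(h),
    )
    completed: list[Haplotype] = []
    seen: set[tuple] = set()
    for seed in ordered:
        alleles = dict(seed.alleles)
        provenance = {p: PROV_DIRECT for p in alleles}
        missing = block_positions - alleles.keys()
        while missing:
            candidates = [
                c for c in ordered
                if (c.alleles.keys() & missing) and not _conflicts(alleles, c.alleles)
            ]
            if not candidates:
                break
            best = min(
                candidates,
                key=lambda c: (
                    -haplotype_similarity(alleles, c.alleles),
                    -len(c.alleles),
                    canon(c),
                ),
            )
            for p, base in best.alleles.items():
                if p not in alleles:
                    alleles[p] = base
                    provenance[p] = PROV_GAP_FILLED
            missing = block_positions - alleles.keys()
        hap = Haplotype(alleles=alleles, provenance=provenance)
        if missing:
            if incomplete_out is not None:
                incomplete_out.append(hap)
            continue
        sig = tuple(sorted(alleles.items()))
        if sig not in seen:
            seen.add(sig)
            completed.append(hap)
    completed.sort(key=lambda h: _allele_string(h.alleles))
    return completed


# ---------------------------------------------------------------------------
# Parsimonious haplotype selection
# ---------------------------------------------------------------------------

def select_parsimonious_haplotypes(
    block: PhaseBlock,
    haplotypes: Sequence[Haplotype],
    index: SNVMoleculeIndex,
) -> list[Haplotype]:
    """Smallest set of completed haplotypes explaining every block molecule.

    The exhaustive merge deliberately over-generates: wherever two true
    haplotypes agree over a stretch of sites, molecules ending inside the
    stretch can combine into chimeric but conflict-free groups. Reporting
    therefore keeps a minimum subset of completed haplotypes such that
    every molecule touching the block is consistent with at least one kept
    haplotype (molecules consistent with none - e.g. error-bearing ones -
    are left aside). Among minimum covers the one whose members are jointly
    consistent with the most molecules wins (haplotypes backed by more
    evidence are preferred); remaining ties break canonically on the sorted
    allele strings, so output is input-order invariant.
    """
    if not haplotypes:
        return []
    block_positions = set(block.positions)
    molecules = [
        obs for obs in index.mi_to_obs.values()
        if any(p in block_positions for p in obs)
    ]

    def explains(hap: Haplotype, obs: Mapping[int, str]) -> bool:
        return all(
            hap.alleles.get(p) == b for p, b in obs.items() if p in block_positions
        )

    coverable = []
    covers: list[set[int]] = [set() for _ in haplotypes]
    for obs in molecules:
        hit = False
        for i, hap in enumerate(haplotypes):
            if explains(hap, obs):
                covers[i].add(len(coverable))
                hit = True
        if hit:
            coverable.append(obs)
    universe = set(range(len(coverable)))
    if not universe:
        return list(haplotypes)

    order = sorted(range(len(haplotypes)),
                   key=lambda i: _allele_string(haplotypes[i].alleles))
    n = len(haplotypes)
    from itertools import combinations
    from math import comb

    for size in range(1, min(n, 10) + 1):
        if comb(n, size) > 500_000:
            break
        best: Optional[tuple] = None
        for combo in combinations(order, size):
            if set().union(*(covers[i] for i in combo)) == universe:
                key = (
                    -sum(len(covers[i]) for i in combo),
                    tuple(sorted(_allele_string(haplotypes[i].alleles) for i in combo)),
                )
                if best is None or key < best[0]:
                    best = (key, combo)
        if best is not None:
            chosen = sorted(best[1], key=lambda i: _allele_string(haplotypes[i].alleles))
            return [haplotypes[i] for i in chosen]
    # fallback for very large candidate sets: greedy cover
    chosen: list[int] = []
    remaining = set(universe)
    while remaining:
        pick = min(order, key=lambda i: (-len(covers[i] & remaining),
                                         _allele_string(haplotypes[i].alleles)))
        if not covers[pick] & remaining:
            break
        chosen.append(pick)
        remaining -= covers[pick]
    return [haplotypes[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# End-to-end per-chromosome driver and statistics
# ---------------------------------------------------------------------------

@dataclass
class PhasingResult:
    blocks: list[PhaseBlock]
    preliminary: list[PreliminaryHaplotype]
    incomplete: dict[str, list[Haplotype]] = field(default_factory=dict)
    n_eligible_het: int = 0


def phase(
    snvs: Sequence[SNVRecord],
    molecules: Iterable[MoleculeObservation],
    min_score: float = DEFAULT_MIN_SCORE,
    parsimony: bool = True,
) -> PhasingResult:
    """Run the full phasing scheme for one chromosome's candidate SNVs."""
    index = build_snv_molecule_index(snvs, molecules, min_score=min_score)
    prelims = merge_molecules(index)
    blocks = define_phase_blocks(index)
    grouped = assign_blocks(blocks, prelims)
    incomplete: dict[str, list[Haplotype]] = {}
    for block in blocks:
        failures: list[Haplotype] = []
        block.haplotypes = greedy_complete_haplotypes(
            block, grouped[block.block_id], incomplete_out=failures
        )
        if parsimony:
            block.haplotypes = select_parsimonious_haplotypes(
                block, block.haplotypes, index
            )
        if failures:
            incomplete[block.block_id] = failures
            logger.info(
                "block %s: %d haplotypes could not be completed",
                block.block_id, len(failures),
            )
    n_het = sum(1 for s in snvs if s.genotype_class == HETEROZYGOUS)
    return PhasingResult(
        blocks=blocks, preliminary=prelims, incomplete=incomplete,
        n_eligible_het=n_het,
    )


def phase_statistics(
    blocks: Sequence[PhaseBlock], n_eligible_het: Optional[int] = None
) -> dict:
    """Block count, span statistics, N50, fraction phased, haplotype counts."""
    if not blocks:
        return {
            "n_blocks": 0, "mean_span": 0.0, "longest_span": 0,
            "n50_span": 0, "fraction_het_phased": 0.0,
            "mean_haplotypes_per_block": 0.0, "n_positions_phased": 0,
        }
    spans = sorted((b.span_length for b in blocks), reverse=True)
    total = sum(spans)
    acc, n50 = 0, 0
    for s in spans:
        acc += s
        if acc * 2 >= total:
            n50 = s
            break
    n_pos = sum(len(b.positions) for b in blocks)
    frac = (n_pos / n_eligible_het) if n_eligible_het else 0.0
    return {
        "n_blocks": len(blocks),
        "mean_span": total / len(blocks),
        "longest_span": spans[0],
        "n50_span": n50,
        "fraction_het_phased": frac,
        "mean_haplotypes_per_block": (
            sum(len(b.haplotypes) for b in blocks) / len(blocks)
        ),
        "n_positions_phased": n_pos,
    }
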