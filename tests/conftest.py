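"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from cisphase.phasing import SNVMoleculeIndex
from cisphase.records import HETEROZYGOUS, MoleculeObservation, SNVRecord


def make_molecule(mid, obs, chrom="chr1", read_quality=60.0, base_quality=60.0):
    """Molecule from a simple {pos: base} dict."""
    return MoleculeObservation(
        molecule_id=mid,
        chrom=chrom,
        observations={p: (b, base_quality) for p, b in obs.items()},
        read_quality=read_quality,
    )


def make_het_snv(pos, ref="A", alt="C", chrom="chr1", **kw):
    kw.setdefault("support", 30)
    kw.setdefault("vaf", 0.5)
    return SNVRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                     genotype_class=HETEROZYGOUS, **kw)


def make_index(obs_by_mid, chrom="chr1"):
    """Index directly from {molecule_id: {pos: base}} (no quality filtering)."""
    positions = {p for obs in obs_by_mid.values() for p in obs}
    snv_to_mis = {p: {m for m, obs in obs_by_mid.items() if p in obs}
                  for p in positions}
    return SNVMoleculeIndex(
        chrom=chrom, snv_to_mis=snv_to_mis,
        mi_to_obs={m: dict(obs) for m, obs in obs_by_mid.items()},
        candidate_positions=frozenset(positions),
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_maximal_groups(obs):
    """All maximal consistent connected molecule subsets, as allele maps.

    Enumerates every subset (exponential; for small instances only),
    keeps those that are jointly conflict-free and connected through
    shared matching positions, filters to inclusion-maximal subsets and
    returns the set of deduplicated allele-map unions.
    """
    ids = list(obs)

    def consistent(group):
        for a, b in itertools.combinations(group, 2):
            shared = obs[a].keys() & obs[b].keys()
            if any(obs[a][p] != obs[b][p] for p in shared):
                return False
        return True

    def connected(group):
        group = list(group)
        seen, stack = {group[0]}, [group[0]]
        while stack:
            u = stack.pop()
            for v in group:
                if v in seen:
                    continue
                shared = obs[u].keys() & obs[v].keys()
                if shared and all(obs[u][p] == obs[v][p] for p in shared):
                    seen.add(v)
                    stack.append(v)
        return len(seen) == len(group)

    valid = [
        frozenset(g)
        for r in range(1, len(ids) + 1)
        for g in itertools.combinations(ids, r)
        if consistent(g) and connected(g)
    ]
    maximal = [g for g in valid if not any(g < h for h in valid)]
    maps = set()
    for g in maximal:
        m = {}
        for x in g:
            m.update(obs[x])
        maps.add(tuple(sorted(m.items())))
    return maps


class UnionFind:
    """Minimal union-find used as the phase-block partition oracle."""

    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self):
        comps = {}
        for x in self.parent:
            comps.setdefault(self.find(x), set()).add(x)
        return {frozenset(c) for c in comps.values()}


def random_molecule_instance(rng: random.Random, max_molecules=12, max_sites=6):
    """A random small molecule set over a shared position grid."""
    n = rng.randint(1, max_molecules)
    npos = rng.randint(2, max_sites)
    grid = list(range(100, 100 + npos * 10, 10))
    obs = {}
    for i in range(n):
        k = rng.randint(1, npos)
        positions = rng.sample(grid, k)
        obs[f"M{i}"] = {p: rng.choice("ACGT"[:2]) for p in positions}
    return obs
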