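"""Independent oracles used by the test suite.

These deliberately avoid the production code paths they check: MMPs are
found by quadratic all-pairs fragmentation comparison instead of core
indexing, and maximal simple paths come from networkx path enumeration
instead of the package's DFS.
"""

from __future__ import annotations

import itertools

import networkx as nx

from promiscope.ingest import Molecule
from promiscope.mmp import (
    MatchedMolecularPair,
    SizeRestrictions,
    enumerate_single_cuts,
)


def brute_force_mmps(
    molecules: dict[str, Molecule], restrictions: SizeRestrictions | None = None
) -> list[MatchedMolecularPair]:
    """All-pairs MMP search: compare every fragmentation of every pair of
    molecules directly, keeping per pair the decomposition with the largest
    core (ties broken lexicographically on (core, transformation))."""
    if restrictions is None:
        restrictions = SizeRestrictions()
    frags = {
        cid: enumerate_single_cuts(
            mol, restrictions=restrictions, include_hydrogen=True
        )
        for cid, mol in molecules.items()
    }
    out: list[MatchedMolecularPair] = []
    for ca, cb in itertools.combinations(sorted(molecules), 2):
        best = None
        for fa in frags[ca]:
            for fb in frags[cb]:
                if fa.core != fb.core or fa.substituent == fb.substituent:
                    continue
                if not restrictions.pair_ok(
                    fa.substituent_size, fb.substituent_size
                ):
                    continue
                cand = MatchedMolecularPair(
                    compound_a=ca,
                    compound_b=cb,
                    core=fa.core,
                    substituent_a=fa.substituent,
                    substituent_b=fb.substituent,
                    core_size=fa.core_size,
                    substituent_size_a=fa.substituent_size,
                    substituent_size_b=fb.substituent_size,
                )
                if (
                    best is None
                    or cand.core_size > best.core_size
                    or (
                        cand.core_size == best.core_size
                        and (cand.core, cand.transformation)
                        < (best.core, best.transformation)
                    )
                ):
                    best = cand
        if best is not None:
            out.append(best)
    return out


def mmp_signature(mmps) -> set[tuple]:
    return {
        (m.compound_a, m.compound_b, m.core, m.substituent_a, m.substituent_b)
        for m in mmps
    }


def exhaustive_maximal_paths(graph: nx.Graph, min_length: int) -> set[tuple[str, ...]]:
    """All maximal simple paths via networkx all_simple_paths over every
    node pair, plus isolated-edge/endpoint handling, deduplicated across
    orientations."""
    paths: set[tuple[str, ...]] = set()
    nodes = sorted(graph.nodes)
    candidates = []
    for s, t in itertools.permutations(nodes, 2):
        candidates.extend(nx.all_simple_paths(graph, s, t))
    for path in candidates:
        in_path = set(path)
        if any(n not in in_path for n in graph.neighbors(path[0])):
            continue
        if any(n not in in_path for n in graph.neighbors(path[-1])):
            continue
        if len(path) < min_length:
            continue
        fwd, rev = tuple(path), tuple(reversed(path))
        paths.add(min(fwd, rev))
    return paths
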