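"""Conservative assembly graph, walks and external-assembly mapping.

The graph is a condensed de Bruijn graph built from short accurate reads:
k-mers are counted, low-coverage k-mers and short dead-end tips are removed
(basic error correction), and maximal unambiguous chains are concatenated
into contig nodes.  The goal is conservative: short contigs with as few
internal errors as possible, leaving contiguity decisions to the
likelihood search.

An assembly is a set of walks: ordered, oriented traversals of contig nodes,
optionally interrupted by runs of Ns of known length (scaffold gaps).
Consecutive nodes of a walk overlap by k-1 bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx

from .sequtils import BASES, canonical, revcomp

__all__ = [
    "AssemblyGraph",
    "Walk",
    "Assembly",
    "GraphBuildError",
    "MappingError",
    "build_conservative_graph",
    "graph_from_contigs",
    "initial_assembly",
    "enumerate_short_loops",
    "map_external_assembly",
    "walk_sequence",
    "walk_layout",
]

Node = tuple[int, int]  # (contig id, strand)


class GraphBuildError(RuntimeError):
    pass


class MappingError(RuntimeError):
    pass


class AssemblyGraph:
    """Contig nodes with directed overlap edges.

    ``contigs`` maps id to the forward-strand sequence; edges connect
    oriented nodes ``(id, strand)`` whose sequences overlap by exactly
    ``k - 1`` bases.  The edge set is strand-symmetric: ``u -> v`` implies
    ``rc(v) -> rc(u)``.
    """

    def __init__(self, k: int, contigs: dict[int, str]):
        self.k = k
        self.contigs = contigs
        self.out: dict[Node, list[Node]] = {}
        self._build_edges()

    # -- construction -----------------------------------------------------
    def _build_edges(self) -> None:
        k = self.k
        by_prefix: dict[str, list[Node]] = {}
        for cid in sorted(self.contigs):
            for strand in (1, -1):
                seq = self.node_seq((cid, strand))
                by_prefix.setdefault(seq[: k - 1], []).append((cid, strand))
        for cid in sorted(self.contigs):
            for strand in (1, -1):
                node = (cid, strand)
                seq = self.node_seq(node)
                succ = by_prefix.get(seq[-(k - 1):], [])
                self.out[node] = sorted(succ)
        for node in self.out:
            self.out.setdefault(node, [])

    # -- basic accessors ---------------------------------------------------
    @staticmethod
    def rc(node: Node) -> Node:
        return (node[0], -node[1])

    def node_seq(self, node: Node) -> str:
        seq = self.contigs[node[0]]
        return seq if node[1] == 1 else revcomp(seq)

    def node_len(self, node: Node | int) -> int:
        cid = node[0] if isinstance(node, tuple) else node
        return len(self.contigs[cid])

    def successors(self, node: Node) -> list[Node]:
        return self.out.get(node, [])

    def predecessors(self, node: Node) -> list[Node]:
        return [self.rc(u) for u in self.out.get(self.rc(node), [])]

    def has_edge(self, u: Node, v: Node) -> bool:
        return v in self.out.get(u, ())

    def long_contigs(self, threshold: int = 500) -> list[int]:
        return sorted(cid for cid, seq in self.contigs.items() if len(seq) > threshold)

    def total_contig_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def to_gfa(self) -> str:
        lines = ["H\tVN:Z:1.0"]
        for cid in sorted(self.contigs):
            lines.append(f"S\t{cid}\t{self.contigs[cid]}")
        seen = set()
        for u, targets in sorted(self.out.items()):
            for v in targets:
                key = (u, v)
                if (self.rc(v), self.rc(u)) in seen:
                    continue
                seen.add(key)
                ou = "+" if u[1] == 1 else "-"
                ov = "+" if v[1] == 1 else "-"
                lines.append(f"L\t{u[0]}\t{ou}\t{v[0]}\t{ov}\t{self.k - 1}M")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# de Bruijn construction
# ---------------------------------------------------------------------------


def _count_kmers(seqs: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" not in km:
                counts[canonical(km)] += 1
    return counts


def _condense(kept: set[str], k: int) -> dict[int, str]:
    """Concatenate unambiguous k-mer chains into contig sequences."""

    def present(km: str) -> bool:
        return canonical(km) in kept

    def successors(km: str) -> list[str]:
        return [km[1:] + b for b in BASES if present(km[1:] + b)]

    def predecessors(km: str) -> list[str]:
        return [b + km[:-1] for b in BASES if present(b + km[:-1])]

    oriented: list[str] = []
    for km in kept:
        oriented.append(km)
        rc = revcomp(km)
        if rc != km:
            oriented.append(rc)
    oriented_set = set(oriented)

    def is_start(km: str) -> bool:
        preds = predecessors(km)
        if len(preds) != 1:
            return True
        return len(successors(preds[0])) != 1

    visited: set[str] = set()
    unitigs: list[str] = []
    for km in sorted(oriented_set):
        if km in visited or not is_start(km):
            continue
        chain = [km]
        visited.add(km)
        cur = km
        while True:
            succs = successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(predecessors(nxt)) != 1 or is_start(nxt) or nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(chain[0] + "".join(c[-1] for c in chain[1:]))
    # isolated cycles: every k-mer has in/out degree 1
    for km in sorted(oriented_set):
        if km in visited:
            continue
        chain = [km]
        visited.add(km)
        cur = km
        while True:
            nxt = successors(cur)[0]
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(chain[0] + "".join(c[-1] for c in chain[1:]))

    # keep one orientation per contig
    out: dict[int, str] = {}
    seen: set[str] = set()
    cid = 0
    for seq in sorted(unitigs, key=lambda s: (-len(s), s)):
        canon = min(seq, revcomp(seq))
        if canon in seen:
            continue
        seen.add(canon)
        out[cid] = canon
        cid += 1
    return out


def _clip_tips(contigs: dict[int, str], k: int) -> set[str]:
    """Drop short dead-end contigs; return the retained canonical k-mer set."""
    graph = AssemblyGraph(k, contigs)
    keep: set[str] = set()
    for cid, seq in contigs.items():
        dead_fwd = not graph.successors((cid, 1))
        dead_rev = not graph.successors((cid, -1))
        is_tip = (dead_fwd or dead_rev) and not (dead_fwd and dead_rev) and len(seq) < 2 * k
        if is_tip:
            continue
        for i in range(len(seq) - k + 1):
            keep.add(canonical(seq[i : i + k]))
    return keep


def build_conservative_graph(
    reads: Iterable[str],
    kmer_size: int = 21,
    min_count: int | None = None,
) -> AssemblyGraph:
    """Conservative de Bruijn graph from short accurate reads.

    K-mers with coverage below ``max(2, 0.1 * median)`` are dropped and
    dead-end tips shorter than ``2k`` clipped before unambiguous chains are
    condensed into contigs.
    """
    k = kmer_size
    counts = _count_kmers(reads, k)
    if not counts:
        raise GraphBuildError("no k-mers found in the input reads")
    if min_count is None:
        import numpy as np

        median = float(np.median(list(counts.values())))
        min_count = max(2, int(round(0.1 * median)))
    kept = {km for km, c in counts.items() if c >= min_count}
    if not kept:
        raise GraphBuildError(
            f"coverage too low: no k-mer reaches the threshold {min_count}"
        )
    contigs = _condense(kept, k)
    kept2 = _clip_tips(contigs, k)
    if kept2 and kept2 != kept:
        contigs = _condense(kept2, k)
    if not contigs:
        raise GraphBuildError("coverage too low to form any contig")
    return AssemblyGraph(k, contigs)


def graph_from_contigs(contigs: Iterable[str], kmer_size: int = 21) -> AssemblyGraph:
    """de Bruijn graph built directly from assembled sequence (fallback used
    when an external assembly cannot be mapped onto the read graph)."""
    counts = _count_kmers(contigs, kmer_size)
    if not counts:
        raise GraphBuildError("no k-mers found in the input contigs")
    condensed = _condense(set(counts), kmer_size)
    return AssemblyGraph(kmer_size, condensed)


# ---------------------------------------------------------------------------
# Walks and assemblies
# ---------------------------------------------------------------------------


@dataclass
class Walk:
    """Ordered, oriented contig traversal with optional N-gap segments.

    ``elements`` holds ``("node", cid, strand)`` and ``("gap", length)``
    entries; consecutive node entries must be joined by a graph edge.
    """

    elements: list[tuple]

    def nodes(self) -> list[Node]:
        return [(e[1], e[2]) for e in self.elements if e[0] == "node"]

    def contig_ids(self) -> list[int]:
        return [e[1] for e in self.elements if e[0] == "node"]

    def copy(self) -> "Walk":
        return Walk(list(self.elements))

    def reverse(self) -> "Walk":
        out = []
        for e in reversed(self.elements):
            if e[0] == "node":
                out.append(("node", e[1], -e[2]))
            else:
                out.append(e)
        return Walk(out)

    def is_valid(self, graph: AssemblyGraph) -> bool:
        if not self.elements:
            return False
        prev: Node | None = None
        for e in self.elements:
            if e[0] == "gap":
                if e[1] < 1:
                    return False
                prev = None
                continue
            if e[0] == "seq":
                if not e[1]:
                    return False
                prev = None
                continue
            node = (e[1], e[2])
            if e[1] not in graph.contigs:
                return False
            if prev is not None and not graph.has_edge(prev, node):
                return False
            prev = node
        return True


def walk_layout(walk: Walk, graph: AssemblyGraph) -> list[tuple[tuple, int, int]]:
    """Element spans on the walk's rendered sequence.

    Each entry is ``(element, start, end)``: the bases the element
    contributes once ``k - 1`` overlaps with its predecessor are merged.
    The first node after a walk start or a gap contributes its full
    sequence.
    """
    k = graph.k
    layout = []
    pos = 0
    prev_node = False
    for e in walk.elements:
        if e[0] == "gap":
            layout.append((e, pos, pos + e[1]))
            pos += e[1]
            prev_node = False
        elif e[0] == "seq":
            layout.append((e, pos, pos + len(e[1])))
            pos += len(e[1])
            prev_node = False
        else:
            length = graph.node_len(e[1])
            contrib = length - (k - 1) if prev_node else length
            layout.append((e, pos, pos + contrib))
            pos += contrib
            prev_node = True
    return layout


def walk_sequence(walk: Walk, graph: AssemblyGraph) -> str:
    """Render a walk: node sequences merged over ``k - 1`` overlaps, gaps as
    runs of N."""
    k = graph.k
    parts: list[str] = []
    prev_node = False
    prev: Node | None = None
    for e in walk.elements:
        if e[0] == "gap":
            parts.append("N" * e[1])
            prev_node = False
            prev = None
        elif e[0] == "seq":
            parts.append(e[1])
            prev_node = False
            prev = None
        else:
            node = (e[1], e[2])
            seq = graph.node_seq(node)
            if prev_node:
                if prev is not None and not graph.has_edge(prev, node):
                    raise RuntimeError(f"walk uses missing edge {prev} -> {node}")
                parts.append(seq[k - 1 :])
            else:
                parts.append(seq)
            prev = node
            prev_node = True
    return "".join(parts)


@dataclass
class Assembly:
    """A set of walks; the state evolved by the annealer."""

    walks: dict[int, Walk] = field(default_factory=dict)
    next_id: int = 0

    @classmethod
    def from_walks(cls, walks: Iterable[Walk]) -> "Assembly":
        asm = cls()
        for w in walks:
            asm.add(w)
        return asm

    def add(self, walk: Walk) -> int:
        wid = self.next_id
        self.walks[wid] = walk
        self.next_id += 1
        return wid

    def remove(self, wid: int) -> Walk:
        return self.walks.pop(wid)

    def copy(self) -> "Assembly":
        return Assembly({wid: w.copy() for wid, w in self.walks.items()}, self.next_id)

    def apply(self, removed: Sequence[int], added: Sequence[Walk]) -> list[int]:
        for wid in removed:
            self.remove(wid)
        return [self.add(w) for w in added]

    def sequences(self, graph: AssemblyGraph) -> dict[int, str]:
        return {wid: walk_sequence(w, graph) for wid, w in sorted(self.walks.items())}

    def placed_contigs(self) -> Counter:
        usage: Counter = Counter()
        for w in self.walks.values():
            for cid in w.contig_ids():
                usage[cid] += 1
        return usage


def initial_assembly(graph: AssemblyGraph, long_threshold: int = 500) -> Assembly:
    """One single-node walk per long contig; short contigs stay unplaced."""
    longs = graph.long_contigs(long_threshold)
    if not longs:
        raise GraphBuildError(
            f"no contig exceeds {long_threshold} bp; cannot seed an assembly"
        )
    return Assembly.from_walks(Walk([("node", cid, 1)]) for cid in longs)


def enumerate_short_loops(graph: AssemblyGraph, max_nodes: int = 5) -> list[list[Node]]:
    """All directed cycles of at most ``max_nodes`` oriented nodes."""
    g = nx.DiGraph()
    for u, targets in graph.out.items():
        g.add_node(u)
        for v in targets:
            g.add_edge(u, v)
    loops = []
    seen = set()
    for cycle in nx.simple_cycles(g, length_bound=max_nodes):
        # normalise rotation for dedup
        idx = min(range(len(cycle)), key=lambda i: cycle[i])
        rot = tuple(cycle[idx:] + cycle[:idx])
        if rot in seen:
            continue
        seen.add(rot)
        loops.append(list(rot))
    loops.sort(key=lambda c: (len(c), c))
    return loops


def loops_by_node(loops: Sequence[Sequence[Node]]) -> dict[Node, list[int]]:
    index: dict[Node, list[int]] = {}
    for i, loop in enumerate(loops):
        for node in loop:
            index.setdefault(node, []).append(i)
    return index


# ---------------------------------------------------------------------------
# Mapping an external assembly onto the graph
# ---------------------------------------------------------------------------


def _contig_matches(external: str, graph: AssemblyGraph, identity: float) -> list[tuple]:
    """High-identity placements of whole graph contigs inside ``external``."""
    matches = []
    for cid in sorted(graph.contigs):
        for strand in (1, -1):
            seq = graph.node_seq((cid, strand))
            kmax = int((1.0 - identity) * len(seq))
            res = edlib.align(seq, external, mode="HW", task="locations", k=kmax)
            if res["editDistance"] < 0:
                continue
            for s, e in res["locations"][:8]:
                matches.append((s, e + 1, cid, strand, res["editDistance"]))
    matches.sort(key=lambda m: (m[0], m[1], m[4]))
    return matches


def _chain_matches(matches: list[tuple], k: int) -> list[tuple]:
    """Greedy colinear chain of non-conflicting contig placements."""
    chain: list[tuple] = []
    last_end = -(10**9)
    for m in sorted(matches, key=lambda m: (m[0], m[4], -(m[1] - m[0]))):
        s, e, cid, strand, dist = m
        if s >= last_end - (k - 1) - 5 and e > last_end:
            chain.append(m)
            last_end = e
    return chain


def _search_gap_path(
    graph: AssemblyGraph,
    src: Node,
    dst: Node,
    target_fill: str,
    edit_budget: int,
    max_nodes: int = 12,
    max_states: int = 4000,
) -> list[Node] | None:
    """Interior node path from ``src`` to ``dst`` whose contributed sequence
    is within ``edit_budget`` edits of ``target_fill`` (DP abandoned beyond
    the budget)."""
    k = graph.k
    limit = len(target_fill) + edit_budget
    best: tuple[int, list[Node]] | None = None
    stack: list[tuple[Node, str, list[Node]]] = [(src, "", [])]
    states = 0
    while stack and states < max_states:
        node, interior, path = stack.pop()
        states += 1
        if len(path) > max_nodes or len(interior) > limit:
            continue
        for nxt in graph.successors(node):
            if nxt == dst:
                dist = edlib.align(interior, target_fill, mode="NW", task="distance")[
                    "editDistance"
                ]
                if dist <= edit_budget and (best is None or dist < best[0]):
                    best = (dist, path)
                continue
            contribution = graph.node_seq(nxt)[k - 1 :]
            stack.append((nxt, interior + contribution, path + [nxt]))
    return best[1] if best else None


def map_external_assembly(
    external_contigs: Sequence[str],
    graph: AssemblyGraph,
    identity: float = 0.95,
    edit_budget: int = 10,
) -> Assembly:
    """Represent an existing assembly as walks in the graph.

    Graph contigs covered entirely by high-identity alignments inside an
    external contig are chained left to right; gaps between consecutive
    placements are bridged by searching graph paths minimising the edit
    distance to the external sequence, abandoning beyond ``edit_budget``
    edits and emitting an N-gap of the spanned length instead.  Raises
    :class:`MappingError` if no external contig maps at all (callers fall
    back to building a graph from the external assembly itself).
    """
    k = graph.k
    walks: list[Walk] = []
    for external in external_contigs:
        chain = _chain_matches(_contig_matches(external, graph, identity), k)
        if not chain:
            continue
        elements: list[tuple] = [("node", chain[0][2], chain[0][3])]
        for prev, cur in zip(chain, chain[1:]):
            a_end = prev[1]
            b_start = cur[0]
            src: Node = (prev[2], prev[3])
            dst: Node = (cur[2], cur[3])
            direct_gap = b_start - a_end + (k - 1)
            if graph.has_edge(src, dst) and abs(direct_gap) <= 5:
                elements.append(("node", dst[0], dst[1]))
                continue
            fill_end = min(len(external), b_start + k - 1)
            target_fill = external[a_end:fill_end] if fill_end > a_end else ""
            path = _search_gap_path(graph, src, dst, target_fill, edit_budget)
            if path is not None:
                for node in path:
                    elements.append(("node", node[0], node[1]))
                elements.append(("node", dst[0], dst[1]))
            else:
                gap = max(1, b_start - a_end)
                elements.append(("gap", gap))
                elements.append(("node", dst[0], dst[1]))
        walks.append(Walk(elements))
    if not walks:
        raise MappingError("no external contig could be mapped onto the graph")
    return Assembly.from_walks(walks)
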