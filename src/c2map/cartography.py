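"""C2 beta-sandwich recognition, topology typing, boundaries and loops.

A candidate C2 domain is a set of eight strands forming two four-stranded
sheets whose faces pack within :data:`SANDWICH_DIST` of each other.  The
candidate's observed strand-pairing adjacency (strands renamed 1..8 by
sequence order) is matched against the Type-I and Type-II templates; domain
boundaries run from the first residue of strand 1 that takes part in an
inter-strand backbone H-bond through the last such residue of strand 8.
Inter-strand segments are named beta-i-j loops; the loops clustered on the
pocket face (the side of the sandwich mid-plane holding the beta-1-2
connection) are additionally named loop1..loop3 in sequence order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import templates
from .errors import AnnotationError
from .secstruct import (HBondGraph, SheetTopology, Strand, assign_strands,
                        build_hbond_graph, place_amide_hydrogens, ss_string)
from .structure import Structure

logger = logging.getLogger(__name__)

#: Maximal mean facing-strand CA distance for two sheets to count as packed.
SANDWICH_DIST = 11.0
#: Strands split by <= this many residues and paired to the same partner
#: are merged before candidate search.
SPLIT_MERGE_GAP = 2


def loop_name(i: int) -> str:
    return f"b{i}-{i + 1}"


LOOP_NAMES = tuple(loop_name(i) for i in range(1, 8))


@dataclass
class C2Candidate:
    """Eight strands (by SheetTopology index) in sequence order, plus the
    4+4 sheet split that made them a sandwich."""

    chain: str
    strand_indices: tuple[int, ...]        # sequence order, len 8
    sheet_split: tuple[frozenset[int], frozenset[int]]

    def ordinal_of(self, strand_index: int) -> int:
        return self.strand_indices.index(strand_index) + 1


@dataclass
class C2Annotation:
    chain: str
    strands: list[Strand]                  # the 8 member strands, sequence order
    boundaries: tuple[int, int]            # closed [start, end] in seq_id
    topology: str                          # Type-I | Type-II | ambiguous
    loops: dict[str, Optional[tuple[int, int]]]
    apex_loops: dict[str, str] = field(default_factory=dict)  # loop1 -> b1-2 ...
    pocket: Optional[object] = None        # PocketCensus, filled by seq_features
    subdomains: list = field(default_factory=list)

    def strand_interval(self, ordinal: int) -> tuple[int, int]:
        st = self.strands[ordinal - 1]
        return (st.first, st.last)

    def loop_interval(self, name: str) -> Optional[tuple[int, int]]:
        if name in self.apex_loops:
            name = self.apex_loops[name]
        return self.loops.get(name)


def _merge_split_strands(topo: SheetTopology, s: Structure) -> SheetTopology:
    """Merge adjacent strands separated by <= SPLIT_MERGE_GAP residues that
    pair to the same partner (an over-split strand, not two real strands)."""
    strands = [Strand(st.chain, st.first, st.last, st.index, st.first_idx, st.last_idx)
               for st in topo.strands]
    merged = True
    pairings = set(topo.pairings)
    while merged:
        merged = False
        for a, b in zip(strands, strands[1:]):
            if a.chain != b.chain:
                continue
            if b.first_idx - a.last_idx - 1 > SPLIT_MERGE_GAP:
                continue
            partners_a = {x for p, q, _ in pairings for x in (p, q) if a.index in (p, q)} - {a.index}
            partners_b = {x for p, q, _ in pairings for x in (p, q) if b.index in (p, q)} - {b.index}
            if not (partners_a & partners_b):
                continue
            a.last, a.last_idx = b.last, b.last_idx
            strands.remove(b)
            pairings = {
                (min(p if p != b.index else a.index, q if q != b.index else a.index),
                 max(p if p != b.index else a.index, q if q != b.index else a.index),
                 o)
                for p, q, o in pairings
                if {p, q} != {a.index, b.index}
            }
            merged = True
            break
    # renumber and remap pairings
    remap = {st.index: k for k, st in enumerate(sorted(strands, key=lambda x: (x.chain, x.first_idx)), 1)}
    for st in strands:
        st.index = remap[st.index]
    strands.sort(key=lambda x: x.index)
    pairings = {(min(remap[a], remap[b]), max(remap[a], remap[b]), o)
                for a, b, o in pairings if a in remap and b in remap}
    adjacency: dict[int, set[int]] = {st.index: set() for st in strands}
    for a, b, _ in pairings:
        adjacency[a].add(b)
        adjacency[b].add(a)
    sheets, seen = [], set()
    for st in strands:
        if st.index in seen:
            continue
        comp, frontier = {st.index}, [st.index]
        while frontier:
            for nxt in adjacency[frontier.pop()]:
                if nxt not in comp:
                    comp.add(nxt)
                    frontier.append(nxt)
        seen |= comp
        sheets.append(comp)
    return SheetTopology(strands=strands, pairings=pairings, sheets=sheets)


def _sheet_distance(s: Structure, topo: SheetTopology,
                    sheet_a: set[int], sheet_b: set[int]) -> float:
    """Mean over CAs of one sheet of the distance to the nearest CA of the
    other sheet, symmetrised."""
    def cas(sheet):
        pts = []
        for idx in sheet:
            st = topo.strand_by_index(idx)
            chain = s.chains[st.chain]
            pts.extend(chain[k].ca for k in range(st.first_idx, st.last_idx + 1)
                       if chain[k].ca is not None)
        return np.array(pts)

    a, b = cas(sheet_a), cas(sheet_b)
    if len(a) == 0 or len(b) == 0:
        return np.inf
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def detect_c2_domains(topo: SheetTopology, s: Structure,
                      sandwich_dist: float = SANDWICH_DIST) -> list[C2Candidate]:
    """Maximal 8-strand candidates: two 4-strand sheets packed face to face.

    Overlapping candidates are resolved greedily; the one starting earlier
    in the sequence wins.
    """
    topo = _merge_split_strands(topo, s)
    four_sheets = [frozenset(sh) for sh in topo.sheets if len(sh) == 4]
    candidates = []
    for i, sa in enumerate(four_sheets):
        for sb in four_sheets[i + 1:]:
            members = sa | sb
            chains = {topo.strand_by_index(k).chain for k in members}
            if len(chains) != 1:
                continue
            if _sheet_distance(s, topo, set(sa), set(sb)) >= sandwich_dist:
                continue
            ordered = tuple(sorted(members,
                                   key=lambda k: topo.strand_by_index(k).first_idx))
            candidates.append(C2Candidate(chain=chains.pop(),
                                          strand_indices=ordered,
                                          sheet_split=(sa, sb)))
    candidates.sort(key=lambda c: topo.strand_by_index(c.strand_indices[0]).first_idx)
    chosen: list[C2Candidate] = []
    used: set[int] = set()
    for cand in candidates:
        if used & set(cand.strand_indices):
            continue
        chosen.append(cand)
        used |= set(cand.strand_indices)
    # candidates refer to the merged topology; return it for downstream use
    for cand in chosen:
        cand._topo = topo  # type: ignore[attr-defined]
    return chosen


def classify_topology(candidate: C2Candidate, topo: SheetTopology) -> str:
    """Match the candidate's pairing adjacency against both templates."""
    observed = set()
    for a, b, _ in topo.pairings:
        if a in candidate.strand_indices and b in candidate.strand_indices:
            observed.add(frozenset((candidate.ordinal_of(a), candidate.ordinal_of(b))))
    scores = {
        name: len(observed & templates.template_pairs(name))
        for name in (templates.TYPE_I, templates.TYPE_II)
    }
    best = max(scores.values())
    winners = [name for name, sc in scores.items() if sc == best]
    if best == 0 or len(winners) > 1:
        return templates.AMBIGUOUS
    return winners[0]


def extract_boundaries(candidate: C2Candidate, g: HBondGraph,
                       topo: SheetTopology, s: Structure) -> tuple[int, int]:
    """[start, end]: first H-bonded residue of strand 1 to the last H-bonded
    residue of strand 8, H-bonded meaning donor or acceptor of a backbone
    bond to the strand's paired strand(s)."""

    def bonded_seq_ids(ordinal: int) -> list[int]:
        strand = topo.strand_by_index(candidate.strand_indices[ordinal - 1])
        partners = topo.paired_with(strand.index)
        partner_positions = set()
        for p in partners:
            if p not in candidate.strand_indices:
                continue
            ps = topo.strand_by_index(p)
            partner_positions |= {(ps.chain, k)
                                  for k in range(ps.first_idx, ps.last_idx + 1)}
        chain = s.chains[strand.chain]
        out = []
        for k in range(strand.first_idx, strand.last_idx + 1):
            ref = (strand.chain, k)
            if g.partners(ref) & partner_positions:
                out.append(chain[k].seq_id)
        return out

    first = bonded_seq_ids(1)
    last = bonded_seq_ids(8)
    if not first or not last:
        raise AnnotationError("strand 1 or 8 has no inter-strand H-bond")
    return (min(first), max(last))


def label_loops(candidate: C2Candidate, topo: SheetTopology, s: Structure,
                boundaries: tuple[int, int]
                ) -> tuple[dict[str, Optional[tuple[int, int]]], dict[str, str]]:
    """Name inter-strand segments b1-2..b7-8 and the three pocket-apex loops.

    The apex test is geometric: a loop belongs to the pocket face if its
    midpoint CA falls on the same side of the sandwich mid-plane as the
    majority of the b1-2 segment.  The first three apex loops in sequence
    order become loop1 < loop2 < loop3.
    """
    chain = s.chains[candidate.chain]
    strands = [topo.strand_by_index(k) for k in candidate.strand_indices]
    loops: dict[str, Optional[tuple[int, int]]] = {}
    for i in range(7):
        a, b = strands[i], strands[i + 1]
        if b.first_idx - a.last_idx <= 1:
            loops[loop_name(i + 1)] = None  # no residues between the strands
        else:
            loops[loop_name(i + 1)] = (chain[a.last_idx + 1].seq_id,
                                       chain[b.first_idx - 1].seq_id)

    # sandwich frame: strand axis = mean of sign-aligned strand vectors
    pts = []
    vecs = []
    for st in strands:
        cas = [chain[k].ca for k in range(st.first_idx, st.last_idx + 1)
               if chain[k].ca is not None]
        pts.extend(cas)
        if len(cas) >= 2:
            v = cas[-1] - cas[0]
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                vecs.append(v / norm)
    pts = np.array(pts)
    center = pts.mean(axis=0)
    ref = vecs[0]
    axis = np.mean([v if np.dot(v, ref) >= 0 else -v for v in vecs], axis=0)
    axis = axis / max(np.linalg.norm(axis), 1e-9)

    def side_of(seq_interval: tuple[int, int]) -> float:
        cas = [r.ca for r in chain
               if seq_interval[0] <= r.seq_id <= seq_interval[1] and r.ca is not None]
        if not cas:
            return 0.0
        sides = np.sign((np.array(cas) - center) @ axis)
        return float(np.sign(sides.sum()))

    apex: dict[str, str] = {}
    ref_side = side_of(loops["b1-2"]) if loops.get("b1-2") else 0.0
    if ref_side == 0.0:
        logger.info("chain %s: apex clustering degenerate; loops keep b-i-j names",
                    candidate.chain)
        return loops, apex
    rank = 1
    for i in range(7):
        name = loop_name(i + 1)
        if loops[name] is None:
            continue
        if side_of(loops[name]) == ref_side and rank <= 3:
            apex[f"loop{rank}"] = name
            rank += 1
    return loops, apex


@dataclass
class AnnotationResult:
    structure: Structure          # with hydrogens placed
    graph: HBondGraph
    topology: SheetTopology
    annotations: list[C2Annotation]
    ss: dict[str, str]


def annotate_structure(s: Structure,
                       sandwich_dist: float = SANDWICH_DIST) -> AnnotationResult:
    """Full structural pipeline: H-bonds, sheets, C2 recognition, loops."""
    hs = place_amide_hydrogens(s)
    g = build_hbond_graph(hs)
    topo = assign_strands(g, hs)
    candidates = detect_c2_domains(topo, hs, sandwich_dist)
    annotations = []
    for cand in candidates:
        ctopo = cand._topo  # merged topology used during detection
        topology = classify_topology(cand, ctopo)
        bounds = extract_boundaries(cand, g, ctopo, hs)
        loops, apex = label_loops(cand, ctopo, hs, bounds)
        annotations.append(C2Annotation(
            chain=cand.chain,
            strands=[ctopo.strand_by_index(k) for k in cand.strand_indices],
            boundaries=bounds,
            topology=topology,
            loops=loops,
            apex_loops=apex,
        ))
    ss = {cid: ss_string(hs, cid, topo, g) for cid in hs.chains}
    return AnnotationResult(structure=hs, graph=g, topology=topo,
                            annotations=annotations, ss=ss)


def to_gff3(annotations: list[C2Annotation], source: str = "c2map") -> str:
    """GFF3 rendering (seqid = chain, 1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for n, ann in enumerate(annotations, 1):
        did = f"c2_{n}"
        start, end = ann.boundaries
        lines.append("\t".join([
            ann.chain, source, "domain", str(start), str(end), ".", ".", ".",
            f"ID={did};topology={ann.topology}"]))
        for k, st in enumerate(ann.strands, 1):
            lines.append("\t".join([
                ann.chain, source, "strand", str(st.first), str(st.last),
                ".", ".", ".", f"ID={did}.beta{k};Parent={did}"]))
        for name, interval in ann.loops.items():
            if interval is None:
                continue
            alias = [k for k, v in ann.apex_loops.items() if v == name]
            attrs = f"ID={did}.{name};Parent={did}"
            if alias:
                attrs += f";Alias={alias[0]}"
            lines.append("\t".join([
                ann.chain, source, "loop", str(interval[0]), str(interval[1]),
                ".", ".", ".", attrs]))
        for sub in ann.subdomains:
            lines.append("\t".join([
                ann.chain, source, "subdomain",
                str(sub.interval[0]), str(sub.interval[1]), ".", ".", ".",
                f"ID={did}.sub.{sub.host_loop};Parent={did};"
                f"ss_class={sub.ss_class}"]))
    return "\n".join(lines) + "\n"


def to_json(annotations: list[C2Annotation]) -> str:
    payload = []
    for ann in annotations:
        payload.append({
            "chain": ann.chain,
            "topology": ann.topology,
            "boundaries": list(ann.boundaries),
            "strands": [[st.first, st.last] for st in ann.strands],
            "loops": {k: (list(v) if v else None) for k, v in ann.loops.items()},
            "apex_loops": ann.apex_loops,
            "subdomains": [
                {"host_loop": sub.host_loop, "interval": list(sub.interval),
                 "length": sub.length, "ss_class": sub.ss_class,
                 "conserved_in": sorted(sub.conserved_in)}
                for sub in ann.subdomains
            ],
        })
    return json.dumps(payload, indent=2)
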