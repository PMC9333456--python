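"""Backbone hydrogen bonds and beta-sheet topology from coordinates.

Hydrogen bonds are scored with the Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

over the donor N-H and acceptor C=O groups, and accepted below -0.5
kcal/mol.  Beta-bridges follow the classical bridge patterns (with
``Hbond(i, j)`` meaning "CO of residue i accepts the amide H of residue
j"):

    parallel bridge(i, j):      Hbond(i-1, j) and Hbond(j, i+1)
                             or Hbond(j-1, i) and Hbond(i, j+1)
    antiparallel bridge(i, j):  Hbond(i, j)   and Hbond(j, i)
                             or Hbond(i-1, j+1) and Hbond(j-1, i+1)

Bridged residues are chained into ladders, ladders are merged across
single-residue beta-bulges, and the merged runs of length >= 3 become
strands.  Strand pairings and their parallel/antiparallel orientation,
plus the partition of strands into sheets (connected components of the
pairing graph), form the :class:`SheetTopology` consumed by the C2
recognition stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

logger = logging.getLogger(__name__)

#: Kabsch-Sander coupling constant q1*q2*f (kcal*A/mol).
KS_COUPLING = 0.084 * 332.0
#: Acceptance threshold for a backbone H-bond (kcal/mol).
HBOND_CUTOFF = -0.5
#: Sentinel returned on steric clash: "no bond possible".
NO_BOND = math.inf
#: Minimal sequence separation |donor - acceptor| within a chain.
MIN_SEQ_SEP = 2
#: Minimal number of bridged residues in a strand.
MIN_STRAND_LEN = 3
#: Maximal unbridged gap (residues, on the shorter strand) merged as a
#: beta-bulge, and the classical allowance on the longer strand.
BULGE_GAP = 1
BULGE_GAP_LONG = 4
#: CA-CA distance above which the chain is considered broken.
CHAIN_BREAK_CA = 4.5

ResRef = tuple[str, int]  # (chain id, position index within the chain)


@dataclass(frozen=True)
class HBond:
    """One backbone N-H -> C=O hydrogen bond with its Kabsch-Sander energy."""

    donor: ResRef
    acceptor: ResRef
    energy: float


@dataclass
class HBondGraph:
    bonds: list[HBond] = field(default_factory=list)
    by_donor: dict[ResRef, list[HBond]] = field(default_factory=dict)
    by_acceptor: dict[ResRef, list[HBond]] = field(default_factory=dict)

    def add(self, bond: HBond) -> None:
        self.bonds.append(bond)
        self.by_donor.setdefault(bond.donor, []).append(bond)
        self.by_acceptor.setdefault(bond.acceptor, []).append(bond)

    def has(self, donor: ResRef, acceptor: ResRef) -> bool:
        return any(b.acceptor == acceptor for b in self.by_donor.get(donor, ()))

    def partners(self, ref: ResRef) -> set[ResRef]:
        out = {b.acceptor for b in self.by_donor.get(ref, ())}
        out |= {b.donor for b in self.by_acceptor.get(ref, ())}
        return out


@dataclass
class Strand:
    chain: str
    first: int          # author seq_id of the first residue
    last: int           # author seq_id of the last residue
    index: int          # 1-based order along the sequence
    first_idx: int = 0  # position index within the chain
    last_idx: int = 0

    def __len__(self) -> int:
        return self.last_idx - self.first_idx + 1


@dataclass
class SheetTopology:
    strands: list[Strand]
    #: (strand index a, strand index b, 'parallel'|'antiparallel'), a < b
    pairings: set[tuple[int, int, str]]
    #: partition of strand indices into sheets (pairing-graph components)
    sheets: list[set[int]]

    def paired_with(self, index: int) -> set[int]:
        out = set()
        for a, b, _ in self.pairings:
            if a == index:
                out.add(b)
            elif b == index:
                out.add(a)
        return out

    def strand_by_index(self, index: int) -> Strand:
        for s in self.strands:
            if s.index == index:
                return s
        raise KeyError(index)


def place_amide_hydrogens(s: Structure) -> Structure:
    """Return a copy with amide hydrogens built at each peptide nitrogen.

    H is placed 1.0 A from N along the direction of the preceding residue's
    C=O bond (unit(C_prev - O_prev)), the standard DSSP construction.  The
    chain-leading residue and prolines get no amide H; residues with missing
    backbone atoms are skipped with a log message.  Pre-existing H atoms are
    retained.
    """
    out = s.copy()
    for cid, chain in out.chains.items():
        for prev, res in zip(chain, chain[1:]):
            if res.aa == "P" or "H" in res.atoms:
                continue
            if not ("C" in prev.atoms and "O" in prev.atoms and "N" in res.atoms):
                logger.debug("chain %s residue %d: incomplete backbone, no H placed",
                             cid, res.seq_id)
                continue
            if prev.ca is not None and res.ca is not None:
                if np.linalg.norm(prev.ca - res.ca) > CHAIN_BREAK_CA:
                    continue  # chain break: residue is effectively N-terminal
            co = prev.pos("C") - prev.pos("O")
            norm = np.linalg.norm(co)
            if norm < 1e-9:
                continue
            from .structure import Atom
            res.atoms["H"] = Atom("H", "H", res.pos("N") + co / norm)
    return out


def ks_energy(donor, acceptor) -> float:
    """Kabsch-Sander energy (kcal/mol) of the donor N-H vs acceptor C=O.

    Returns :data:`NO_BOND` if any of the four inter-atom distances falls
    below 0.5 A (steric clash; no physical bond).
    """
    n, h = donor.pos("N"), donor.pos("H")
    c, o = acceptor.pos("C"), acceptor.pos("O")
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return NO_BOND
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def build_hbond_graph(s: Structure, cutoff: float = HBOND_CUTOFF) -> HBondGraph:
    """All qualifying backbone H-bonds, keeping the best two per donor.

    Donors are residues with N and a placed H (so never chain-leading
    residues or prolines); acceptors need C and O.  Within a chain the
    donor and acceptor must be at least :data:`MIN_SEQ_SEP` residues apart.
    """
    graph = HBondGraph()
    donors: list[tuple[ResRef, object]] = []
    acceptors: list[tuple[ResRef, object]] = []
    for cid, chain in s.chains.items():
        for i, res in enumerate(chain):
            if "N" in res.atoms and "H" in res.atoms:
                donors.append(((cid, i), res))
            if "C" in res.atoms and "O" in res.atoms:
                acceptors.append(((cid, i), res))
    if not donors or not acceptors:
        return graph

    acc_pos = np.array([res.pos("O") for _, res in acceptors])
    tree = cKDTree(acc_pos)
    # E = -0.5 requires r_ON below ~5.2 A for backbone geometry; 6 A is safe.
    for ref, donor in donors:
        candidates = []
        for j in tree.query_ball_point(donor.pos("N"), 6.0):
            aref, acceptor = acceptors[j]
            if aref == ref:
                continue
            if aref[0] == ref[0] and abs(s.chains[ref[0]][aref[1]].seq_id
                                         - s.chains[ref[0]][ref[1]].seq_id) < MIN_SEQ_SEP:
                continue
            e = ks_energy(donor, acceptor)
            if e < cutoff:
                candidates.append(HBond(ref, aref, e))
        candidates.sort(key=lambda b: b.energy)
        for bond in candidates[:2]:  # best two acceptors per donor
            graph.add(bond)
    return graph


def _connected(chain, i: int, j: int) -> bool:
    """True if residues i..j are consecutive without a chain break."""
    for k in range(i, j):
        a, b = chain[k].ca, chain[k + 1].ca
        if a is None or b is None or np.linalg.norm(a - b) > CHAIN_BREAK_CA:
            return False
    return True


def assign_strands(g: HBondGraph, s: Structure) -> SheetTopology:
    """Beta-bridges -> ladders -> bulge-merged strands -> sheet topology."""
    bridges: dict[tuple[ResRef, ResRef], str] = {}

    def hbond(cid: str, i: int, j: int) -> bool:
        # Kabsch-Sander Hbond(i, j): CO of i accepts the amide H of j.
        return g.has((cid, j), (cid, i))

    for cid, chain in s.chains.items():
        n = len(chain)
        for i in range(1, n - 1):
            if not _connected(chain, i - 1, i + 1):
                continue
            for j in range(i + 3, n - 1):
                if not _connected(chain, j - 1, j + 1):
                    continue
                if (hbond(cid, i - 1, j) and hbond(cid, j, i + 1)) or \
                   (hbond(cid, j - 1, i) and hbond(cid, i, j + 1)):
                    bridges[((cid, i), (cid, j))] = "parallel"
                elif (hbond(cid, i, j) and hbond(cid, j, i)) or \
                     (hbond(cid, i - 1, j + 1) and hbond(cid, j - 1, i + 1)):
                    bridges[((cid, i), (cid, j))] = "antiparallel"

    # chain bridges of one orientation into ladders
    ladders: list[dict] = []
    by_key: dict[tuple, dict] = {}
    for (a, b), typ in sorted(bridges.items(),
                              key=lambda kv: (kv[0][0][0], kv[0][0][1],
                                              kv[0][1][1])):
        cid, i, j = a[0], a[1], b[1]
        prev = (cid, i - 1, j + 1 if typ == "antiparallel" else j - 1, typ)
        lad = by_key.get(prev)
        if lad is None:
            lad = {"chain": cid, "type": typ, "bridges": []}
            ladders.append(lad)
        lad["bridges"].append((i, j))
        by_key[(cid, i, j, typ)] = lad
    for lad in ladders:
        iis = [i for i, _ in lad["bridges"]]
        jjs = [j for _, j in lad["bridges"]]
        lad["i"] = (min(iis), max(iis))
        lad["j"] = (min(jjs), max(jjs))

    # merge ladders across beta-bulges: <= BULGE_GAP extra residues on one
    # strand and <= BULGE_GAP_LONG on the other, no chain break in between
    parent = list(range(len(ladders)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for x, l1 in enumerate(ladders):
        for y, l2 in enumerate(ladders):
            if x >= y or l1["chain"] != l2["chain"] or l1["type"] != l2["type"]:
                continue
            a, b = (l1, l2) if l1["i"][1] < l2["i"][0] else (l2, l1)
            if a["i"][1] >= b["i"][0]:
                continue
            g_i = b["i"][0] - a["i"][1] - 1
            if a["type"] == "antiparallel":
                if b["j"][1] >= a["j"][0]:
                    continue
                g_j = a["j"][0] - b["j"][1] - 1
                j_lo, j_hi = b["j"][1], a["j"][0]
            else:
                if a["j"][1] >= b["j"][0]:
                    continue
                g_j = b["j"][0] - a["j"][1] - 1
                j_lo, j_hi = a["j"][1], b["j"][0]
            if min(g_i, g_j) > BULGE_GAP or max(g_i, g_j) > BULGE_GAP_LONG:
                continue
            chain = s.chains[a["chain"]]
            if _connected(chain, a["i"][1], b["i"][0]) and \
                    _connected(chain, j_lo, j_hi):
                union(x, y)

    # each merged component contributes a residue interval per strand side;
    # overlapping intervals (a strand shared by two pairings) are unified
    intervals: dict[str, list[list[int]]] = {cid: [] for cid in s.chains}
    comps: dict[int, list[dict]] = {}
    for x, lad in enumerate(ladders):
        comps.setdefault(find(x), []).append(lad)
    for group in comps.values():
        cid = group[0]["chain"]
        for side in ("i", "j"):
            lo = min(l[side][0] for l in group)
            hi = max(l[side][1] for l in group)
            intervals[cid].append([lo, hi])

    strands: list[Strand] = []
    for cid, ivs in intervals.items():
        ivs.sort()
        merged_ivs: list[list[int]] = []
        for lo, hi in ivs:
            if merged_ivs and lo <= merged_ivs[-1][1]:
                merged_ivs[-1][1] = max(merged_ivs[-1][1], hi)
            else:
                merged_ivs.append([lo, hi])
        chain = s.chains[cid]
        for lo, hi in merged_ivs:
            if hi - lo + 1 >= MIN_STRAND_LEN:
                strands.append(Strand(chain=cid, first=chain[lo].seq_id,
                                      last=chain[hi].seq_id, index=0,
                                      first_idx=lo, last_idx=hi))

    strands.sort(key=lambda st: (st.chain, st.first_idx))
    for k, st in enumerate(strands, start=1):
        st.index = k

    def locate(ref: ResRef) -> int | None:
        for st in strands:
            if st.chain == ref[0] and st.first_idx <= ref[1] <= st.last_idx:
                return st.index
        return None

    pair_votes: dict[tuple[int, int], dict[str, int]] = {}
    for (a, b), orientation in bridges.items():
        sa, sb = locate(a), locate(b)
        if sa is None or sb is None or sa == sb:
            continue
        key = (min(sa, sb), max(sa, sb))
        votes = pair_votes.setdefault(key, {"parallel": 0, "antiparallel": 0})
        votes[orientation] += 1

    pairings = {
        (a, b, max(votes, key=votes.get))
        for (a, b), votes in pair_votes.items()
    }

    # sheets: connected components of the pairing graph
    adjacency: dict[int, set[int]] = {st.index: set() for st in strands}
    for a, b, _ in pairings:
        adjacency[a].add(b)
        adjacency[b].add(a)
    sheets: list[set[int]] = []
    seen: set[int] = set()
    for st in strands:
        if st.index in seen:
            continue
        component = {st.index}
        frontier = [st.index]
        while frontier:
            cur = frontier.pop()
            for nxt in adjacency[cur]:
                if nxt not in component:
                    component.add(nxt)
                    frontier.append(nxt)
        seen |= component
        sheets.append(component)

    return SheetTopology(strands=strands, pairings=pairings, sheets=sheets)


def ss_string(s: Structure, chain_id: str, topo: SheetTopology,
              g: HBondGraph) -> str:
    """Per-residue secondary-structure string: 'E' strand, 'H' helix, '-' coil.

    Helix marking is minimal: runs supported by two consecutive i+4 -> i
    backbone H-bonds (enough to classify ideal helical insertions); the
    full 8-state assignment is out of scope.
    """
    chain = s.chains[chain_id]
    n = len(chain)
    out = ["-"] * n
    for st in topo.strands:
        if st.chain == chain_id:
            for k in range(st.first_idx, st.last_idx + 1):
                out[k] = "E"
    for i in range(n - 5):
        if g.has((chain_id, i + 4), (chain_id, i)) and \
           g.has((chain_id, i + 5), (chain_id, i + 1)):
            for k in range(i + 1, i + 6):
                if out[k] == "-":
                    out[k] = "H"
    return "".join(out)


def secondary_structure(s: Structure) -> dict[str, str]:
    """Convenience driver: H placement, H-bond graph, strand assignment, ss."""
    hs = place_amide_hydrogens(s)
    g = build_hbond_graph(hs)
    topo = assign_strands(g, hs)
    return {cid: ss_string(hs, cid, topo, g) for cid in s.chains}
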