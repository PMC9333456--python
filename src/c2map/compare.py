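"""Structure-guided comparison of annotated C2 domains.

Covers least-squares rigid superposition (Kabsch, SVD form), strand-anchored
alignment of two annotated C2 domains, loop-insertion detection against a
reference domain, the subdomain-calling rule (insertion > 20 residues with a
matching secondary-structure class in at least two paralogs), stitching of
overlapping fragment models, and all-vs-all overlay RMSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cartography import C2Annotation, LOOP_NAMES
from .errors import AlignmentError, DegeneracyError, StitchError
from .structure import Structure

logger = logging.getLogger(__name__)

#: Minimal shared residues for stitching consecutive fragments.
MIN_OVERLAP = 10
#: Junction RMSD above which a stitch is flagged (still performed).
STITCH_TOL = 2.0
#: A called subdomain needs an insertion strictly longer than this.
SUBDOMAIN_MIN = 20
#: ... conserved in at least this many paralogs.
CONSERVATION_MIN = 2
#: Secondary-structure fraction above which an insertion is helix/sheet-rich.
SS_RICH_FRACTION = 0.4


def superpose_kabsch(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired point sets A onto B.

    Returns ``(R, t, rmsd)`` with ``R @ a + t`` the image of a point of A,
    R a proper rotation (det = +1).  Raises :class:`DegeneracyError` for
    fewer than 3 points or (near-)collinear input, where the rotation about
    the common axis is undetermined.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise DegeneracyError(f"need >= 3 paired points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    cov = a0.T @ b0
    u, sing, vt = np.linalg.svd(cov)
    scale = max(np.linalg.norm(a0, axis=1).max(), np.linalg.norm(b0, axis=1).max(), 1e-12)
    if sing[1] / (scale * scale * n) < 1e-12:
        raise DegeneracyError("collinear coordinates: rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cb - rot @ ca
    diff = (a0 @ rot.T) - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, t, rmsd


@dataclass
class Correspondence:
    """Residue pairing between two annotated domains.

    ``pairs`` holds ``((chain_a, seq_a), (chain_b, seq_b))`` tuples, strictly
    increasing in both sequences; ``strand_pairs`` is the subset inside
    matched strands (the set the RMSD is computed over).
    """

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    strand_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    rmsd: float


def _ca_by_seqid(s: Structure, chain: str) -> dict[int, np.ndarray]:
    return {r.seq_id: r.ca for r in s.chains[chain] if r.ca is not None}


def align_structures(a: tuple[C2Annotation, Structure],
                     b: tuple[C2Annotation, Structure]) -> Correspondence:
    """Strand-anchored rigid alignment of two annotated C2 domains.

    Strands are matched by ordinal (1..8); within a matched strand pair,
    residues pair positionally from the strand start up to the shorter
    strand length.  Loops pair likewise up to the shorter loop length.
    The reported RMSD is over strand-paired CA after Kabsch superposition.
    Domains of different topology types are refused.
    """
    ann_a, s_a = a
    ann_b, s_b = b
    if ann_a.topology != ann_b.topology:
        raise AlignmentError(
            f"topology mismatch: {ann_a.topology} vs {ann_b.topology}")

    strand_pairs = []
    for ordinal in range(1, 9):
        fa, la = ann_a.strand_interval(ordinal)
        fb, lb = ann_b.strand_interval(ordinal)
        for k in range(min(la - fa, lb - fb) + 1):
            strand_pairs.append(((ann_a.chain, fa + k), (ann_b.chain, fb + k)))

    pairs = list(strand_pairs)
    for name in LOOP_NAMES:
        ia, ib = ann_a.loops.get(name), ann_b.loops.get(name)
        if ia is None or ib is None:
            continue
        for k in range(min(ia[1] - ia[0], ib[1] - ib[0]) + 1):
            pairs.append(((ann_a.chain, ia[0] + k), (ann_b.chain, ib[0] + k)))
    pairs.sort()

    ca_a = _ca_by_seqid(s_a, ann_a.chain)
    ca_b = _ca_by_seqid(s_b, ann_b.chain)
    xa = np.array([ca_a[p[0][1]] for p in strand_pairs if p[0][1] in ca_a and p[1][1] in ca_b])
    xb = np.array([ca_b[p[1][1]] for p in strand_pairs if p[0][1] in ca_a and p[1][1] in ca_b])
    _, _, rmsd = superpose_kabsch(xa, xb)
    return Correspondence(pairs=pairs, strand_pairs=strand_pairs, rmsd=rmsd)


def detect_insertions(candidate: tuple[C2Annotation, Structure],
                      reference: tuple[C2Annotation, Structure]
                      ) -> list[tuple[str, int, tuple[int, int]]]:
    """Loop insertions of the candidate relative to the reference.

    Per inter-strand loop, the insertion length is the candidate loop length
    minus the reference loop length (floored at 0); the interval is the
    candidate residues left unpaired by :func:`align_structures` -- i.e. the
    trailing part of the candidate loop beyond the reference loop length.
    Only loops with a positive insertion are reported.
    """
    ann_c, ann_r = candidate[0], reference[0]
    out = []
    for name in LOOP_NAMES:
        ic, ir = ann_c.loops.get(name), ann_r.loops.get(name)
        len_c = 0 if ic is None else ic[1] - ic[0] + 1
        len_r = 0 if ir is None else ir[1] - ir[0] + 1
        extra = max(0, len_c - len_r)
        if extra > 0:
            interval = (ic[0] + len_r, ic[1])
            out.append((name, extra, interval))
    return out


@dataclass
class Subdomain:
    host_loop: str
    interval: tuple[int, int]
    length: int
    ss_class: str
    conserved_in: set[str] = field(default_factory=set)
    paralog: str = ""
    confirmed: bool = True


def classify_ss(ss_fragment: str) -> str:
    """helix-rich / sheet-rich / coil by the dominant >40% state."""
    n = max(len(ss_fragment), 1)
    frac_h = ss_fragment.count("H") / n
    frac_e = ss_fragment.count("E") / n
    if frac_h > SS_RICH_FRACTION and frac_h >= frac_e:
        return "helix-rich"
    if frac_e > SS_RICH_FRACTION:
        return "sheet-rich"
    return "coil"


def call_subdomains(insertion_sets: dict[str, list[tuple[str, int, tuple[int, int]]]],
                    ss: dict[str, dict[int, str]],
                    min_length: int = SUBDOMAIN_MIN,
                    min_conserved: int = CONSERVATION_MIN) -> list[Subdomain]:
    """Apply the subdomain rule across paralogs.

    A subdomain is called at a host loop iff at least ``min_conserved``
    paralogs carry an insertion strictly longer than ``min_length`` there
    and their secondary-structure classes agree.  ``ss`` maps each paralog
    to a seq_id -> 'H'/'E'/'-' map.  With a single paralog the conservation
    rule cannot be evaluated; its candidates are returned unconfirmed.
    """
    per_loop: dict[str, list[Subdomain]] = {}
    for paralog, insertions in insertion_sets.items():
        for name, length, interval in insertions:
            if length <= min_length:
                continue
            frag = "".join(ss[paralog].get(k, "-")
                           for k in range(interval[0], interval[1] + 1))
            per_loop.setdefault(name, []).append(Subdomain(
                host_loop=name, interval=interval, length=length,
                ss_class=classify_ss(frag), paralog=paralog))

    single = len(insertion_sets) < 2
    called: list[Subdomain] = []
    for name in sorted(per_loop):
        group = per_loop[name]
        if single:
            for sub in group:
                sub.confirmed = False
                sub.conserved_in = {sub.paralog}
                called.append(sub)
            continue
        by_class: dict[str, list[Subdomain]] = {}
        for sub in group:
            by_class.setdefault(sub.ss_class, []).append(sub)
        for ss_class, members in sorted(by_class.items()):
            if len(members) >= min_conserved:
                conserved = {m.paralog for m in members}
                for m in sorted(members, key=lambda m: m.paralog):
                    m.conserved_in = conserved
                    called.append(m)
    return called


def stitch_fragments(fragments: list[Structure],
                     min_overlap: int = MIN_OVERLAP,
                     stitch_tol: float = STITCH_TOL
                     ) -> tuple[Structure, list[float]]:
    """Assemble overlapping fragment models of one chain into a whole.

    Fragments are ordered by their first residue number; each next fragment
    is rigid-superposed onto the growing assembly over the shared-residue
    CAs, and its non-overlapping residues are appended (overlap coordinates
    are kept from the earlier fragment).  Returns the assembly and the
    per-junction overlap RMSDs.
    """
    if not fragments:
        raise StitchError("no fragments")
    frags = sorted(fragments, key=lambda f: min(r.seq_id
                                                for ch in f.chains.values() for r in ch))
    chain_ids = {cid for f in frags for cid in f.chains}
    if len(chain_ids) != 1:
        raise StitchError(f"fragments span multiple chains: {sorted(chain_ids)}")
    cid = chain_ids.pop()

    assembly = frags[0].copy()
    junction_rmsds: list[float] = []
    for k, frag in enumerate(frags[1:], start=1):
        have = {r.seq_id for r in assembly.chains[cid]}
        frag_ca = _ca_by_seqid(frag, cid)
        asm_ca = _ca_by_seqid(assembly, cid)
        shared = sorted(have & set(frag_ca) & set(asm_ca))
        if len(shared) < min_overlap:
            raise StitchError(
                f"junction {k}: overlap of {len(shared)} residues "
                f"(< {min_overlap}) between fragments {k - 1} and {k}")
        xa = np.array([frag_ca[i] for i in shared])
        xb = np.array([asm_ca[i] for i in shared])
        rot, t, rmsd = superpose_kabsch(xa, xb)
        junction_rmsds.append(rmsd)
        if rmsd > stitch_tol:
            logger.warning("junction %d: overlap RMSD %.2f A exceeds %.2f A",
                           k, rmsd, stitch_tol)
        moved = frag.transform(rot, t)
        for res in moved.chains[cid]:
            if res.seq_id not in have:
                assembly.add_residue(cid, res)
    assembly.chains[cid].sort(key=lambda r: r.key())
    return assembly, junction_rmsds


def overlay_rmsd(domains: list[tuple[C2Annotation, Structure]]
                 ) -> tuple[np.ndarray, float]:
    """Pairwise strand-anchored CA RMSD matrix and its mean over pairs."""
    n = len(domains)
    if n < 2:
        raise AlignmentError("need at least two domains to overlay")
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd = align_structures(domains[i], domains[j]).rmsd
            matrix[i, j] = matrix[j, i] = rmsd
    mean = float(matrix[np.triu_indices(n, 1)].mean())
    return matrix, mean
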