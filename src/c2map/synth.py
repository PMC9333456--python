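"""Synthetic coordinate models with known ground truth.

The generator emulates the architecture this package is built to detect: an
eight-stranded antiparallel beta-sandwich (two four-stranded sheets packed
face to face ~10 A apart) with configurable strand connectivity (the
Type-I / Type-II circular permutation), smooth-arc loops, and optional loop
insertions built as ideal alpha-helices or coil.  Backbone geometry on the
strands is constructed so that registered residue pairs form textbook
reciprocal N-H...O=C hydrogen bonds under the Kabsch-Sander energy, which
is what makes every downstream stage testable without external data.

Only backbone-level realism is attempted: no side chains, no Ramachandran
statistics.  Strand and helix sequences are drawn from a proline-free
distribution (proline lacks the amide H these elements depend on); loops
use the full 20-letter alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import templates
from .errors import SpecError
from .structure import Atom, Residue, Structure

# strand geometry (A)
RISE = 3.3              # translation per residue along the strand axis
STRAND_SEP = 4.8        # axis-to-axis spacing of sheet neighbours
SHEET_SEP = 10.0        # inter-sheet spacing of the sandwich
SHEET_STAGGER = 2.4     # x offset between the two sheets
PLEAT = 0.94            # CA pleat amplitude; gives CA-CA ~ 3.8
AXIAL_OFF = 1.25        # N/C offset from the CA point along the axis
SIDE_OFF = 0.35         # N/C offset toward the H-bonding side
O_LEN = 1.23            # C=O bond length
LOOP_SPACING = 3.8      # CA spacing along loop arcs
HELIX_RISE = 1.5        # rise per residue of an ideal alpha-helix

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: Roughly natural amino-acid frequencies used for sequence assignment.
AA_FREQS = np.array([
    0.083, 0.014, 0.055, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
    0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.030,
])

LOOP_NAMES = tuple(f"b{i}-{i + 1}" for i in range(1, 8))
DEFAULT_LOOP_LEN = 8


@dataclass
class SandwichSpec:
    """Parameters of one synthetic beta-sandwich; ``seed`` fixes everything."""

    n_strands: int = 8
    strand_len: int = 8
    connectivity: int = 1                      # permutation offset: 0 Type-I, 1 Type-II
    loop_lengths: dict[str, int] = field(default_factory=dict)
    insertions: dict[str, tuple[int, str]] = field(default_factory=dict)
    noise_sigma: float = 0.1
    seed: int = 0
    chain_id: str = "A"
    first_seq_id: int = 1

    def loop_len(self, name: str) -> int:
        return self.loop_lengths.get(name, DEFAULT_LOOP_LEN)

    def validate(self) -> None:
        if self.strand_len < 4:
            raise SpecError("strand_len must be >= 4")
        if self.n_strands not in (7, 8):
            raise SpecError("n_strands must be 7 or 8")
        for name, ln in self.loop_lengths.items():
            if ln < 1:
                raise SpecError(f"loop {name}: length must be >= 1")
        for name, (length, ss_class) in self.insertions.items():
            if length < 1 or ss_class not in ("helix", "coil"):
                raise SpecError(f"insertion {name}: bad spec ({length}, {ss_class})")


@dataclass
class GroundTruth:
    strands: list[tuple[int, int]]             # per ordinal, closed seq_id range
    pairings: set[tuple[int, int, str]]        # ordinal pairs + orientation
    topology: str
    boundary: tuple[int, int]
    loops: dict[str, Optional[tuple[int, int]]]
    insertions: list[tuple[str, int, tuple[int, int], str]]
    sequence: str
    ss: str                                    # per-residue ground truth H/E/-


# ---------------------------------------------------------------- strands

def build_strand(n: int, origin: np.ndarray, direction: np.ndarray,
                 side: np.ndarray, normal: np.ndarray, phase: int = 0
                 ) -> list[dict[str, np.ndarray]]:
    """Ideal extended-beta backbone along ``direction``.

    ``side`` is the unit vector toward the first residue's H-bonding
    neighbour when ``phase`` is even; the bonding side alternates per
    residue.  ``normal`` (perpendicular to both) carries the CA pleat.
    Consecutive CAs are ~3.8 A apart with a 3.3 A axial rise.
    """
    if n < 2:
        raise SpecError("a strand needs at least 2 residues")
    direction = direction / np.linalg.norm(direction)
    side = side / np.linalg.norm(side)
    normal = normal / np.linalg.norm(normal)
    out = []
    for t in range(n):
        axis = origin + direction * (RISE * t)
        d = side * (-1.0) ** (t + phase)
        out.append({
            "N": axis - direction * AXIAL_OFF + d * SIDE_OFF,
            "CA": axis + normal * (PLEAT * (-1.0) ** t),
            "C": axis + direction * AXIAL_OFF + d * SIDE_OFF,
            "O": axis + direction * AXIAL_OFF + d * (SIDE_OFF + O_LEN),
        })
    return out


# ------------------------------------------------------------------ loops

def _arc_points(a: np.ndarray, b: np.ndarray, n: int, bulge: np.ndarray,
                spacing: float = LOOP_SPACING) -> list[np.ndarray]:
    """``n`` interior points of a circular arc from a to b of arc length
    ``(n + 1) * spacing``, bulging toward ``bulge``."""
    chord = float(np.linalg.norm(b - a))
    arclen = (n + 1) * spacing
    if arclen <= chord * 1.001:
        raise SpecError(
            f"loop of {n} residues cannot span {chord:.1f} A "
            f"(available arc {arclen:.1f} A)")
    # solve sin(t)/t = chord/arclen for the half-angle t
    lo, hi = 1e-6, math.pi - 1e-6
    ratio = chord / arclen
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if math.sin(mid) / mid > ratio:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    radius = arclen / (2.0 * theta)

    v = b - a
    vhat = v / max(chord, 1e-9)
    w = bulge - np.dot(bulge, vhat) * vhat
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(vhat, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(vhat, np.array([0.0, 1.0, 0.0]))
    w = w / np.linalg.norm(w)

    mid = 0.5 * (a + b)
    center = mid - w * (radius * math.cos(theta))
    e1 = (a - center) / radius
    e2_raw = (b - center) / radius
    e2 = e2_raw - np.dot(e2_raw, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    total = 2.0 * theta
    pts = []
    for k in range(1, n + 1):
        ang = total * k / (n + 1)
        pts.append(center + radius * (math.cos(ang) * e1 + math.sin(ang) * e2))
    return pts


def _coil_residues(ca_points: list[np.ndarray], prev_ca: np.ndarray,
                   next_ca: np.ndarray, away_from: np.ndarray
                   ) -> list[dict[str, np.ndarray]]:
    """Backbone atoms for coil CAs: N/C along the local tangent, O pointing
    away from ``away_from`` (the domain interior) to avoid stray H-bonds."""
    out = []
    extended = [prev_ca] + list(ca_points) + [next_ca]
    for i, ca in enumerate(ca_points, start=1):
        tangent = extended[i + 1] - extended[i - 1]
        tangent = tangent / max(np.linalg.norm(tangent), 1e-9)
        radial = ca - away_from
        radial = radial - np.dot(radial, tangent) * tangent
        nr = np.linalg.norm(radial)
        if nr < 1e-6:
            radial = np.cross(tangent, np.array([1.0, 0.0, 0.0]))
            nr = np.linalg.norm(radial)
        radial = radial / nr
        out.append({
            "N": ca - tangent * AXIAL_OFF,
            "CA": ca,
            "C": ca + tangent * AXIAL_OFF,
            "O": ca + tangent * AXIAL_OFF + radial * O_LEN,
        })
    return out


# ----------------------------------------------------------------- helices

_PHI_HELIX, _PSI_HELIX = -57.0, -47.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / max(np.linalg.norm(n), 1e-12)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _torsion_backbone(n_res: int, phi: float, psi: float
                      ) -> list[dict[str, np.ndarray]]:
    """Backbone chain from repeated (phi, psi), trans peptide, ideal geometry."""
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = _place_atom(np.array([0.0, 0.0, -1.0]), n0, ca0, 1.525, 111.2, 60.0)
    atoms = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = atoms[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, 1.458, 121.7, 180.0)
        c_next = _place_atom(prev["C"], n_next, ca_next, 1.525, 111.2, phi)
        atoms.append({"N": n_next, "CA": ca_next, "C": c_next})
    n_extra = _place_atom(atoms[-1]["N"], atoms[-1]["CA"], atoms[-1]["C"],
                          1.329, 116.2, psi)
    for res, nxt in zip(atoms, [a["N"] for a in atoms[1:]] + [n_extra]):
        u = res["C"] - res["CA"]
        v = res["C"] - nxt
        bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        res["O"] = res["C"] + O_LEN * bis / np.linalg.norm(bis)
    return atoms


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        axis = np.cross(a, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, np.array([0.0, 1.0, 0.0]))
        axis = axis / np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _helix_segment(n_res: int, start: np.ndarray, axis: np.ndarray
                   ) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix of ``n_res`` residues, first CA at ``start``,
    axis pointing along ``axis``."""
    atoms = _torsion_backbone(n_res, _PHI_HELIX, _PSI_HELIX)
    cas = np.array([a["CA"] for a in atoms])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    own_axis = vt[0]
    if np.dot(cas[-1] - cas[0], own_axis) < 0:
        own_axis = -own_axis
    rot = _rotation_between(own_axis, axis)
    shift = start - rot @ atoms[0]["CA"]
    return [{k: rot @ v + shift for k, v in res.items()} for res in atoms]


def build_helix_chain(n: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """An all-helical chain (ideal alpha-helix) with a seeded sequence."""
    rng = np.random.default_rng(seed)
    atoms = _torsion_backbone(n, _PHI_HELIX, _PSI_HELIX)
    seq = _draw_sequence(rng, n, allow_pro=False)
    s = Structure(id=f"helix{n}")
    for i, res_atoms in enumerate(atoms):
        res = Residue(seq_id=i + 1, aa=seq[i])
        for name, pos in res_atoms.items():
            res.atoms[name] = Atom(name, name[0], pos)
        s.add_residue(chain_id, res)
    return s


def atoms_to_structure(residue_atoms: list[dict[str, np.ndarray]],
                       sequence: Optional[str] = None, chain_id: str = "A",
                       first_seq_id: int = 1, structure: Optional[Structure] = None
                       ) -> Structure:
    """Wrap raw per-residue atom dictionaries into a Structure (fixture aid)."""
    s = structure if structure is not None else Structure(id="fixture")
    start = first_seq_id
    if structure is not None and chain_id in s.chains and s.chains[chain_id]:
        start = max(start, s.chains[chain_id][-1].seq_id + 1)
    for k, res_atoms in enumerate(residue_atoms):
        aa = sequence[k] if sequence else "A"
        res = Residue(seq_id=start + k, aa=aa)
        for name, pos in res_atoms.items():
            res.atoms[name] = Atom(name, name[0], np.array(pos, dtype=float))
        s.add_residue(chain_id, res)
    return s


# ------------------------------------------------------------- sequences

def _draw_sequence(rng: np.random.Generator, n: int, allow_pro: bool = True) -> str:
    freqs = AA_FREQS.copy()
    if not allow_pro:
        freqs[AA_ORDER.index("P")] = 0.0
    freqs = freqs / freqs.sum()
    return "".join(rng.choice(list(AA_ORDER), size=n, p=freqs))


#: Correlation length (residues) of the coordinate-noise field.
NOISE_CORR_LEN = 3.0


def _correlated_noise(rng: np.random.Generator, n: int, sigma: float
                      ) -> np.ndarray:
    """(n, 3) Gaussian displacement field with per-residue marginal standard
    deviation ``sigma`` and correlation length :data:`NOISE_CORR_LEN` along
    the chain.  Residues far apart in sequence move independently; sequence
    neighbours move almost rigidly together, preserving local geometry."""
    from scipy.ndimage import gaussian_filter1d
    white = rng.normal(0.0, 1.0, size=(n, 3))
    smooth = gaussian_filter1d(white, NOISE_CORR_LEN, axis=0, mode="nearest")
    impulse = np.zeros(max(n, int(8 * NOISE_CORR_LEN) + 1))
    impulse[len(impulse) // 2] = 1.0
    kernel = gaussian_filter1d(impulse, NOISE_CORR_LEN, mode="constant")
    return smooth * (sigma / np.sqrt((kernel ** 2).sum()))


# ------------------------------------------------------------- sandwiches

def _ordinal_layout(topology: str, n_strands: int
                    ) -> dict[int, tuple[int, int]]:
    """ordinal -> (sheet, slot) from the packing template."""
    sheets = templates.TEMPLATE_SHEETS[topology]
    layout = {}
    for sheet_idx, order in enumerate(sheets):
        for slot, ordinal in enumerate(order):
            if ordinal <= n_strands:
                layout[ordinal] = (sheet_idx, slot)
    return layout


def build_sandwich(spec: SandwichSpec) -> tuple[Structure, GroundTruth]:
    """Construct the sandwich and its ground truth.

    The chain runs strand 1, loop b1-2, strand 2, ... strand ``n_strands``.
    Strand direction alternates with the ordinal (odd ordinals run -z), which
    makes every sheet neighbour pairing antiparallel, exactly as in the
    template.  Loops are circular arcs bulging away from the domain center;
    insertions extend their host loop by the requested number of residues.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    topology = templates.template_for_offset(spec.connectivity)
    layout = _ordinal_layout(topology, spec.n_strands)
    length = spec.strand_len

    xhat = np.array([1.0, 0.0, 0.0])
    yhat = np.array([0.0, 1.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])

    strand_atoms: dict[int, list[dict[str, np.ndarray]]] = {}
    for ordinal, (sheet, slot) in layout.items():
        x = STRAND_SEP * slot + (SHEET_STAGGER if sheet == 1 else 0.0)
        y = SHEET_SEP * sheet
        up = ordinal % 2 == 0
        if up:
            origin = np.array([x, y, 0.0])
            direction = zhat
            phase = slot % 2
        else:
            origin = np.array([x, y, RISE * (length - 1)])
            direction = -zhat
            phase = (slot + length - 1) % 2
        strand_atoms[ordinal] = build_strand(
            length, origin, direction, xhat, yhat, phase)

    centroid = np.mean(
        [res["CA"] for atoms in strand_atoms.values() for res in atoms], axis=0)

    # assemble chain: strands and loops in ordinal order
    chain_plan: list[tuple[str, list[dict[str, np.ndarray]], str]] = []
    gt_strands: list[tuple[int, int]] = []
    gt_loops: dict[str, Optional[tuple[int, int]]] = {}
    gt_insertions: list[tuple[str, int, tuple[int, int], str]] = []

    def loop_atoms(name: str, a_ca: np.ndarray, b_ca: np.ndarray
                   ) -> tuple[list[dict[str, np.ndarray]], str]:
        n_base = spec.loop_len(name)
        insertion = spec.insertions.get(name)
        mid = 0.5 * (a_ca + b_ca)
        out_dir = mid - centroid
        if np.linalg.norm(out_dir) < 1e-6:
            out_dir = yhat
        out_dir = out_dir / np.linalg.norm(out_dir)
        if insertion is None or insertion[1] == "coil":
            extra = 0 if insertion is None else insertion[0]
            n = n_base + extra
            pts = _arc_points(a_ca, b_ca, n, out_dir)
            return _coil_residues(pts, a_ca, b_ca, centroid), "-" * n
        # helical insertion: lead-in coil, helix pointing back toward the
        # re-entry point from outside, short return coil
        m, _ = insertion
        n_return = 3
        for m_h in range(max(5, round(0.66 * m)), 4, -1):
            n_lead = n_base + m - m_h - n_return
            if n_lead < 2:
                continue
            lateral = a_ca - b_ca
            lateral = lateral - np.dot(lateral, out_dir) * out_dir
            ln = np.linalg.norm(lateral)
            lateral = lateral / ln if ln > 1e-6 else np.cross(out_dir, zhat)
            helix_end = b_ca + out_dir * 4.0 + lateral * 3.0
            helix_start = helix_end + out_dir * (HELIX_RISE * (m_h - 1))
            if (n_lead + 1) * LOOP_SPACING > np.linalg.norm(helix_start - a_ca) * 1.05:
                helix = _helix_segment(m_h, helix_start, -out_dir)
                lead_pts = _arc_points(a_ca, helix[0]["CA"], n_lead,
                                       out_dir + lateral)
                lead = _coil_residues(lead_pts, a_ca, helix[0]["CA"], centroid)
                ret_pts = _arc_points(helix[-1]["CA"], b_ca, n_return, lateral)
                ret = _coil_residues(ret_pts, helix[-1]["CA"], b_ca, centroid)
                ss = "-" * n_lead + "H" * m_h + "-" * n_return
                return lead + helix + ret, ss
        raise SpecError(f"helical insertion of {m} residues infeasible at {name}")

    for ordinal in range(1, spec.n_strands + 1):
        atoms = strand_atoms[ordinal]
        chain_plan.append(("strand", atoms, "E" * len(atoms)))
        if ordinal < spec.n_strands:
            name = f"b{ordinal}-{ordinal + 1}"
            res, ss = loop_atoms(name, atoms[-1]["CA"],
                                 strand_atoms[ordinal + 1][0]["CA"])
            chain_plan.append((name, res, ss))

    # materialise residues, sequence and numbering
    structure = Structure(id=f"sandwich_{topology}_{spec.seed}")
    seq_parts: list[str] = []
    ss_parts: list[str] = []
    seq_id = spec.first_seq_id
    ordinal = 0
    for kind, atoms, ss in chain_plan:
        n = len(atoms)
        if kind == "strand":
            ordinal += 1
            seq = _draw_sequence(rng, n, allow_pro=False)
            gt_strands.append((seq_id, seq_id + n - 1))
        else:
            # proline-free under the helix, free elsewhere
            seq = "".join(
                _draw_sequence(rng, 1, allow_pro=(state != "H"))
                for state in ss)
            gt_loops[kind] = (seq_id, seq_id + n - 1) if n else None
            if kind in spec.insertions:
                m = spec.insertions[kind][0]
                gt_insertions.append(
                    (kind, m, (seq_id + n - m, seq_id + n - 1),
                     "helix-rich" if spec.insertions[kind][1] == "helix" else "coil"))
        for k, res_atoms in enumerate(atoms):
            res = Residue(seq_id=seq_id, aa=seq[k])
            for name, pos in res_atoms.items():
                res.atoms[name] = Atom(name, name[0], np.array(pos))
            structure.add_residue(spec.chain_id, res)
            seq_id += 1
        seq_parts.append(seq)
        ss_parts.append(ss)

    if spec.noise_sigma > 0:
        # displacement field, smoothly correlated along the chain and rigid
        # within each residue: emulates the placement uncertainty of
        # predicted models, whose local covalent geometry is near-ideal
        chain = structure.chains[spec.chain_id]
        shifts = _correlated_noise(rng, len(chain), spec.noise_sigma)
        for res, shift in zip(chain, shifts):
            for atom in res.atoms.values():
                atom.position = atom.position + shift

    pairings = {
        (min(a, b), max(a, b), "antiparallel")
        for pair in templates.template_pairs(topology)
        for a, b in [tuple(pair)]
        if a <= spec.n_strands and b <= spec.n_strands
    }
    truth = GroundTruth(
        strands=gt_strands,
        pairings=pairings,
        topology=topology if spec.n_strands == 8 else templates.AMBIGUOUS,
        boundary=(gt_strands[0][0], gt_strands[-1][1]),
        loops=gt_loops,
        insertions=gt_insertions,
        sequence="".join(seq_parts),
        ss="".join(ss_parts),
    )
    return structure, truth


def build_tandem(spec_a: SandwichSpec, spec_b: SandwichSpec,
                 linker_len: int = 20, spacing: float = 40.0
                 ) -> tuple[Structure, GroundTruth, GroundTruth]:
    """Two sandwiches on one chain joined by a coil linker.

    The second domain is translated ``spacing`` A along x and renumbered to
    continue after the linker; both ground truths are returned with their
    final numbering."""
    s_a, t_a = build_sandwich(spec_a)
    cid = spec_a.chain_id
    last_a = s_a.chains[cid][-1]
    start_b = last_a.seq_id + linker_len + 1
    spec_b = SandwichSpec(**{**spec_b.__dict__,
                             "chain_id": cid, "first_seq_id": start_b})
    s_b, t_b = build_sandwich(spec_b)
    shift = np.array([spacing, 0.0, 0.0])
    out = s_a.copy()
    first_b = s_b.chains[cid][0]
    a_ca = last_a.ca
    b_ca = first_b.ca + shift
    mid_out = np.array([0.0, -1.0, 0.0])
    pts = _arc_points(a_ca, b_ca, linker_len, mid_out,
                      spacing=max(LOOP_SPACING,
                                  np.linalg.norm(b_ca - a_ca) / (linker_len + 1) * 1.2))
    rng = np.random.default_rng(spec_a.seed + 104729)
    linker_seq = _draw_sequence(rng, linker_len)
    for k, res_atoms in enumerate(_coil_residues(pts, a_ca, b_ca,
                                                 0.5 * (a_ca + b_ca) + np.array([0, 30.0, 0]))):
        res = Residue(seq_id=last_a.seq_id + 1 + k, aa=linker_seq[k])
        for name, pos in res_atoms.items():
            res.atoms[name] = Atom(name, name[0], pos)
        out.add_residue(cid, res)
    for res in s_b.chains[cid]:
        moved = res.copy()
        for atom in moved.atoms.values():
            atom.position = atom.position + shift
        out.add_residue(cid, moved)
    return out, t_a, t_b


def split_with_overlap(s: Structure, cut_points: list[int], overlap: int,
                       reposed: bool = False, seed: int = 0
                       ) -> list[Structure]:
    """Split a single-chain structure into overlapping fragments.

    Fragment k runs from the previous cut to ``cut + overlap - 1``, so
    consecutive fragments share exactly ``overlap`` residues.  With
    ``reposed=True`` every fragment after the first is moved by a seeded
    random rigid motion (the regime fragment-wise structure prediction
    produces)."""
    if overlap < 1:
        raise SpecError("overlap must be >= 1")
    (cid, chain), = s.chains.items()
    first, last = chain[0].seq_id, chain[-1].seq_id
    cuts = sorted(cut_points)
    if any(c <= first or c > last for c in cuts):
        raise SpecError("cut points must be interior")
    starts = [first] + cuts
    ends = [c + overlap - 1 for c in cuts] + [last]
    rng = np.random.default_rng(seed)
    frags = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        if b - a + 1 <= overlap:
            raise SpecError(f"fragment {k}: overlap {overlap} >= length {b - a + 1}")
        frag = s.extract_region(cid, a, min(b, last))
        frag.id = f"{s.id}_frag{k}"
        if reposed and k > 0:
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            t = rng.normal(0.0, 20.0, size=3)
            frag = frag.transform(rot, t)
        frags.append(frag)
    return frags


# ------------------------------------------------- canonical reference data

#: Seed of the packaged canonical reference domain (synthetic stand-in for
#: an experimentally anchored Type-II C2 reference).
REFERENCE_SEED = 73


def canonical_reference() -> tuple[Structure, GroundTruth, list[int]]:
    """The package's canonical Type-II reference domain plus pocket slots.

    This is a *synthetic* reference: a noise-free generator sandwich whose
    pocket slots are the two central residues of each of the three apex
    loops, with acidic residues written into its sequence there.  It plays
    the role an experimentally solved reference C2 domain would play when
    the user supplies one.
    """
    spec = SandwichSpec(noise_sigma=0.0, seed=REFERENCE_SEED)
    s, truth = build_sandwich(spec)
    pocket: list[int] = []
    acidic = "DEDDED"
    k = 0
    cid = spec.chain_id
    by_seq = {r.seq_id: r for r in s.chains[cid]}
    # apex loops of a Type-II domain: b1-2, b3-4, b5-6 (hairpins at the
    # pocket face); take their two central residues
    for name in ("b1-2", "b3-4", "b5-6"):
        a, b = truth.loops[name]
        mid = (a + b) // 2
        for pos in (mid, mid + 1):
            by_seq[pos].aa = acidic[k]
            pocket.append(pos)
            k += 1
    truth.sequence = "".join(r.aa for r in s.chains[cid])
    return s, truth, pocket
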