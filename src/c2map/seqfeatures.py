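"""Sequence-level analytics: composition, pI, extinction coefficient,
Ca2+-pocket census, identity/similarity, and transmembrane-span arithmetic.

Conventions mirror how the source tables are printed: residue ranges are
closed intervals; a TM span length is inclusive (last - first + 1) while
the extracellular tail count is exclusive (last - first).  The isoelectric
point uses the Bjellqvist pKa set as implemented by Biopython's ProtParam
module (charge-bisection to |charge| < 1e-4); the 280 nm molar extinction
coefficient uses the Gill & von Hippel increments 5500 (Trp), 1490 (Tyr)
and 125 per cystine pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import AlignmentError, C2MapError
from .compare import Correspondence

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Residue classes counted as 'similar' for identity/similarity reporting.
SIMILARITY_CLASSES = ("ILVM", "FWY", "KRH", "DE", "ST", "NQ", "AG", "C", "P")

EXT_TRP, EXT_TYR, EXT_CYSTINE = 5500, 1490, 125

#: Acidic slots needed for a binding-likely pocket call.
POCKET_THRESHOLD = 4


@dataclass
class SequenceSegment:
    """A named residue range with its (gap-stripped) sequence."""

    name: str
    sequence: str
    protein: str = ""
    interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.replace("-", "").upper()
        bad = set(self.sequence) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.name}: non-amino-acid letters {sorted(bad)}")
        if "X" in self.sequence:
            logger.warning("%s: nonstandard residues present; they are excluded "
                           "from pI/extinction/composition", self.name)

    @property
    def standard_sequence(self) -> str:
        return self.sequence.replace("X", "")


@dataclass
class CompositionReport:
    length: int
    fraction: dict[str, float]

    def percent(self, letter: str) -> float:
        """Display form, rounded to one decimal."""
        return round(100.0 * self.fraction.get(letter, 0.0), 1)


def composition(seg: SequenceSegment,
                letters: Optional[str] = None) -> CompositionReport:
    """Per-letter fraction of the segment (all 20 letters unless restricted)."""
    seq = seg.standard_sequence
    if not seq:
        raise C2MapError(f"{seg.name}: empty sequence")
    wanted = letters if letters is not None else "".join(sorted(STANDARD_AA))
    frac = {aa: seq.count(aa) / len(seq) for aa in wanted}
    return CompositionReport(length=len(seq), fraction=frac)


def isoelectric_point(seg: SequenceSegment, tol: float = 1e-4) -> float:
    """pH of zero net charge under the Bjellqvist/ProtParam pKa set.

    The Henderson-Hasselbalch net charge (Biopython's ProtParam tables,
    including the terminal-residue pKa adjustments) is bisected over the
    full pH 0-14 range to |charge| < ``tol``.  Bisecting the full range
    matters: strongly acidic segments have pI below 4, which the stock
    ProtParam-module bracket would clip.
    """
    seq = seg.standard_sequence
    if not seq:
        raise C2MapError(f"{seg.name}: no standard residues, pI undefined")
    ip = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        charge = ip.charge_at_pH(mid)
        if abs(charge) < tol:
            break
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return float(mid)


def net_charge(seg: SequenceSegment, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (same pKa set as pI)."""
    return float(IsoelectricPoint(seg.standard_sequence).charge_at_pH(ph))


def extinction_coefficient(seg: SequenceSegment,
                           cystine_mode: str = "all-cystine") -> int:
    """Molar extinction coefficient at 280 nm (M^-1 cm^-1).

    ``cystine_mode='all-cystine'`` pairs up every cysteine (floor(nCys / 2)
    cystines); ``'all-reduced'`` counts none.
    """
    seq = seg.standard_sequence
    n_w, n_y, n_c = seq.count("W"), seq.count("Y"), seq.count("C")
    if cystine_mode == "all-cystine":
        pairs = n_c // 2
    elif cystine_mode == "all-reduced":
        pairs = 0
    else:
        raise ValueError(f"unknown cystine_mode: {cystine_mode!r}")
    return EXT_TRP * n_w + EXT_TYR * n_y + EXT_CYSTINE * pairs


@dataclass
class PocketCensus:
    positions: list[int]          # reference coordinating seq_ids
    acidic_count: int
    call: str                     # binding-likely | binding-unlikely


def pocket_census(correspondence: Correspondence,
                  candidate_seq: dict[int, str],
                  reference_positions: list[int],
                  threshold: int = POCKET_THRESHOLD) -> PocketCensus:
    """Count acidic candidate residues aligned to the reference pocket slots.

    ``correspondence`` comes from :func:`c2map.compare.align_structures` with
    the reference as the *second* domain; ``candidate_seq`` maps candidate
    seq_id -> one-letter code.
    """
    if not correspondence.pairs:
        raise AlignmentError("empty correspondence; census undefined")
    ref_to_cand = {pb[1]: pa[1] for pa, pb in correspondence.pairs}
    count = 0
    for pos in reference_positions:
        cand_pos = ref_to_cand.get(pos)
        if cand_pos is not None and candidate_seq.get(cand_pos) in ("D", "E"):
            count += 1
    call = "binding-likely" if count >= threshold else "binding-unlikely"
    return PocketCensus(positions=list(reference_positions),
                        acidic_count=count, call=call)


def identity_similarity(rows: list[str]) -> tuple[float, float]:
    """Mean pairwise identity and similarity fractions of a gapped alignment.

    Per pair, the denominator is the number of columns where at least one of
    the two rows has a residue; identity counts identical residue pairs,
    similarity counts pairs within one :data:`SIMILARITY_CLASSES` class.
    """
    if len(rows) < 2:
        raise C2MapError("need at least two alignment rows")
    if len({len(r) for r in rows}) != 1:
        raise C2MapError("alignment rows differ in length")
    cls = {}
    for group in SIMILARITY_CLASSES:
        for aa in group:
            cls[aa] = group
    idents, simils = [], []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i].upper(), rows[j].upper()
            denom = ident = simil = 0
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                denom += 1
                if x == "-" or y == "-":
                    continue
                if x == y:
                    ident += 1
                    simil += 1
                elif cls.get(x) is not None and cls.get(x) == cls.get(y):
                    simil += 1
            if denom == 0:
                raise C2MapError("pair of all-gap rows")
            idents.append(ident / denom)
            simils.append(simil / denom)
    return (sum(idents) / len(idents), sum(simils) / len(simils))


@dataclass
class TmAnnotation:
    span: tuple[int, int]
    length: int                       # inclusive residue count
    conserved_pro: Optional[int]      # seq_id of the hinge proline
    extracellular: Optional[tuple[int, int]] = None
    extracellular_count: Optional[int] = None


def tm_analytics(protein: str, span: tuple[int, int],
                 sequence: Optional[str] = None,
                 extracellular: Optional[tuple[int, int]] = None,
                 pro_window: int = 10) -> TmAnnotation:
    """TM-span arithmetic under the table conventions.

    Length is inclusive (last - first + 1); the extracellular count is
    exclusive (last - first).  The conserved hinge proline is the first Pro
    at or after the span end (searching ``pro_window`` residues forward);
    when the span prediction has shifted past the hinge -- the otoferlin
    case -- the nearest Pro inside the span is accepted instead.
    ``sequence`` is the full-length protein sequence indexed from 1.
    """
    first, last = span
    if first > last:
        raise C2MapError(f"{protein}: inverted span {span}")
    length = last - first + 1
    pro = None
    if sequence is not None:
        def aa(pos: int) -> str:
            return sequence[pos - 1] if 1 <= pos <= len(sequence) else ""
        for pos in range(last, last + pro_window + 1):
            if aa(pos) == "P":
                pro = pos
                break
        if pro is None:
            for pos in range(last - 1, first - 1, -1):
                if aa(pos) == "P":
                    pro = pos
                    break
        if pro is None:
            logger.info("%s: no conserved Pro near span end %d", protein, last)
    count = None
    if extracellular is not None:
        count = extracellular[1] - extracellular[0]
    return TmAnnotation(span=span, length=length, conserved_pro=pro,
                        extracellular=extracellular, extracellular_count=count)


def hydropathy_scan(sequence: str, window: int = 19,
                    threshold: float = 1.6) -> list[tuple[int, int]]:
    """Kyte-Doolittle sliding-window screen for candidate TM stretches.

    Returns maximal runs (1-based inclusive, over window centers) whose
    window-mean hydropathy exceeds the threshold.  A crude stand-in for a
    dedicated TM predictor, used only as a screening fallback.
    """
    if window % 2 == 0 or window < 7:
        raise C2MapError("window must be odd and >= 7")
    if len(sequence) < window:
        raise C2MapError("sequence shorter than window")
    seq = sequence.upper()
    half = window // 2
    centers = []
    for i in range(half, len(seq) - half):
        vals = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq[i - half:i + half + 1]]
        if sum(vals) / window > threshold:
            centers.append(i + 1)  # 1-based
    runs: list[tuple[int, int]] = []
    for c in centers:
        if runs and c == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], c)
        else:
            runs.append((c, c))
    return runs
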