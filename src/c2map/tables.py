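"""Packaged reference tables: FerI spans/sequences/pI and TM spans.

The TSV files ship cell-for-cell as printed in their source.  The printed
tables contain a small number of internal inconsistencies, which the
loaders surface and reconcile explicitly rather than silently:

* FerI table: the otoferlin and myoferlin rows have their scalar columns
  (Length and pI) transposed with each other -- each row's printed Length
  matches the *other* row's actual sequence length.  Sequences are treated
  as authoritative; ``pi_expected`` carries the value consistent with the
  row's own sequence (i.e. the printed pair swapped back), and the
  discrepancy is flagged on the record.
* TM table: two span end positions disagree by a digit with the row's own
  printed length / extracellular count, which every other row satisfies
  exactly (TM length inclusive, extracellular count exclusive).  The end
  positions are reconstructed from the row's printed scalars and flagged.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

_DASH = re.compile(r"[–—-]")


def _parse_span(text: str) -> tuple[int, int]:
    a, b = _DASH.split(text.strip())
    return int(a), int(b)


def _rows(filename: str) -> list[dict[str, str]]:
    path = resources.files("c2map.data").joinpath(filename)
    with path.open(encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


@dataclass
class FerIRecord:
    ferlin: str
    span: tuple[int, int]
    sequence: str               # gapped, exactly as printed
    length_printed: int
    pi_printed: float
    pi_expected: float          # value consistent with the row's sequence
    reconciled: bool

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class TmRecord:
    ferlin: str
    length_printed: int
    span: tuple[int, int]             # reconciled when flagged
    span_printed: tuple[int, int]
    conserved_pro: int
    extracellular: tuple[int, int]    # reconciled when flagged
    extracellular_printed: tuple[int, int]
    extracellular_count_printed: int
    reconciled: bool


def feri_records() -> list[FerIRecord]:
    raw = _rows("feri_table.tsv")
    # detect pairs of rows whose printed Length matches the other row's
    # actual (ungapped) sequence length: transposed scalar columns
    actual = [len(r["Sequence"].replace("-", "")) for r in raw]
    printed = [int(r["Length"]) for r in raw]
    swapped_with: dict[int, int] = {}
    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            if (printed[i] != actual[i] and printed[j] != actual[j]
                    and printed[i] == actual[j] and printed[j] == actual[i]):
                swapped_with[i], swapped_with[j] = j, i
    records = []
    for i, row in enumerate(raw):
        j = swapped_with.get(i, i)
        records.append(FerIRecord(
            ferlin=row["Ferlin"],
            span=_parse_span(row["FerI Span"]),
            sequence=row["Sequence"],
            length_printed=printed[i],
            pi_printed=float(row["pI"]),
            pi_expected=float(raw[j]["pI"]),
            reconciled=(j != i),
        ))
    return records


def tm_records() -> list[TmRecord]:
    records = []
    for row in _rows("tm_table.tsv"):
        length = int(row["Length"])
        span = _parse_span(row["Transmembrane Span"])
        pro = int(_DASH.split(row["Conserved Proline"])[-1])
        m = re.match(r"(\S+)\s+\((\d+)\)", row["Extracellular"])
        extra = _parse_span(m.group(1))
        count = int(m.group(2))
        reconciled = False
        if span[1] - span[0] + 1 != length:
            span = (span[0], span[0] + length - 1)
            reconciled = True
        if extra[1] - extra[0] != count:
            extra = (extra[0], extra[0] + count)
            reconciled = True
        records.append(TmRecord(
            ferlin=row["Ferlin"],
            length_printed=length,
            span=span,
            span_printed=_parse_span(row["Transmembrane Span"]),
            conserved_pro=pro,
            extracellular=extra,
            extracellular_printed=_parse_span(m.group(1)),
            extracellular_count_printed=count,
            reconciled=reconciled,
        ))
    return records


def fixture_tables() -> dict[str, list]:
    """Both packaged tables keyed 'feri' and 'tm' (six records each)."""
    return {"feri": feri_records(), "tm": tm_records()}
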