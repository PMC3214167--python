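"""GSPPP-anchored three-window stop-codon survey over genome collections.

For each record the anchor pentapeptide is located by six-frame
translation; three contiguous 100-codon windows are then read in the
anchor's frame: window *i* upstream of the anchor glycine, window *ii*
from the glycine (the antisense-ORF body, residues 2-101 of the located
region), and window *iii* immediately downstream.  Stop positions are
summarised per decile: window *i* reports the position of the LAST stop
(5'-proximal truncation relevance), windows *ii*/*iii* the FIRST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from gauscan.codon_core import GeneticCode, translate
from gauscan.gau_locator import find_anchor, select_primary_anchor

WINDOW_CODONS = 100
WINDOWS = ("i", "ii", "iii")
DECILES = tuple(range(10, 101, 10))


def decile(position: int) -> int:
    """Bin a 1-based codon position 1..100 into its decile upper bound."""
    if not 1 <= position <= WINDOW_CODONS:
        raise ValueError(f"position {position} outside 1..{WINDOW_CODONS}")
    return math.ceil(position / 10) * 10


@dataclass(frozen=True)
class StopScanRow:
    """One record's anchored three-window stop catalogue."""

    record_id: str
    taxon: str
    phylum: str
    anchor_found: bool
    anchor_frame: str = ""
    stops: dict = field(default_factory=dict)       # window -> tuple of 1-based positions
    deciles: dict = field(default_factory=dict)     # window -> decile of last (i) / first (ii,iii) stop
    no_stop: dict = field(default_factory=dict)     # window -> bool


def scan_record(
    seq: str,
    code: GeneticCode,
    record_id: str = "rec",
    taxon: str = "",
    phylum: str = "",
    motif: str = "GSPPP",
) -> StopScanRow:
    """Locate the anchor and catalogue stops in the three 100-codon windows.

    When the anchor is absent the row carries ``anchor_found=False`` and
    empty windows.  Windows truncated by a sequence end are scanned over
    the available codons.
    """
    hits = find_anchor(seq, code, motif)
    primary = select_primary_anchor(hits)
    if primary is None:
        return StopScanRow(record_id=record_id, taxon=taxon, phylum=phylum, anchor_found=False)
    frame, j_a = primary
    protein = translate(seq, code, frame).protein
    bounds = {
        "i": (j_a - WINDOW_CODONS, j_a),
        "ii": (j_a, j_a + WINDOW_CODONS),
        "iii": (j_a + WINDOW_CODONS, j_a + 2 * WINDOW_CODONS),
    }
    stops: dict = {}
    decs: dict = {}
    nostop: dict = {}
    for w, (lo, hi) in bounds.items():
        lo_c = max(lo, 0)
        hi_c = min(hi, len(protein))
        window = protein[lo_c:hi_c]
        # positions stay anchored to the window's nominal start so deciles
        # are comparable even when the 5' end truncates window i
        shift = lo_c - lo
        pos = tuple(i + 1 + shift for i, aa in enumerate(window) if aa == "*")
        stops[w] = pos
        nostop[w] = not pos
        if pos:
            decs[w] = decile(pos[0] if w in ("ii", "iii") else pos[-1])
        else:
            decs[w] = None
    return StopScanRow(
        record_id=record_id,
        taxon=taxon,
        phylum=phylum,
        anchor_found=True,
        anchor_frame=frame,
        stops=stops,
        deciles=decs,
        no_stop=nostop,
    )


@dataclass(frozen=True)
class ScanSummary:
    """Per-phylum x window decile histograms plus grand totals."""

    table: pd.DataFrame          # rows: phylum x window; columns: deciles + no_stop
    totals_with_stops: dict      # window -> count
    totals_without_stops: dict   # window -> count
    n_anchor_found: int
    n_records: int


def aggregate_scan(rows) -> ScanSummary:
    """Tabulate scan rows into the decile-histogram summary layout."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to aggregate")
    found = [r for r in rows if r.anchor_found]
    recs = []
    for phylum in sorted({r.phylum for r in found}):
        sub = [r for r in found if r.phylum == phylum]
        for w in WINDOWS:
            counts = {d: 0 for d in DECILES}
            nostop = 0
            for r in sub:
                if r.no_stop[w]:
                    nostop += 1
                else:
                    counts[r.deciles[w]] += 1
            recs.append({"phylum": phylum, "window": w, **{f"d{d}": c for d, c in counts.items()}, "no_stop": nostop})
    table = pd.DataFrame(recs)
    totals_with = {w: sum(1 for r in found if not r.no_stop[w]) for w in WINDOWS}
    totals_without = {w: sum(1 for r in found if r.no_stop[w]) for w in WINDOWS}
    return ScanSummary(
        table=table,
        totals_with_stops=totals_with,
        totals_without_stops=totals_without,
        n_anchor_found=len(found),
        n_records=len(rows),
    )
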