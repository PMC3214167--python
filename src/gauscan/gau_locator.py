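"""Anchor-based location of the antisense ORF and simple protein profiles.

The *gau* region is located through the conserved pentapeptide GSPPP,
whose glycine sits at residue 2 of the deduced protein.  The region is
fixed at 101 codons: one codon upstream of the anchor glycine (the
candidate start, residue 1) through codon 101 (the candidate stop), i.e.
303 nt on the parent sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gauscan.codon_core import (
    FRAME_LABELS,
    GeneticCode,
    InvalidSequenceError,
    frame_codons,
    normalize_seq,
    translate,
    translate_codons,
)

REGION_CODONS = 101
#: residue index (1-based) of the anchor glycine within the region
ANCHOR_RESIDUE = 2

#: alternative mitochondrial initiation codons considered at residue 1
DEFAULT_START_SET = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG"})

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


class BoundaryError(ValueError):
    """Anchor too close to a sequence end to host the full region."""


@dataclass(frozen=True)
class GauRegion:
    """The located 101-codon antisense ORF on a parent sequence.

    ``start_nt``/``end_nt`` are 1-based inclusive on the parent (sense)
    sequence; the region itself is read on the antisense strand.
    ``anchor_codon_index`` is the 1-based residue index of the anchor
    glycine (2 by construction).  ``stop_positions`` are 1-based codon
    indices of '*' under the code used at extraction.
    """

    parent_id: str
    start_nt: int
    end_nt: int
    codons: tuple
    anchor_codon_index: int
    protein: str
    stop_positions: tuple
    agr_count: int
    strand: str = "-"

    def __post_init__(self) -> None:
        if len(self.codons) != REGION_CODONS:
            raise ValueError(f"region has {len(self.codons)} codons, expected {REGION_CODONS}")
        if self.end_nt - self.start_nt + 1 != 3 * REGION_CODONS:
            raise ValueError("region coordinates do not span 303 nt")

    @property
    def nt_seq(self) -> str:
        """The 303-nt region read 5'->3' on the antisense strand."""
        return "".join(self.codons)


def find_anchor(seq: str, code: GeneticCode, motif: str = "GSPPP") -> list:
    """Exact-match hits of a peptide motif across all six frames.

    Returns ``(frame_label, codon_index)`` pairs (codon index 0-based
    within the frame's translation), sorted by frame label order then
    position.  Empty list when the motif is absent.
    """
    if not motif or not motif.isalpha():
        raise ValueError("motif must be a non-empty peptide string")
    motif = motif.upper()
    hits = []
    for label in FRAME_LABELS:
        protein = translate(seq, code, label).protein
        start = protein.find(motif)
        while start != -1:
            hits.append((label, start))
            start = protein.find(motif, start + 1)
    return hits


def select_primary_anchor(hits: list, prefer_frame: str = "-2") -> "tuple | None":
    """Pick the anchor to report first: the preferred-frame hit, else the 5'-most."""
    if not hits:
        return None
    preferred = [h for h in hits if h[0] == prefer_frame]
    pool = preferred or hits
    return min(pool, key=lambda h: (h[1], h[0]))


def extract_gau_region(
    cox1: str,
    code: GeneticCode,
    anchor: "tuple | int",
    parent_id: str = "seq",
) -> GauRegion:
    """Cut the 101-codon region around a frame ``-2`` anchor hit.

    ``anchor`` is a ``(frame_label, codon_index)`` pair from
    :func:`find_anchor` (the frame must be ``-2``) or a bare codon index in
    the ``-2`` frame.  Needs one codon upstream of the anchor glycine and
    99 downstream.
    """
    s = normalize_seq(cox1)
    if isinstance(anchor, tuple):
        frame_label, j_a = anchor
        if frame_label != "-2":
            raise InvalidSequenceError(f"anchor must lie in frame -2, got {frame_label}")
    else:
        j_a = int(anchor)
    codons_m2 = frame_codons(s, "-2")
    if j_a < 1:
        raise BoundaryError("insufficient sequence 5' of the anchor (need 1 codon upstream)")
    if j_a + REGION_CODONS - 1 > len(codons_m2):
        missing = j_a + REGION_CODONS - 1 - len(codons_m2)
        raise BoundaryError(
            f"insufficient sequence 3' of the anchor ({missing} codons short of {REGION_CODONS - 2} downstream)"
        )
    region = codons_m2[j_a - 1 : j_a + REGION_CODONS - 1]
    protein = translate_codons(region, code)
    # -2 frame codon j occupies parent (0-based) positions [n-4-3j, n-2-3j]
    n = len(s)
    lo = n - 4 - 3 * (j_a + REGION_CODONS - 2)
    hi = n - 2 - 3 * (j_a - 1)
    stops = tuple(i + 1 for i, aa in enumerate(protein) if aa == "*")
    agr = sum(1 for c in region if c in ("AGA", "AGG"))
    return GauRegion(
        parent_id=parent_id,
        start_nt=lo + 1,
        end_nt=hi + 1,
        codons=tuple(region),
        anchor_codon_index=ANCHOR_RESIDUE,
        protein=protein,
        stop_positions=stops,
        agr_count=agr,
    )


def locate(cox1: str, code: GeneticCode, motif: str = "GSPPP", parent_id: str = "seq") -> GauRegion:
    """find_anchor + extract_gau_region convenience wrapper."""
    hits = [h for h in find_anchor(cox1, code, motif) if h[0] == "-2"]
    if not hits:
        raise ValueError(f"anchor motif {motif!r} not found in frame -2 of {parent_id}")
    return extract_gau_region(cox1, code, hits[0], parent_id=parent_id)


def candidate_starts(region: GauRegion, start_set: frozenset = DEFAULT_START_SET) -> list:
    """Initiation-codon candidates at residue 1 of the region."""
    first = region.codons[0]
    return [(1, first)] if first in start_set else []


@dataclass(frozen=True)
class HydropathyProfile:
    window: int
    values: tuple

    def max_position(self) -> int:
        """1-based window start of the maximal mean hydropathy."""
        return max(range(len(self.values)), key=self.values.__getitem__) + 1


def hydropathy_profile(protein: str, window: int = 9) -> HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    '*' (and unknown) positions are excluded from each window's mean; a
    window with no scorable residue gets 0.0.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if len(protein) < window:
        raise ValueError("protein shorter than window")
    scores = [KYTE_DOOLITTLE.get(aa) for aa in protein.upper()]
    values = []
    for i in range(len(protein) - window + 1):
        vals = [v for v in scores[i : i + window] if v is not None]
        values.append(sum(vals) / len(vals) if vals else 0.0)
    return HydropathyProfile(window=window, values=tuple(values))


def charge_hydrophobic_domains(
    protein: str,
    charge_window: int = 10,
    min_net_charge: int = 3,
    hydro_window: int = 15,
    min_mean_kd: float = 1.5,
) -> list:
    """Positively charged and hydrophobic domains, reported 5'->3'.

    A position belongs to a positive domain when covered by some window of
    ``charge_window`` residues with net charge >= ``min_net_charge``
    (K,R = +1; D,E = -1; H = 0), and to a hydrophobic domain when covered
    by some window of ``hydro_window`` residues with mean Kyte-Doolittle
    score >= ``min_mean_kd``.  Overlapping qualifying windows merge into
    maximal domains; returns ``(type, start, end)`` 1-based inclusive.
    """
    if not protein:
        raise ValueError("empty protein")
    p = protein.upper()

    def covered(window: int, ok) -> set:
        pos = set()
        for i in range(len(p) - window + 1):
            if ok(p[i : i + window]):
                pos.update(range(i, i + window))
        return pos

    def runs(positions: set, kind: str) -> list:
        out = []
        for i in sorted(positions):
            if out and i == out[-1][2]:
                out[-1][2] = i + 1
            else:
                out.append([kind, i, i + 1])
        return [(k, a + 1, b) for k, a, b in out]

    domains = []
    if len(p) >= charge_window:
        pos = covered(charge_window, lambda w: sum(RESIDUE_CHARGE.get(a, 0) for a in w) >= min_net_charge)
        domains += runs(pos, "positive")
    if len(p) >= hydro_window:
        def mean_kd(w):
            vals = [KYTE_DOOLITTLE[a] for a in w if a in KYTE_DOOLITTLE]
            return (sum(vals) / len(vals)) if vals else float("-inf")
        pos = covered(hydro_window, lambda w: mean_kd(w) >= min_mean_kd)
        domains += runs(pos, "hydrophobic")
    return sorted(domains, key=lambda d: (d[1], d[0]))
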