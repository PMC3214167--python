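"""Pairwise six-frame conservation tables and per-column family profiles.

Given two homologous coding sequences, a global nucleotide alignment is
partitioned into gene regions (on the first sequence's coordinates) and,
for each region and each of the six reading frames, amino-acid identity,
identical-or-similar fraction under a similarity scheme, per-sequence
stop-codon fractions and indel counts are tabulated.  A second entry
point profiles columns of a protein MSA for changes confined to one
functionally similar amino-acid family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import Align

from gauscan.codon_core import FRAME_LABELS, GeneticCode, normalize_seq, revcomp

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SimilarityScheme:
    """Named partition of amino acids into functionally similar families."""

    name: str
    groups: tuple  # tuple of frozensets

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            if not set(g) <= _STANDARD_AA:
                raise ValueError(f"scheme {self.name}: non-standard residues {set(g) - _STANDARD_AA}")
            if seen & set(g):
                raise ValueError(f"scheme {self.name}: groups not pairwise disjoint")
            seen |= set(g)

    def group_of(self, aa: str) -> "frozenset | None":
        for g in self.groups:
            if aa in g:
                return g
        return None

    def similar(self, a: str, b: str) -> bool:
        """Identical, or members of the same family."""
        if a == b and a in _STANDARD_AA:
            return True
        ga = self.group_of(a)
        return ga is not None and b in ga


def _scheme(name: str, *groups: str) -> SimilarityScheme:
    return SimilarityScheme(name, tuple(frozenset(g) for g in groups))


#: Dayhoff-style six-class partition (default; disjoint by construction)
DAYHOFF = _scheme("dayhoff", "AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")
#: the conservative families observed to dominate Gau column variation
GAU_FAMILIES = _scheme("gau-families", "FLIMV", "KN", "QH")

SCHEMES = {s.name: s for s in (DAYHOFF, GAU_FAMILIES)}


@dataclass(frozen=True)
class PairAlignment:
    """A global pairwise nucleotide alignment with '-' gaps."""

    id_a: str
    id_b: str
    aln_a: str
    aln_b: str
    params: dict

    def __post_init__(self) -> None:
        if len(self.aln_a) != len(self.aln_b):
            raise ValueError("aligned strings differ in length")

    @property
    def seq_a(self) -> str:
        return self.aln_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aln_b.replace("-", "")


def global_align_nt(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    id_a: str = "A",
    id_b: str = "B",
) -> PairAlignment:
    """Needleman-Wunsch global alignment with affine gaps.

    Ties are broken deterministically by taking the first optimal
    traceback the aligner reports.
    """
    sa, sb = normalize_seq(seq_a), normalize_seq(seq_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(sa, sb)[0]
    gapped_a, gapped_b = aln[0], aln[1]
    params = dict(match=match, mismatch=mismatch, gap_open=gap_open, gap_extend=gap_extend, score=aln.score)
    return PairAlignment(id_a=id_a, id_b=id_b, aln_a=str(gapped_a), aln_b=str(gapped_b), params=params)


def alignment_score(aln: PairAlignment) -> float:
    return aln.params["score"]


def partition_regions(aln: PairAlignment, breakpoints: Sequence) -> list:
    """Map 1-based inclusive seq-A coordinate ranges to alignment column slices.

    Ranges must be contiguous, start at 1, and end at the ungapped length
    of sequence A.  Gap columns are assigned to the region of the
    preceding seq-A position (leading gaps go to the first region).
    Returns ``(label, col_start, col_end)`` with 0-based half-open column
    ranges covering the whole alignment.
    """
    la = len(aln.seq_a)
    ranges = [tuple(r) for r in breakpoints]
    expect = 1
    for start, end in ranges:
        if start != expect or end < start:
            raise ValueError(f"regions must be contiguous from 1; got range ({start},{end}) expecting start {expect}")
        expect = end + 1
    if expect != la + 1:
        raise ValueError(f"regions cover 1..{expect - 1} but sequence A has {la} nt")
    # seqA coordinate (1-based) of each alignment column; gaps inherit previous
    coord = []
    c = 0
    for ch in aln.aln_a:
        if ch != "-":
            c += 1
        coord.append(max(c, 1))
    slices = []
    col = 0
    for start, end in ranges:
        first = col
        while col < len(coord) and coord[col] <= end:
            col += 1
        slices.append((f"{start}-{end}", first, col))
    return slices


def _gap_preserving_revcomp(gapped: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(gapped))


def _indel_events(a: str, b: str) -> int:
    """Number of maximal gap runs across both rows of an alignment slice."""
    events = 0
    for row in (a, b):
        in_gap = False
        for ch in row:
            if ch == "-" and not in_gap:
                events += 1
            in_gap = ch == "-"
    return events


def _stop_fraction(gapped: str, offset: int, code: GeneticCode) -> float:
    """Fraction of '*' among the codons of one sequence's ungapped region slice."""
    sub = gapped.replace("-", "")
    codons = [sub[i : i + 3] for i in range(offset, len(sub) - 2, 3)]
    if not codons:
        return float("nan")
    stops = sum(1 for c in codons if code.aa(c) == "*")
    return 100.0 * stops / len(codons)


def _frame_cells(
    work_a: str,
    work_b: str,
    col_range: tuple,
    offset: int,
    code_a: GeneticCode,
    code_b: GeneticCode,
    scheme: SimilarityScheme,
) -> dict:
    """aa comparison over one region/frame on (possibly revcomp'd) rows."""
    a0, a1 = col_range
    # seqA coordinate (0-based on the working strand) per column, -1 at gaps
    coords = []
    c = -1
    for ch in work_a:
        if ch != "-":
            c += 1
        coords.append(c if ch != "-" else -1)
    col_of = {coords[i]: i for i in range(len(coords)) if coords[i] >= 0}
    region_a_coords = sorted(c for i, c in enumerate(coords) if a0 <= i < a1 and c >= 0)
    n_ident = n_sim = n_codons = 0
    if region_a_coords:
        lo, hi = region_a_coords[0], region_a_coords[-1]
        first_codon = max(0, -(-(lo - offset) // 3))
        c0 = offset + 3 * first_codon
        for start in range(c0, hi - 1, 3):
            cols = [col_of.get(start + d) for d in range(3)]
            if any(col is None or not (a0 <= col < a1) for col in cols):
                continue
            tri_a = "".join(work_a[col] for col in cols)
            tri_b = "".join(work_b[col] for col in cols)
            if "-" in tri_b:
                continue
            aa_a, aa_b = code_a.aa(tri_a), code_b.aa(tri_b)
            n_codons += 1
            if aa_a == aa_b:
                n_ident += 1
            if aa_a == aa_b or scheme.similar(aa_a, aa_b):
                n_sim += 1
    pct = lambda k: (100.0 * k / n_codons) if n_codons else float("nan")
    return {
        "n_codon_columns": n_codons,
        "pct_identical_aa": pct(n_ident),
        "pct_identical_or_similar_aa": pct(n_sim),
        "pct_stop_seqA": _stop_fraction(work_a[a0:a1], offset, code_a),
        "pct_stop_seqB": _stop_fraction(work_b[a0:a1], offset, code_b),
    }


def frame_comparison_table(
    aln: PairAlignment,
    code_a: GeneticCode,
    code_b: GeneticCode,
    breakpoints: Sequence,
    scheme: SimilarityScheme = DAYHOFF,
) -> pd.DataFrame:
    """Region x frame conservation table over a pairwise alignment.

    For each region (seq-A coordinate range) and each frame: amino-acid
    identity and identical-or-similar percentages over codon columns free
    of gaps in either sequence, per-sequence stop percentages (each
    sequence under its own code, gaps excluded from the denominator),
    nucleotide identity over both-non-gap columns, and the indel event
    count.  Frames are anchored on seq-A coordinates; minus frames work
    on the gap-preserving reverse complement of both rows.
    """
    slices = partition_regions(aln, breakpoints)
    L = len(aln.aln_a)
    rc_a, rc_b = _gap_preserving_revcomp(aln.aln_a), _gap_preserving_revcomp(aln.aln_b)
    rows = []
    for label, a0, a1 in slices:
        cols = [(aln.aln_a[i], aln.aln_b[i]) for i in range(a0, a1)]
        both = [(x, y) for x, y in cols if x != "-" and y != "-"]
        pct_nt = 100.0 * sum(x == y for x, y in both) / len(both) if both else float("nan")
        indels = _indel_events(aln.aln_a[a0:a1], aln.aln_b[a0:a1])
        for frame in FRAME_LABELS:
            offset = int(frame[1]) - 1
            if frame[0] == "+":
                cell = _frame_cells(aln.aln_a, aln.aln_b, (a0, a1), offset, code_a, code_b, scheme)
            else:
                cell = _frame_cells(rc_a, rc_b, (L - a1, L - a0), offset, code_a, code_b, scheme)
            rows.append(
                {
                    "region": label,
                    "frame": frame,
                    "pct_identical_nt": pct_nt,
                    "gap_indel_count": indels,
                    **cell,
                }
            )
    return pd.DataFrame(rows)


def column_family_profile(msa: Sequence, scheme: SimilarityScheme = GAU_FAMILIES) -> pd.DataFrame:
    """Per-column residue counts of a protein MSA with a same-family flag.

    The flag is true when a column holds at least two distinct standard
    residues and all of them fall within a single family of ``scheme``.
    Gap characters are ignored in the flag; a ragged MSA is an error.
    Positions are 1-based.
    """
    seqs = [s.upper() for s in msa]
    if not seqs:
        raise ValueError("empty MSA")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("ragged MSA: sequences differ in length")
    rows = []
    for i in range(n):
        col = [s[i] for s in seqs]
        counts: dict = {}
        for aa in col:
            counts[aa] = counts.get(aa, 0) + 1
        residues = {aa for aa in col if aa in _STANDARD_AA}
        flag = False
        if len(residues) >= 2:
            groups = {scheme.group_of(aa) for aa in residues}
            flag = len(groups) == 1 and None not in groups
        rows.append({"position": i + 1, "counts": counts, "same_family": flag})
    return pd.DataFrame(rows)
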