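"""Genetic-code tables, frame-aware translation, and antisense codon geometry.

Frames are labelled ``+1, +2, +3`` (sense strand, offsets 0..2) and
``-1, -2, -3`` (reverse complement, offsets 0..2).  The ``-2`` frame is the
one in which the *gau* ORF lies: third codon positions of the sense gene
and of the antisense ORF triplets are complementary, while antisense
positions 1 and 2 come from positions 2 and 1 of the *next* sense codon.

Coordinates are 0-based half-open internally; reporting functions emit
1-based inclusive coordinates (GenBank convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data import CodonTable as _BioCodonTable

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")
# IUPAC nucleotide alphabet accepted on input; anything else is rejected.
_VALID_CHARS = frozenset("ACGTUNRYSWKMBDHV")

FRAME_LABELS = ("+1", "+2", "+3", "-1", "-2", "-3")

_CODE_ALIASES = {
    "standard": 1,
    "vertebrate-mt": 2,
    "yeast-mt": 3,
    "mold-mt": 4,
    "protozoan-mt": 4,
    "invertebrate-mt": 5,
}


class InvalidSequenceError(ValueError):
    """Raised for empty input, non-nucleotide characters, or bad frames."""


def normalize_seq(seq: str) -> str:
    """Uppercase, map RNA U to T, and validate the alphabet."""
    if not seq:
        raise InvalidSequenceError("empty sequence")
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise InvalidSequenceError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with start and stop codon sets.

    ``agr_as_stop`` is true for codes (vertebrate mitochondrial) in which
    AGA and AGG terminate translation rather than coding arginine.
    """

    code_id: str
    table: Mapping[str, str]
    starts: frozenset
    stops: frozenset

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"code {self.code_id}: {len(self.table)} codons mapped, need 64")
        derived_stops = frozenset(c for c, aa in self.table.items() if aa == "*")
        if derived_stops != self.stops:
            raise ValueError(f"code {self.code_id}: stop set inconsistent with table")

    @property
    def agr_as_stop(self) -> bool:
        return "AGA" in self.stops and "AGG" in self.stops

    def aa(self, codon: str) -> str:
        """Translate one codon; ambiguity codes give 'X' (never a stop)."""
        if len(codon) != 3:
            raise InvalidSequenceError(f"codon of length {len(codon)}")
        return self.table.get(codon, "X")

    def family(self, aa: str) -> tuple:
        """Synonymous codons of an amino acid (or of '*')."""
        return tuple(sorted(c for c, a in self.table.items() if a == aa))


def _from_ncbi(table_id: int, code_id: str) -> GeneticCode:
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    table = dict(bio.forward_table)
    for stop in bio.stop_codons:
        table[stop] = "*"
    return GeneticCode(
        code_id=code_id,
        table=table,
        starts=frozenset(bio.start_codons),
        stops=frozenset(bio.stop_codons),
    )


_BUILTIN: dict = {}
for _name, _tid in _CODE_ALIASES.items():
    _BUILTIN.setdefault(_tid, _from_ncbi(_tid, _name))


def get_code(which: "int | str" = 1) -> GeneticCode:
    """Look up a built-in genetic code by NCBI table number or short name.

    Built-ins: 1 standard, 2 vertebrate-mt, 3 yeast-mt, 4 mold/protozoan-mt,
    5 invertebrate-mt.
    """
    if isinstance(which, str):
        if which.isdigit():
            which = int(which)
        else:
            key = which.lower()
            if key not in _CODE_ALIASES:
                raise KeyError(f"unknown genetic code {which!r}; know {sorted(_CODE_ALIASES)}")
            which = _CODE_ALIASES[key]
    if which not in _BUILTIN:
        raise KeyError(f"no built-in NCBI table {which}; have {sorted(_BUILTIN)}")
    return _BUILTIN[which]


def load_code_tsv(path: "str | Path", code_id: "str | None" = None) -> GeneticCode:
    """Load a user-supplied code from TSV columns: codon, aa, is_start."""
    table: dict = {}
    starts = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("codon"):
            continue
        parts = line.split("\t")
        codon = normalize_seq(parts[0])
        table[codon] = parts[1].strip().upper()
        if len(parts) > 2 and parts[2].strip() in {"1", "true", "True", "yes"}:
            starts.add(codon)
    stops = frozenset(c for c, aa in table.items() if aa == "*")
    return GeneticCode(code_id or Path(path).stem, table, frozenset(starts), stops)


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame's conceptual translation.

    ``protein`` keeps '*' for stops and continues through them (no
    truncation); ``nt_offset`` is the 0-based offset of the first translated
    base on the labelled strand.
    """

    frame_label: str
    protein: str
    nt_offset: int

    def __len__(self) -> int:
        return len(self.protein)


def _parse_frame(frame: "str | int") -> tuple:
    """Return (strand, offset) with strand +1/-1 and offset 0..2."""
    if isinstance(frame, int):
        frame = f"{frame:+d}"
    frame = str(frame)
    if frame in ("1", "2", "3"):
        frame = "+" + frame
    if frame not in FRAME_LABELS:
        raise InvalidSequenceError(f"unknown frame label {frame!r}")
    return (1 if frame[0] == "+" else -1), int(frame[1]) - 1


def translate_codons(codons: Iterable[str], code: GeneticCode) -> str:
    return "".join(code.aa(c) if set(c) <= set(BASES) else "X" for c in codons)


def translate(seq: str, code: GeneticCode, frame: "str | int" = "+1") -> FrameTranslation:
    """Translate one frame; N/ambiguity codons give 'X', stops give '*'."""
    s = normalize_seq(seq)
    if len(s) < 3:
        raise InvalidSequenceError("sequence shorter than one codon")
    strand, offset = _parse_frame(frame)
    work = s if strand == 1 else revcomp(s)
    codons = [work[i : i + 3] for i in range(offset, len(work) - 2, 3)]
    label = f"{'+' if strand == 1 else '-'}{offset + 1}"
    return FrameTranslation(frame_label=label, protein=translate_codons(codons, code), nt_offset=offset)


def six_frame_translate(seq: str, code: GeneticCode) -> dict:
    """All six conceptual translations, keyed by frame label."""
    return {label: translate(seq, code, label) for label in FRAME_LABELS}


def frame_codons(seq: str, frame: "str | int") -> list:
    """The codon strings a frame translates, in translation order."""
    s = normalize_seq(seq)
    strand, offset = _parse_frame(frame)
    work = s if strand == 1 else revcomp(s)
    return [work[i : i + 3] for i in range(offset, len(work) - 2, 3)]


def minus2_codon(seq: str, k: int) -> str:
    """The antisense (-2 frame) codon whose third position pairs with sense codon ``k``.

    For a sense sequence read as codons 0..m-1, antisense codon positions
    1 and 2 are the complements of positions 2 and 1 of sense codon k+1,
    and antisense position 3 is the complement of position 3 of sense
    codon k.  Requires the adjacent sense codon, so ``k < m - 1``.
    """
    s = normalize_seq(seq)
    if len(s) % 3:
        raise InvalidSequenceError("sequence length must be a multiple of 3")
    m = len(s) // 3
    if not 0 <= k < m - 1:
        raise IndexError(f"sense codon index {k} out of range 0..{m - 2}")
    comp = lambda b: b.translate(_COMPLEMENT)
    return comp(s[3 * k + 4]) + comp(s[3 * k + 3]) + comp(s[3 * k + 2])


def minus2_frame_index(n_sense_codons: int, k: int) -> int:
    """Map sense codon index k to the codon's index in the -2 frame translation."""
    return n_sense_codons - 2 - k


def count_stops(ft: FrameTranslation, start_codon: int, n_codons: int) -> list:
    """1-based stop positions within a window of a frame translation.

    ``start_codon`` is 1-based within the translation; positions in the
    returned list are relative to the window start (1..n_codons).
    """
    if start_codon < 1 or n_codons < 1 or start_codon + n_codons - 1 > len(ft.protein):
        raise IndexError(
            f"window ({start_codon}, {n_codons}) outside translation of length {len(ft.protein)}"
        )
    window = ft.protein[start_codon - 1 : start_codon - 1 + n_codons]
    return [i + 1 for i, aa in enumerate(window) if aa == "*"]
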