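"""Generators for synthetic inputs with planted, exactly recoverable truth.

The central generator builds a cox1-like coding sequence whose ``-2``
frame carries a GSPPP-anchored 101-codon region with user-planted stop
codons and AGR (AGA/AGG) codons, while the sense frame stays stop-free.
It works constructively: sense codons are chosen left to right, and each
choice simultaneously satisfies (a) the antisense codon completed by the
new sense codon's first two bases and (b) a lookahead on the new codon's
third base, which becomes the third position of the next antisense
codon.  Every antisense codon inside the three scan windows is
constrained, so the planted truth is exact, not statistical.

All generators are deterministic functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gauscan.codon_core import BASES, GeneticCode, get_code
from gauscan.gau_locator import find_anchor
from gauscan.stop_scan import WINDOW_CODONS, decile

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ANCHOR_PEPTIDE = "GSPPP"
_AGR = ("AGA", "AGG")


class InfeasibleSpecError(ValueError):
    """The planted constraints cannot be realised."""


@dataclass(frozen=True)
class OverlapSpec:
    """Recipe for one anchored overlap CDS.

    ``n_codons`` counts sense codons; ``anchor_offset`` is the codon index
    of the anchor glycine in the ``-2`` frame translation.  ``stops`` maps
    scan windows ('i', 'ii', 'iii') to 1-based positions (1..100) of
    planted stop codons; all other window positions are guaranteed
    stop-free (and AGR-free).  ``agr_count`` AGA/AGG codons are planted at
    deterministic positions within the region body.  ``start_codon``, when
    set, is planted verbatim at region residue 1.
    """

    n_codons: int = 520
    anchor_offset: int = 110
    stops: dict = field(default_factory=dict)
    agr_count: int = 0
    code_id: "int | str" = 5
    seed: int = 0
    start_codon: "str | None" = "ATA"

    def validate(self) -> None:
        j_a = self.anchor_offset
        if j_a < 101 or j_a + 2 * WINDOW_CODONS > self.n_codons - 3:
            raise InfeasibleSpecError(
                f"anchor offset {j_a} leaves no room for the three scan windows in {self.n_codons} codons"
            )
        for w, positions in self.stops.items():
            if w not in ("i", "ii", "iii"):
                raise InfeasibleSpecError(f"unknown window {w!r}")
            for p in positions:
                if not 1 <= p <= WINDOW_CODONS:
                    raise InfeasibleSpecError(f"planted stop position {p} outside 1..{WINDOW_CODONS}")
        if self.agr_count < 0 or self.agr_count > 80:
            raise InfeasibleSpecError(f"AGR target {self.agr_count} outside the region's capacity")


@dataclass(frozen=True)
class GeneratedCds:
    """A generated CDS plus its planted ground truth."""

    cds: str
    spec: OverlapSpec
    anchor_offset: int                 # -2 frame codon index of the glycine
    region_stop_residues: tuple        # 1-based residues within the 101-codon region
    window_stops: dict                 # window -> tuple of 1-based positions
    agr_residues: tuple                # 1-based region residues carrying AGA/AGG


def _plan_constraints(spec: OverlapSpec, code: GeneticCode, rng: np.random.Generator) -> tuple:
    """Map -2 frame codon index j -> constraint class."""
    j_a = spec.anchor_offset
    plan: dict = {}
    # scan windows default to 'nonstop'
    for j in range(j_a - WINDOW_CODONS, j_a + 2 * WINDOW_CODONS):
        plan[j] = ("nonstop",)
    plan[j_a - 1] = ("codon", spec.start_codon) if spec.start_codon else ("nonstop",)
    for i, aa in enumerate(_ANCHOR_PEPTIDE):
        plan[j_a + i] = ("aa", aa)
    window_start = {"i": j_a - WINDOW_CODONS, "ii": j_a, "iii": j_a + WINDOW_CODONS}
    for w, positions in spec.stops.items():
        for p in positions:
            j = window_start[w] + p - 1
            if plan[j][0] == "aa":
                raise InfeasibleSpecError(f"planted stop at window {w} position {p} collides with the anchor")
            # a stop planted on the start-codon position (window i, 100) wins
            plan[j] = ("stop",)
    agr_residues = []
    if spec.agr_count:
        # region residues 8..100 keep clear of the anchor block and residue 101
        candidates = [r for r in range(8, 101) if plan[j_a - 2 + r] == ("nonstop",)]
        if len(candidates) < spec.agr_count:
            raise InfeasibleSpecError(f"cannot place {spec.agr_count} AGR codons in the region")
        agr_residues = sorted(rng.choice(len(candidates), size=spec.agr_count, replace=False).tolist())
        agr_residues = [candidates[i] for i in agr_residues]
        for r in agr_residues:
            plan[j_a - 2 + r] = ("agr",)
    return plan, tuple(agr_residues)


def _satisfies(gau_codon: str, cls: tuple, code: GeneticCode) -> bool:
    kind = cls[0]
    if kind == "free":
        return True
    if kind == "agr":
        return gau_codon in _AGR
    # all other constrained classes avoid AGA/AGG so the AGR count is exact
    if gau_codon in _AGR:
        return False
    if kind == "aa":
        return code.aa(gau_codon) == cls[1]
    if kind == "codon":
        return gau_codon == cls[1]
    if kind == "stop":
        return gau_codon in code.stops
    if kind == "nonstop":
        return gau_codon not in code.stops
    raise ValueError(kind)


def _third_base_ok(sense_third: str, cls: tuple, code: GeneticCode) -> bool:
    """Can some antisense codon with third base comp(sense_third) satisfy cls?"""
    g3 = _COMP[sense_third]
    kind = cls[0]
    if kind in ("free", "nonstop"):
        return True
    if kind == "aa":
        return any(
            code.aa(g1 + g2 + g3) == cls[1] and (g1 + g2 + g3) not in _AGR
            for g1 in BASES for g2 in BASES
        )
    if kind == "codon":
        return g3 == cls[1][2]
    if kind == "stop":
        return any(s[2] == g3 for s in code.stops if s not in _AGR)
    if kind == "agr":
        return g3 in ("A", "G")
    raise ValueError(kind)


_ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _build_sense(spec: OverlapSpec, code: GeneticCode, plan: dict, rng: np.random.Generator) -> str:
    m = spec.n_codons
    cls_for_k = {m - 2 - j: cls for j, cls in plan.items() if 0 <= m - 2 - j <= m - 2}
    free = ("free",)
    codons: list = []
    for k in range(m):
        terminal = k == m - 1
        cls_prev = cls_for_k.get(k - 1, free)   # antisense codon completed by this sense codon
        cls_here = cls_for_k.get(k, free)       # antisense codon whose third base this codon fixes
        candidates = []
        for c in _ALL_CODONS:
            if terminal:
                if c not in code.stops:
                    continue
            else:
                if c in code.stops:
                    continue
                if not _third_base_ok(c[2], cls_here, code):
                    continue
            if k > 0:
                gau = _COMP[c[1]] + _COMP[c[0]] + _COMP[codons[-1][2]]
                if not _satisfies(gau, cls_prev, code):
                    continue
            candidates.append(c)
        if not candidates:
            raise InfeasibleSpecError(f"no sense codon satisfies the constraints at position {k}")
        codons.append(candidates[rng.integers(len(candidates))])
    return "".join(codons)


def make_overlap_cds(spec: OverlapSpec) -> GeneratedCds:
    """Generate a CDS whose ``-2`` frame carries the planted anchored region.

    The sense frame is stop-free except for the terminal codon; the
    anchor pentapeptide occurs exactly once across all six frames (the
    generator retries derived seeds until that uniqueness holds, which is
    part of the deterministic construction).
    """
    spec.validate()
    code = get_code(spec.code_id)
    for attempt in range(50):
        rng = np.random.default_rng((spec.seed * 1000 + attempt) % (2**31))
        plan, agr_residues = _plan_constraints(spec, code, rng)
        cds = _build_sense(spec, code, plan, rng)
        hits = find_anchor(cds, code, _ANCHOR_PEPTIDE)
        if hits == [("-2", spec.anchor_offset)]:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise InfeasibleSpecError("could not realise a unique anchor in 50 attempts")
    j_a = spec.anchor_offset
    window_stops = {w: tuple(sorted(spec.stops.get(w, ()))) for w in ("i", "ii", "iii")}
    region_stops = tuple(sorted(p + 1 for p in window_stops["ii"]))
    if code.agr_as_stop:
        region_stops = tuple(sorted(set(region_stops) | set(agr_residues)))
    return GeneratedCds(
        cds=cds,
        spec=spec,
        anchor_offset=j_a,
        region_stop_residues=region_stops,
        window_stops=window_stops,
        agr_residues=agr_residues,
    )


def make_divergent_pair(spec: OverlapSpec, identity: float, seed: int = 0) -> tuple:
    """A homologous CDS pair at a requested gap-free nucleotide identity.

    Sequence B is sequence A with exactly ``round((1-identity)*L)``
    substitutions placed outside the 15-nt anchor span, so both sequences
    retain the anchor and the realised positional identity is exact.
    """
    if not 0.3 <= identity <= 1.0:
        raise ValueError("identity must be within [0.3, 1.0]")
    gen = make_overlap_cds(spec)
    a = gen.cds
    n = len(a)
    j_a = gen.anchor_offset
    # parent 0-based span of the five anchor codons in frame -2
    lo = n - 4 - 3 * (j_a + len(_ANCHOR_PEPTIDE) - 1)
    hi = n - 2 - 3 * j_a
    protected = set(range(lo, hi + 1))
    rng = np.random.default_rng(seed % (2**31))
    n_mut = round((1.0 - identity) * n)
    mutable = [i for i in range(n) if i not in protected]
    if n_mut > len(mutable):
        raise ValueError("identity target requires mutating protected anchor positions")
    positions = rng.choice(len(mutable), size=n_mut, replace=False)
    b = list(a)
    for idx in positions:
        i = mutable[idx]
        b[i] = rng.choice([x for x in BASES if x != a[i]])
    return gen, "".join(b)


def make_contrast_dataset(
    n_groups: int,
    effect: float,
    noise: float,
    seed: int = 0,
    baseline: float = 10.0,
    gain_fraction: float = 0.5,
    max_group_size: int = 3,
    times: "list | None" = None,
) -> pd.DataFrame:
    """Taxon table for the contrast analysis with a planted AGR effect.

    With-tRNA taxa draw AGR counts from round(Normal(baseline + effect,
    noise)) clipped at 0; without-tRNA taxa from round(Normal(baseline,
    noise)).  Divergence times default to uniform 5-60 My.  Scenarios are
    assigned gain/loss at ``gain_fraction``.
    """
    if n_groups < 2 or noise < 0:
        raise ValueError("need n_groups >= 2 and noise >= 0")
    rng = np.random.default_rng(seed % (2**31))
    rows = []
    for g in range(n_groups):
        gid = chr(ord("A") + g % 26) + ("" if g < 26 else str(g // 26))
        n_with = int(rng.integers(1, max_group_size + 1))
        n_without = int(rng.integers(1, max_group_size + 1))
        time = times[g] if times is not None else float(np.round(rng.uniform(5, 60), 1))
        scenario = "gain" if rng.random() < gain_fraction else "loss"
        for t in range(n_with):
            count = max(0, int(np.round(rng.normal(baseline + effect, noise))))
            rows.append((f"{gid}_with_{t}", gid, 1, count, time, scenario))
        for t in range(n_without):
            count = max(0, int(np.round(rng.normal(baseline, noise))))
            rows.append((f"{gid}_without_{t}", gid, 0, count, time, scenario))
    return pd.DataFrame(
        rows,
        columns=["taxon", "group_id", "trna_present", "agr_count", "divergence_time_my", "scenario"],
    )


def _anchor_free_sequence(length: int, code: GeneticCode, rng: np.random.Generator) -> str:
    for _ in range(100):
        seq = "".join(rng.choice(list(BASES), size=length))
        if not find_anchor(seq, code, _ANCHOR_PEPTIDE):
            return seq
    raise RuntimeError("could not draw an anchor-free sequence")  # pragma: no cover


def make_genome_set(
    n: int,
    seed: int = 0,
    phyla: tuple = ("Arthropoda", "Mollusca", "Chordata", "Nematoda"),
    anchor_free_fraction: float = 0.1,
    mean_stops_per_window: float = 1.0,
    code_id: "int | str" = 5,
    n_codons: int = 520,
) -> tuple:
    """A multi-record genome set plus its planted truth table.

    Each anchored record embeds an overlap CDS (with window stop counts
    drawn Poisson around ``mean_stops_per_window``) between random flanks;
    a configurable fraction of records carry no anchor at all.  The truth
    table lists, per record and window, the planted stop deciles exactly
    as the scanner should recover them.
    Returns ``(records, truth)`` where records is a list of
    ``(record_id, phylum, sequence)`` and truth a DataFrame.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    code = get_code(code_id)
    master = np.random.default_rng(seed % (2**31))
    records = []
    truth_rows = []
    for i in range(n):
        rec_id = f"g{i:04d}"
        phylum = phyla[i % len(phyla)]
        sub_seed = int(master.integers(2**31))
        rng = np.random.default_rng(sub_seed)
        if rng.random() < anchor_free_fraction:
            seq = _anchor_free_sequence(3 * n_codons, code, rng)
            records.append((rec_id, phylum, seq))
            truth_rows.append(
                {"record_id": rec_id, "phylum": phylum, "anchor": False,
                 **{f"{w}_decile": None for w in ("i", "ii", "iii")},
                 **{f"{w}_no_stop": None for w in ("i", "ii", "iii")}}
            )
            continue
        stops = {}
        for w in ("i", "ii", "iii"):
            k = int(rng.poisson(mean_stops_per_window))
            if k:
                # window ii positions 1-5 hold the anchor pentapeptide and stay stop-free
                low = 6 if w == "ii" else 1
                pool = WINDOW_CODONS - low + 1
                pos = rng.choice(pool, size=min(k, pool), replace=False) + low
                stops[w] = sorted(int(p) for p in pos)
        spec = OverlapSpec(n_codons=n_codons, stops=stops, code_id=code_id, seed=sub_seed)
        gen = make_overlap_cds(spec)
        for _ in range(50):
            left = _anchor_free_sequence(int(rng.integers(30, 90)), code, rng)
            right = _anchor_free_sequence(int(rng.integers(30, 90)), code, rng)
            seq = left + gen.cds + right
            if len(find_anchor(seq, code, _ANCHOR_PEPTIDE)) == 1:
                break
        records.append((rec_id, phylum, seq))
        row = {"record_id": rec_id, "phylum": phylum, "anchor": True}
        for w in ("i", "ii", "iii"):
            pos = gen.window_stops[w]
            row[f"{w}_no_stop"] = not pos
            if pos:
                row[f"{w}_decile"] = decile(pos[-1] if w == "i" else pos[0])
            else:
                row[f"{w}_decile"] = None
        truth_rows.append(row)
    return records, pd.DataFrame(truth_rows)


def write_fasta(records, path) -> None:
    """Write (id, ..., sequence) tuples as FASTA (sequence is the last field)."""
    with open(path, "w") as fh:
        for rec in records:
            rec_id, seq = rec[0], rec[-1]
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
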