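"""Sense-protein-preserving synonymous-shuffle null model.

Each codon of a coding sequence is independently redrawn from its
synonymous family according to the codon-usage frequencies of the gene
itself.  The sense-frame protein is bit-identical by construction, but
the overlapping antisense (-2 frame) reading is free to change; the
metrics quantify how much, and whether stop codons appear in the
antisense region.  Six-fold families (Leu, Ser) are treated as single
families, so reassignment may cross codon blocks.

The terminal stop codon of the CDS is excluded from reassignment.  Stop
counting inside the antisense region defaults to the vertebrate
mitochondrial code (AGA/AGG terminate); this is switchable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from gauscan.codon_core import GeneticCode, get_code, normalize_seq, translate_codons
from gauscan.gau_locator import GauRegion
from gauscan.overlap_tables import SimilarityScheme, DAYHOFF


@dataclass(frozen=True)
class CodonUsage:
    """Within-family relative synonymous codon frequencies of one gene."""

    frequencies: dict  # aa -> {codon: freq summing to 1 within the family}

    def family(self, aa: str) -> dict:
        if aa not in self.frequencies:
            raise KeyError(f"no usage family for amino acid {aa!r}")
        return self.frequencies[aa]


def _codons_of(cds: str) -> list:
    s = normalize_seq(cds)
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not a multiple of 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def codon_usage(cds: str, code: GeneticCode) -> CodonUsage:
    """Observed within-family synonymous frequencies; unobserved codons get 0."""
    codons = _codons_of(cds)
    counts: dict = {}
    for c in codons:
        aa = code.aa(c)
        counts.setdefault(aa, {}).setdefault(c, 0)
        counts[aa][c] += 1
    freqs = {}
    for aa, obs in counts.items():
        total = sum(obs.values())
        fam = {c: obs.get(c, 0) / total for c in code.family(aa)}
        # keep observed non-table codons (ambiguity -> 'X') out of families
        if not fam:
            fam = {c: n / total for c, n in obs.items()}
        freqs[aa] = fam
    return CodonUsage(frequencies=freqs)


def shuffle_synonymous(cds: str, code: GeneticCode, usage: CodonUsage, seed: int) -> str:
    """Redraw every codon from its family's usage distribution.

    The sense-frame protein is unchanged by construction (asserted);
    the terminal codon is kept verbatim when it is a stop.  The same
    seed always yields the same output.
    """
    rng = np.random.default_rng(seed)
    codons = _codons_of(cds)
    out = []
    last = len(codons) - 1
    for i, c in enumerate(codons):
        aa = code.aa(c)
        if i == last and aa == "*":
            out.append(c)
            continue
        fam = usage.family(aa)
        names = sorted(fam)
        probs = np.array([fam[n] for n in names], dtype=float)
        total = probs.sum()
        if total <= 0:
            out.append(c)
            continue
        out.append(names[rng.choice(len(names), p=probs / total)])
    shuffled = "".join(out)
    assert translate_codons(out, code) == translate_codons(codons, code), "sense protein altered"
    return shuffled


def _gau_sense_codon_span(cds: str, gau: GauRegion) -> range:
    """Indices of sense codons whose bases fall inside the region's parent span."""
    n_codons = len(cds) // 3
    lo = (gau.start_nt - 1) // 3
    hi = (gau.end_nt - 1) // 3
    if not (0 <= lo <= hi < n_codons):
        raise ValueError("gau region does not lie within the CDS span")
    return range(lo, hi + 1)


def _gau_protein(cds: str, gau: GauRegion, gau_code: GeneticCode) -> str:
    """Translate the region's parent span of ``cds`` in frame -2."""
    sub = normalize_seq(cds)[gau.start_nt - 1 : gau.end_nt]
    from gauscan.codon_core import revcomp

    rc = revcomp(sub)
    codons = [rc[i : i + 3] for i in range(0, len(rc) - 2, 3)]
    return translate_codons(codons, gau_code)


def _aligned_similarity(sim: str, ref: str, scheme: SimilarityScheme) -> float:
    """% identical-or-similar residues between two proteins (global alignment)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    a = aligner.align(sim.replace("*", "X"), ref.replace("*", "X"))[0]
    ga, gb = str(a[0]), str(a[1])
    pairs = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
    if not pairs:
        return float("nan")
    ok = sum(1 for x, y in pairs if x == y or scheme.similar(x, y))
    return 100.0 * ok / len(pairs)


@dataclass(frozen=True)
class ShuffleReplicate:
    """Per-replicate metrics of one synonymous reshuffling."""

    seed: int
    frac_altered_gene: float
    frac_altered_gau: float
    frac_gau_aa_unchanged: float
    frac_altered_to_aa_change: float
    gau_stop_count: int
    pct_ident_or_sim_vs_reference: float = float("nan")


def replicate_metrics(
    original: str,
    shuffled: str,
    gau: GauRegion,
    gau_code: "GeneticCode | None" = None,
    sense_code: "GeneticCode | None" = None,
    reference_gau_protein: "str | None" = None,
    scheme: SimilarityScheme = DAYHOFF,
    seed: int = -1,
) -> ShuffleReplicate:
    """Compare one shuffled CDS against the original over the antisense region.

    ``frac_altered_gene``: % of sense codons changed over the whole CDS.
    ``frac_altered_gau``: same, restricted to sense codons overlapping the
    region.  ``frac_gau_aa_unchanged``: % of the 101 antisense residues
    identical to the natural ones.  ``frac_altered_to_aa_change``: % of
    altered sense codons (within the region span) whose change altered at
    least one antisense residue.
    """
    gau_code = gau_code or get_code(2)
    orig_codons, shuf_codons = _codons_of(original), _codons_of(shuffled)
    if len(orig_codons) != len(shuf_codons):
        raise ValueError("original and shuffled CDS differ in length")
    if sense_code is not None:
        if translate_codons(orig_codons, sense_code) != translate_codons(shuf_codons, sense_code):
            raise ValueError("shuffled CDS does not preserve the sense protein")
    altered = [i for i in range(len(orig_codons)) if orig_codons[i] != shuf_codons[i]]
    span = _gau_sense_codon_span(original, gau)
    altered_gau = [i for i in altered if i in span]
    prot_orig = _gau_protein(original, gau, gau_code)
    prot_shuf = _gau_protein(shuffled, gau, gau_code)
    unchanged = sum(1 for a, b in zip(prot_orig, prot_shuf) if a == b)
    # which antisense residues each sense codon touches: residue r covers
    # parent codons overlapping its 3 nt; recompute per altered codon
    n_changing = 0
    for i in altered_gau:
        lo_nt, hi_nt = 3 * i, 3 * i + 2
        touched = []
        for r in range(len(prot_orig)):
            # region residue r (0-based) occupies parent 0-based positions
            r_hi = gau.end_nt - 1 - 3 * r
            r_lo = r_hi - 2
            if r_lo <= hi_nt and lo_nt <= r_hi:
                touched.append(r)
        if any(prot_orig[r] != prot_shuf[r] for r in touched):
            n_changing += 1
    stops = prot_shuf.count("*")
    sim_pct = float("nan")
    if reference_gau_protein is not None:
        sim_pct = _aligned_similarity(prot_shuf, reference_gau_protein, scheme)
    pct = lambda k, n: (100.0 * k / n) if n else 0.0
    return ShuffleReplicate(
        seed=seed,
        frac_altered_gene=pct(len(altered), len(orig_codons)),
        frac_altered_gau=pct(len(altered_gau), len(span)),
        frac_gau_aa_unchanged=pct(unchanged, len(prot_orig)),
        frac_altered_to_aa_change=pct(n_changing, len(altered_gau)),
        gau_stop_count=stops,
        pct_ident_or_sim_vs_reference=sim_pct,
    )


def enumerate_stop_sites(
    cds: str,
    code: GeneticCode,
    gau: GauRegion,
    gau_code: "GeneticCode | None" = None,
) -> set:
    """Antisense residue indices (1-based, 1..101) where some synonymous
    sense change creates a stop.

    Brute force: for every sense codon overlapping the region, try every
    synonymous alternative, retranslate the region in frame -2, and record
    residues that become stops.  Deterministic.
    """
    gau_code = gau_code or get_code(2)
    codons = _codons_of(cds)
    span = _gau_sense_codon_span(cds, gau)
    base_prot = _gau_protein(cds, gau, gau_code)
    sites: set = set()
    for i in span:
        aa = code.aa(codons[i])
        for alt in code.family(aa):
            if alt == codons[i]:
                continue
            variant = codons.copy()
            variant[i] = alt
            prot = _gau_protein("".join(variant), gau, gau_code)
            for r, (a, b) in enumerate(zip(base_prot, prot)):
                if b == "*" and a != "*":
                    sites.add(r + 1)
    return sites


@dataclass(frozen=True)
class ShuffleSummary:
    n_reps: int
    means: dict
    sds: dict
    paired_t: float
    paired_p: float
    one_sample_t: float
    one_sample_p: float
    natural_gau_stop_count: int
    degenerate: bool = False


_METRICS = (
    "frac_altered_gene",
    "frac_altered_gau",
    "frac_gau_aa_unchanged",
    "frac_altered_to_aa_change",
    "gau_stop_count",
    "pct_ident_or_sim_vs_reference",
)


def summarize_replicates(
    reps: list,
    natural_gau_stop_count: int,
    natural_similarity: "float | None" = None,
) -> ShuffleSummary:
    """Aggregate replicate metrics with paired and one-sample t tests.

    The paired test contrasts per-replicate altered fractions over the
    whole gene versus the antisense region (two-tailed, n-1 df); the
    one-sample test contrasts replicate reference-similarity against the
    natural value when both are available.  Zero variance of the paired
    differences is flagged degenerate and the p-value omitted (nan).
    """
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates for t statistics")
    arr = {m: np.array([getattr(r, m) for r in reps], dtype=float) for m in _METRICS}
    means = {m: float(np.mean(v)) for m, v in arr.items()}
    sds = {m: float(np.std(v, ddof=1)) for m, v in arr.items()}
    diffs = arr["frac_altered_gau"] - arr["frac_altered_gene"]
    degenerate = bool(np.isclose(np.std(diffs, ddof=1), 0.0))
    if degenerate:
        paired_t, paired_p = (0.0 if np.allclose(diffs, 0) else math.inf), float("nan")
    else:
        paired_t, paired_p = stats.ttest_rel(arr["frac_altered_gau"], arr["frac_altered_gene"])
    one_t = one_p = float("nan")
    sims = arr["pct_ident_or_sim_vs_reference"]
    if natural_similarity is not None and not np.isnan(sims).any():
        if np.isclose(np.std(sims, ddof=1), 0.0):
            one_t, one_p = 0.0, float("nan")
        else:
            one_t, one_p = stats.ttest_1samp(sims, natural_similarity)
    return ShuffleSummary(
        n_reps=len(reps),
        means=means,
        sds=sds,
        paired_t=float(paired_t),
        paired_p=float(paired_p),
        one_sample_t=float(one_t),
        one_sample_p=float(one_p),
        natural_gau_stop_count=natural_gau_stop_count,
        degenerate=degenerate,
    )


def run_shuffle(
    cds: str,
    gau: GauRegion,
    sense_code: GeneticCode,
    gau_code: "GeneticCode | None" = None,
    n_reps: int = 20,
    seed: int = 0,
    reference_gau_protein: "str | None" = None,
    scheme: SimilarityScheme = DAYHOFF,
) -> tuple:
    """Full null-model run: usage, ``n_reps`` reshufflings, summary.

    Replicate seeds are derived counter-style from the master seed
    (``seed * 10000 + index``) and logged on each replicate.
    """
    gau_code = gau_code or get_code(2)
    usage = codon_usage(cds, sense_code)
    natural_prot = _gau_protein(cds, gau, gau_code)
    reps = []
    for i in range(n_reps):
        rep_seed = (seed * 10_000 + i) % (2**31)
        shuffled = shuffle_synonymous(cds, sense_code, usage, rep_seed)
        reps.append(
            replicate_metrics(
                cds,
                shuffled,
                gau,
                gau_code=gau_code,
                sense_code=sense_code,
                reference_gau_protein=reference_gau_protein,
                scheme=scheme,
                seed=rep_seed,
            )
        )
    natural_sim = None
    if reference_gau_protein is not None:
        natural_sim = _aligned_similarity(natural_prot, reference_gau_protein, scheme)
    summary = summarize_replicates(reps, natural_prot.count("*"), natural_sim)
    return reps, summary
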