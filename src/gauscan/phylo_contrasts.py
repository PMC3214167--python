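"""Phylogenetically independent contrasts of AGR-codon counts.

Each contrast compares, at a matched node of the phylogeny, the mean
number of AGA/AGG codons in the antisense region between a monophyletic
group of taxa predicted to carry an antitermination tRNA (anticodon
matching AGR stop codons) and its sister group without the tRNA.
Physiological translation of the region predicts positive contrasts.
Tests: an exact one-sided sign test over contrast signs (integer
binomial arithmetic), Spearman rank correlation of contrast versus
divergence time (exact permutation p for small n), and Fitch parsimony
labelling of gain versus loss scenarios on a supplied tree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from gauscan.gau_locator import GauRegion


def count_agr(region: GauRegion) -> int:
    """Number of AGA + AGG codons among the region's 101 codons."""
    return sum(1 for c in region.codons if c in ("AGA", "AGG"))


@dataclass(frozen=True)
class ContrastRecord:
    """One matched-group contrast: with-tRNA versus without-tRNA AGR counts."""

    group_id: str
    with_counts: tuple
    without_counts: tuple
    divergence_time: float = float("nan")
    scenario: str = ""  # "gain" | "loss" | ""

    def __post_init__(self) -> None:
        if not self.with_counts or not self.without_counts:
            raise ValueError(f"group {self.group_id}: both taxon lists must be non-empty")

    @property
    def contrast(self) -> float:
        return compute_contrast(self.with_counts, self.without_counts)

    @property
    def min_n(self) -> int:
        return min(len(self.with_counts), len(self.without_counts))


def compute_contrast(with_counts, without_counts) -> float:
    """mean(with-tRNA counts) - mean(without-tRNA counts)."""
    if not len(with_counts) or not len(without_counts):
        raise ValueError("empty count list")
    return float(np.mean(with_counts) - np.mean(without_counts))


def sign_test(contrasts, direction: str = "positive") -> dict:
    """Exact one-sided sign test on contrast signs.

    Zeros are dropped (their count is reported); the tail probability
    P(X >= k | n, 1/2) is computed by exact integer binomial arithmetic.
    ``direction='negative'`` counts negative contrasts as successes.
    """
    values = [float(c) for c in contrasts]
    nonzero = [c for c in values if c != 0.0]
    n_zero = len(values) - len(nonzero)
    if not nonzero:
        return {"n": 0, "k": 0, "n_zero_dropped": n_zero, "p": float("nan"), "degenerate": True}
    success = (lambda c: c > 0) if direction == "positive" else (lambda c: c < 0)
    k = sum(1 for c in nonzero if success(c))
    n = len(nonzero)
    tail = Fraction(sum(math.comb(n, i) for i in range(k, n + 1)), 2**n)
    return {"n": n, "k": k, "n_zero_dropped": n_zero, "p": float(tail), "p_exact": tail, "degenerate": False}


def _rankdata(x) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y, alternative: str = "two-sided", exact_max_n: int = 8) -> dict:
    """Spearman rank correlation with average-rank ties.

    rs is the Pearson correlation of the ranks.  For n <= ``exact_max_n``
    the p-value is exact, computed by full enumeration of the n!
    permutations of one margin; larger samples use the t approximation
    with n-2 df.  ``alternative``: 'two-sided', 'greater' (positive
    association) or 'less'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rs": float("nan"), "p": float("nan"), "degenerate": True, "method": "degenerate"}
    rx, ry = _rankdata(x), _rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if alternative == "greater":
                count += r >= rs - 1e-12
            elif alternative == "less":
                count += r <= rs + 1e-12
            else:
                count += abs(r) >= abs(rs) - 1e-12
        return {"rs": rs, "p": count / total, "degenerate": False, "method": "exact-permutation"}
    t = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
    if alternative == "greater":
        p = float(stats.t.sf(t, n - 2))
    elif alternative == "less":
        p = float(stats.t.cdf(t, n - 2))
    else:
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return {"rs": rs, "p": p, "degenerate": False, "method": "t-approximation"}


# ---------------------------------------------------------------- Fitch

def fitch_gain_loss(tree, tip_presence: dict) -> dict:
    """Fitch small parsimony for a binary presence/absence character.

    ``tree`` is a dendropy Tree or a newick string; every leaf label must
    appear in ``tip_presence`` (0/1).  Bottom-up pass computes state sets;
    the top-down pass assigns a single state per node (root ambiguity is
    resolved to absence, so changes along the tree read as gains where
    possible).  Returns the minimal change count, per-node states, and
    per-edge events ('gain' for 0->1 on the stem edge, 'loss' for 1->0).
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    sets: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in tip_presence:
                raise ValueError(f"unlabeled tip {label!r}")
            sets[node] = {int(tip_presence[label])}
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = set.intersection(*child_sets)
            if inter:
                sets[node] = inter
            else:
                sets[node] = set.union(*child_sets)
                changes += 1
    states: dict = {}
    events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = 0 if 0 in sets[node] else 1
        else:
            parent_state = states[node.parent_node]
            states[node] = parent_state if parent_state in sets[node] else min(sets[node])
            if states[node] != parent_state:
                label = node.taxon.label if node.is_leaf() and node.taxon else (node.label or "")
                events.append(("gain" if states[node] == 1 else "loss", label))
    named_states = {}
    for node, st in states.items():
        label = node.taxon.label if node.is_leaf() and node.taxon else node.label
        if label:
            named_states[label] = st
    return {"n_changes": changes, "events": events, "states": named_states}


# ------------------------------------------------------- analysis driver

@dataclass(frozen=True)
class ContrastTests:
    n_contrasts: int
    n_positive: int
    sign_all: dict
    sign_gains: dict
    spearman_gains: dict
    spearman_losses: dict


def records_from_table(table: pd.DataFrame) -> list:
    """Build ContrastRecords from a taxon table.

    Expected columns: taxon, group_id, trna_present (0/1), agr_count,
    and optionally divergence_time_my and scenario.
    """
    records = []
    for gid, grp in table.groupby("group_id", sort=True):
        with_counts = tuple(grp.loc[grp["trna_present"] == 1, "agr_count"])
        without_counts = tuple(grp.loc[grp["trna_present"] == 0, "agr_count"])
        time = float(grp["divergence_time_my"].iloc[0]) if "divergence_time_my" in grp else float("nan")
        scenario = str(grp["scenario"].iloc[0]) if "scenario" in grp else ""
        records.append(
            ContrastRecord(
                group_id=str(gid),
                with_counts=with_counts,
                without_counts=without_counts,
                divergence_time=time,
                scenario=scenario,
            )
        )
    return records


def run_contrast_analysis(records) -> tuple:
    """All contrast tests plus per-group scatter rows.

    One-sided sign tests (all contrasts, and gains only); Spearman of
    contrast against divergence time one-sided for gains, two-sided for
    losses.  Spearman is skipped (nan) when divergence times are missing
    or a scenario has fewer than 3 groups.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_table(records)
    if len(records) < 2:
        raise ValueError("need at least 2 contrasts")
    contrasts = [r.contrast for r in records]
    gains = [r for r in records if r.scenario == "gain"]
    losses = [r for r in records if r.scenario == "loss"]
    skipped = {"rs": float("nan"), "p": float("nan"), "degenerate": True, "method": "skipped"}

    def _spear(rs_list, alternative):
        times = [r.divergence_time for r in rs_list]
        if len(rs_list) < 3 or any(math.isnan(t) for t in times):
            return skipped
        return spearman_rho(times, [r.contrast for r in rs_list], alternative=alternative)

    tests = ContrastTests(
        n_contrasts=len(records),
        n_positive=sum(1 for c in contrasts if c > 0),
        sign_all=sign_test(contrasts),
        sign_gains=sign_test([r.contrast for r in gains]) if gains else {"n": 0, "k": 0, "p": float("nan"), "degenerate": True},
        spearman_gains=_spear(gains, "greater"),
        spearman_losses=_spear(losses, "two-sided"),
    )
    scatter = pd.DataFrame(
        {
            "group_id": [r.group_id for r in records],
            "divergence_time_my": [r.divergence_time for r in records],
            "contrast": contrasts,
            "min_n": [r.min_n for r in records],
            "scenario": [r.scenario for r in records],
        }
    )
    return tests, scatter
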