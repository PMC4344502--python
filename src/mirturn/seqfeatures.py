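"""Positional sequence features of fast- vs slow-turnover isoforms.

Compares nucleotide composition position by position (1-based from the
5' end, plus the final base as "last") between the fast- and
slow-turnover isoform sets, using Fisher's exact test on the 2x2
(nucleotide yes/no) x (fast/slow) table and a label-permutation null:
draw the fast-set size from the pooled fast+slow isoforms without
replacement, M times, and count iterations with a nucleotide frequency
at least as extreme as observed (one-sided in the observed direction, no
pseudocount). Since the permutation statistic depends only on how many
marked isoforms land in the drawn set, the draws are sampled directly
from the hypergeometric distribution, which is distributionally
identical to permuting labels.

Also computes the positions-13-16 A-rich motif statistic (indicator:
>= min_a A's in the window, sequences >= 16 nt) and per-set length
histograms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import NTS, ThresholdConfig


class FeatureError(ValueError):
    pass


@dataclass
class GroupedIsoformSets:
    """Disjoint fast- and slow-turnover isoform sequence sets."""

    fast: list
    slow: list

    def __post_init__(self):
        if not self.fast or not self.slow:
            raise FeatureError("both the fast and the slow set must be non-empty")
        self.fast = [s.upper().replace("U", "T") for s in self.fast]
        self.slow = [s.upper().replace("U", "T") for s in self.slow]
        if set(self.fast) & set(self.slow):
            raise FeatureError("fast and slow sets must be disjoint")

    @property
    def pool(self):
        return self.fast + self.slow


def sets_from_calls(calls: pd.DataFrame, meta: pd.DataFrame) -> GroupedIsoformSets:
    """Build fast/slow sets from isoform-level turnover calls.

    Keeps detected mature-region isoforms only; fast = the <50%/<25%
    classes, slow = the slow class; intermediate and unclassified
    isoforms are excluded.
    """
    merged = calls.join(meta[["sequence", "region"]], how="inner")
    ok = merged["detected"] & merged["region"].str.startswith("mature")
    fast = merged.loc[ok & merged["turnover_class"].isin(("fast_lt25", "fast_lt50")),
                      "sequence"]
    slow = merged.loc[ok & (merged["turnover_class"] == "slow"), "sequence"]
    slow = slow[~slow.isin(set(fast))]
    return GroupedIsoformSets(fast=list(fast.unique()), slow=list(slow.unique()))


def _base_at(seq: str, position) -> str | None:
    if position == "last":
        return seq[-1] if seq else None
    if 1 <= position <= len(seq):
        return seq[position - 1]
    return None


def positional_composition(sets: GroupedIsoformSets, positions) -> pd.DataFrame:
    """Counts and frequencies per position x nucleotide in each set.

    ``positions`` mixes 1-based integers and the string "last". The
    per-position set size counts only sequences long enough to have that
    position. Pass ``positions="total"`` for the aggregate composition
    over all positions of all sequences.
    """
    if positions == "total":
        return _total_composition(sets)
    rows = []
    for pos in positions:
        bases_fast = [_base_at(s, pos) for s in sets.fast]
        bases_slow = [_base_at(s, pos) for s in sets.slow]
        n_fast = sum(b is not None for b in bases_fast)
        n_slow = sum(b is not None for b in bases_slow)
        cf, cs = Counter(bases_fast), Counter(bases_slow)
        for nt in NTS:
            rows.append({
                "position": pos, "nucleotide": nt,
                "count_fast": cf.get(nt, 0), "count_slow": cs.get(nt, 0),
                "n_fast": n_fast, "n_slow": n_slow,
                "freq_fast": cf.get(nt, 0) / n_fast if n_fast else np.nan,
                "freq_slow": cs.get(nt, 0) / n_slow if n_slow else np.nan,
            })
    df = pd.DataFrame(rows)
    df["freq_ratio"] = df["freq_fast"] / df["freq_slow"]
    return df


def _total_composition(sets: GroupedIsoformSets) -> pd.DataFrame:
    cf = Counter("".join(sets.fast))
    cs = Counter("".join(sets.slow))
    nf, ns = sum(len(s) for s in sets.fast), sum(len(s) for s in sets.slow)
    rows = [{"position": "total", "nucleotide": nt,
             "count_fast": cf.get(nt, 0), "count_slow": cs.get(nt, 0),
             "n_fast": nf, "n_slow": ns,
             "freq_fast": cf.get(nt, 0) / nf, "freq_slow": cs.get(nt, 0) / ns}
            for nt in NTS]
    df = pd.DataFrame(rows)
    df["freq_ratio"] = df["freq_fast"] / df["freq_slow"]
    return df


def fisher_two_sided(count_fast, n_fast, count_slow, n_slow) -> float:
    """Two-sided Fisher exact p for the (feature yes/no) x (fast/slow) table."""
    table = [[count_fast, n_fast - count_fast],
             [count_slow, n_slow - count_slow]]
    if min(n_fast, n_slow) == 0 or (count_fast + count_slow) in (0, n_fast + n_slow):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def permutation_pvalue(count_fast, n_fast, count_slow, n_slow,
                       iterations: int, rng) -> tuple:
    """One-sided permutation p in the observed direction.

    Returns ``(p, direction)`` with direction in {"enriched", "depleted",
    "none"}. p has granularity 1/iterations and no pseudocount; a zero
    count is therefore reported as 0.0 (resolution floor 1/M).
    """
    if iterations <= 0:
        raise FeatureError("iterations must be > 0")
    total = n_fast + n_slow
    marked = count_fast + count_slow
    if total == 0 or n_fast == 0:
        return 1.0, "none"
    if marked in (0, total):
        return 1.0, "none"
    expected = n_fast * marked / total
    draws = rng.hypergeometric(marked, total - marked, n_fast, size=iterations)
    if count_fast > expected:
        return float(np.mean(draws >= count_fast)), "enriched"
    if count_fast < expected:
        return float(np.mean(draws <= count_fast)), "depleted"
    return float(np.mean(draws >= count_fast)), "none"


def position_enrichment_tests(sets: GroupedIsoformSets, positions,
                              iterations: int = 10000,
                              seed: int = 0) -> pd.DataFrame:
    """Fisher and permutation p-values per position x nucleotide."""
    rng = np.random.default_rng(seed)
    comp = positional_composition(sets, positions)
    fisher, perm, direction = [], [], []
    for row in comp.itertuples(index=False):
        fisher.append(fisher_two_sided(row.count_fast, row.n_fast,
                                       row.count_slow, row.n_slow))
        p, d = permutation_pvalue(row.count_fast, row.n_fast,
                                  row.count_slow, row.n_slow, iterations, rng)
        perm.append(p)
        direction.append(d)
    out = comp.copy()
    out["fisher_p"] = fisher
    out["perm_p"] = perm
    out["direction"] = direction
    out["perm_resolution"] = 1.0 / iterations
    return out


def a_rich_motif_stat(sets: GroupedIsoformSets, window=(13, 16), min_a: int = 3,
                      iterations: int = 10000, seed: int = 0):
    """A-rich motif in the central window (default positions 13-16).

    Sequences shorter than the window end are excluded (and tallied).
    Returns ``(motif_row, per_position_a)``: the motif-indicator test
    (>= min_a A's in the window) and the per-position A statistics.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise FeatureError(f"bad window {window}")
    rng = np.random.default_rng(seed)

    def indicator(seqs):
        kept = [s for s in seqs if len(s) >= hi]
        n_with = sum(1 for s in kept if s[lo - 1:hi].count("A") >= min_a)
        return n_with, len(kept), len(seqs) - len(kept)

    wf, nf, exf = indicator(sets.fast)
    ws, ns, exs = indicator(sets.slow)
    fisher = fisher_two_sided(wf, nf, ws, ns)
    perm, direction = permutation_pvalue(wf, nf, ws, ns, iterations, rng)
    motif = pd.Series({
        "window_start": lo, "window_end": hi, "min_a": min_a,
        "count_fast": wf, "n_fast": nf, "excluded_fast": exf,
        "count_slow": ws, "n_slow": ns, "excluded_slow": exs,
        "freq_fast": wf / nf if nf else np.nan,
        "freq_slow": ws / ns if ns else np.nan,
        "fisher_p": fisher, "perm_p": perm, "direction": direction,
        "perm_resolution": 1.0 / iterations,
    })
    window_sets = GroupedIsoformSets(
        fast=[s for s in sets.fast if len(s) >= hi] or sets.fast,
        slow=[s for s in sets.slow if len(s) >= hi] or sets.slow)
    per_pos = position_enrichment_tests(window_sets, list(range(lo, hi + 1)),
                                        iterations=iterations, seed=seed + 1)
    per_pos = per_pos[per_pos["nucleotide"] == "A"].reset_index(drop=True)
    return motif, per_pos


def length_distribution(sets: GroupedIsoformSets) -> pd.DataFrame:
    """Integer length histograms per set, with the modal length."""
    lf = Counter(len(s) for s in sets.fast)
    ls = Counter(len(s) for s in sets.slow)
    lengths = sorted(set(lf) | set(ls))
    df = pd.DataFrame({
        "length": lengths,
        "count_fast": [lf.get(x, 0) for x in lengths],
        "count_slow": [ls.get(x, 0) for x in lengths],
    })
    df.attrs["mode_fast"] = max(lf, key=lambda x: (lf[x], -x))
    df.attrs["mode_slow"] = max(ls, key=lambda x: (ls[x], -x))
    return df


def feature_report(sets: GroupedIsoformSets,
                   thresholds: ThresholdConfig | None = None,
                   iterations: int | None = None, seed: int = 0):
    """The standard feature panel: first base, last base, total
    composition, A-rich 13-16 motif and length distributions."""
    thresholds = thresholds or ThresholdConfig()
    m = iterations or thresholds.permutation_iters
    first_last = position_enrichment_tests(sets, [1, "last"], m, seed)
    total = positional_composition(sets, "total")
    motif, per_pos_a = a_rich_motif_stat(
        sets, min_a=thresholds.min_a_count, iterations=m, seed=seed + 17)
    lengths = length_distribution(sets)
    return {"first_last": first_last, "total_composition": total,
            "a_motif": motif, "a_by_position": per_pos_a, "lengths": lengths}
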