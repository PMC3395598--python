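"""Conditioned-activation and group-comparison statistics.

Covers the analyses that relate the global-factor (RpoS reporter) level to
activation of the mobile-element promoters: quadrant-conditioned activation
fractions, reporter-reporter correlation across replicates, conjugative
transfer frequency, and the ANOVA/Tukey machinery that produces the compact
significance letters used in replicate tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "QuadrantResult",
    "TransferResult",
    "quadrant_activation",
    "reporter_correlation",
    "transfer_frequency",
    "compare_groups",
    "GroupComparison",
]

QUADRANT_NAMES = ("Q1st", "Q2nd", "Q3rd", "Q4th")


@dataclass
class QuadrantResult:
    """Activation fractions conditioned on quartile-like bins of a channel.

    The conditioning distribution (e.g. RpoS-mCherry intensity) is cut at
    mean - SD, mean, and mean + SD; within each of the four bins the fraction
    of cells whose reporter value reaches ``threshold`` is recorded.  An
    empty bin yields a NaN fraction with count 0.
    """

    boundaries: tuple[float, float, float]
    fractions: tuple[float, float, float, float]
    counts: tuple[int, int, int, int]
    threshold: float

    @property
    def overall_fraction(self) -> float:
        """Count-weighted recombination of the per-bin fractions."""
        total = sum(self.counts)
        return (
            sum(f * c for f, c in zip(self.fractions, self.counts) if c > 0) / total
        )


def quadrant_activation(
    conditioning_values, reporter_values, reporter_threshold: float
) -> QuadrantResult:
    """Fraction of cells activated per quadrant of the conditioning channel.

    Boundaries are the empirical mean - SD, mean, and mean + SD of the
    conditioning values (population SD); a cell counts as activated when its
    reporter value is >= ``reporter_threshold``.
    """
    cond = np.asarray(conditioning_values, dtype=float).ravel()
    rep = np.asarray(reporter_values, dtype=float).ravel()
    if cond.size != rep.size:
        raise ValueError("conditioning and reporter lists must be paired")
    if cond.size == 0:
        raise ValueError("empty input")

    mu = float(np.mean(cond))
    sd = float(np.std(cond))
    bounds = (mu - sd, mu, mu + sd)
    edges = np.array([-np.inf, *bounds, np.inf])

    fractions = []
    counts = []
    active = rep >= reporter_threshold
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (cond >= lo) & (cond < hi)
        cnt = int(in_bin.sum())
        counts.append(cnt)
        fractions.append(float(active[in_bin].mean()) if cnt else float("nan"))

    return QuadrantResult(
        boundaries=bounds,
        fractions=tuple(fractions),
        counts=tuple(counts),
        threshold=float(reporter_threshold),
    )


def reporter_correlation(replicates: list[tuple]) -> dict:
    """Pearson correlation between paired reporters, per replicate.

    ``replicates`` is a list of ``(g, c)`` paired arrays, one per biological
    replicate.  Returns per-replicate r plus the across-replicate mean ± SD,
    the standard triplicate-reporting convention.  A replicate with a
    zero-variance channel yields ``r = nan`` and the ``"zero_variance"``
    flag, and is dropped from the summary.
    """
    if not replicates:
        raise ValueError("no replicates given")
    rs = []
    flags = []
    for g, c in replicates:
        g = np.asarray(g, dtype=float).ravel()
        c = np.asarray(c, dtype=float).ravel()
        if g.size != c.size or g.size < 2:
            raise ValueError("each replicate needs >= 2 paired cells")
        if np.std(g) == 0 or np.std(c) == 0:
            rs.append(float("nan"))
            flags.append("zero_variance")
            continue
        rs.append(float(stats.pearsonr(g, c).statistic))
    valid = [r for r in rs if not np.isnan(r)]
    return {
        "r_per_replicate": rs,
        "r_mean": float(np.mean(valid)) if valid else float("nan"),
        "r_sd": float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0,
        "flags": tuple(sorted(set(flags))),
    }


@dataclass
class TransferResult:
    """Conjugative transfer frequency: transconjugant CFU per donor CFU."""

    donor_cfu: int
    transconjugant_cfu: int
    frequency: float
    at_detection_limit: bool

    def detection_limit(self) -> float:
        """Frequency that a single transconjugant colony would represent."""
        return 1.0 / self.donor_cfu


def transfer_frequency(transconjugant_cfu: int, donor_cfu: int) -> TransferResult:
    """Ratio of transconjugant to donor colony-forming units.

    Zero transconjugants gives frequency 0 flagged as at the detection limit
    of the assay (the smallest observable frequency is 1/donors).
    """
    if donor_cfu <= 0:
        raise ValueError(f"donor_cfu must be > 0, got {donor_cfu}")
    if transconjugant_cfu < 0:
        raise ValueError(f"transconjugant_cfu must be >= 0, got {transconjugant_cfu}")
    return TransferResult(
        donor_cfu=int(donor_cfu),
        transconjugant_cfu=int(transconjugant_cfu),
        frequency=transconjugant_cfu / donor_cfu,
        at_detection_limit=transconjugant_cfu == 0,
    )


@dataclass
class GroupComparison:
    """ANOVA/Tukey (or pairwise t-test) outcome with significance letters."""

    method: str
    p_value: float | None              # ANOVA F-test p (or t-test p for 2 groups)
    f_statistic: float | None
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _compact_letter_display(
    names: list[str], significant: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment from a significance relation.

    Groups sharing a letter are not significantly different.  The result
    depends only on the significance relation, not on group ordering: letter
    sets are canonicalized by sorting before letters are assigned.
    """
    letters: list[set[str]] = [set(names)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for col in [c for c in letters if a in c and b in c]:
            letters.remove(col)
            col_a = col - {b}
            col_b = col - {a}
            for new in (col_a, col_b):
                if not any(new <= other for other in letters):
                    letters.append(new)
    # absorb duplicates/subsets, then canonical order for determinism
    letters = [c for c in letters if not any(c < o for o in letters)]
    order = {n: i for i, n in enumerate(sorted(names))}
    letters.sort(key=lambda c: sorted(order[n] for n in c))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {n: "" for n in names}
    for letter, col in zip(alphabet, letters):
        for n in col:
            out[n] += letter
    return {n: "".join(sorted(v)) for n, v in out.items()}


def compare_groups(
    groups: dict[str, list], method: str = "anova_tukey", alpha: float = 0.05
) -> GroupComparison:
    """Compare named groups of replicate values.

    ``method="anova_tukey"`` runs a one-way ANOVA followed by Tukey's HSD
    and derives a compact letter display at ``alpha`` (groups sharing a
    letter are not significantly different).  ``method="ttest"`` requires
    exactly two groups and returns the homoscedastic two-sample t-test.
    """
    names = list(groups)
    arrays = {n: np.asarray(v, dtype=float).ravel() for n, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for n, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {n!r} needs >= 2 values, got {v.size}")

    if method == "ttest":
        if len(names) != 2:
            raise ValueError(f"t-test requires exactly 2 groups, got {len(names)}")
        a, b = names
        res = stats.ttest_ind(arrays[a], arrays[b], equal_var=True)
        p = float(res.pvalue)
        sig = {(a, b): p < alpha}
        return GroupComparison(
            method="ttest",
            p_value=p,
            f_statistic=None,
            pairwise_p={(a, b): p},
            letters=_compact_letter_display(names, sig),
            alpha=alpha,
        )

    if method != "anova_tukey":
        raise ValueError(f"unknown method {method!r}")

    f_stat, p_anova = stats.f_oneway(*(arrays[n] for n in names))
    values = np.concatenate([arrays[n] for n in names])
    labels = np.concatenate([[n] * arrays[n].size for n in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # statsmodels orders pairs by sorted group names
    pair_names = [tuple(pair) for pair in itertools.combinations(sorted(names), 2)]
    pairwise_p = {
        pair: float(p) for pair, p in zip(pair_names, tukey.pvalues)
    }
    significant = {pair: p < alpha for pair, p in pairwise_p.items()}
    return GroupComparison(
        method="anova_tukey",
        p_value=float(p_anova),
        f_statistic=float(f_stat),
        pairwise_p=pairwise_p,
        letters=_compact_letter_display(names, significant),
        alpha=alpha,
    )
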