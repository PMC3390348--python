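"""Cross-study gene-list overlap statistics.

Two studies sharing a common background of testable genes are compared by
counting genes significant in both ("the overlap") and contrasting that
count with its chance expectation under an exact upper-tail binomial test:
each of the N background genes lands in the overlap independently with
probability (size_a/N)(size_b/N).  Signed lists additionally yield
directional concordance, a multi-way same-direction test, and list-based
comparisons against a fixed baseline probability for studies that only
publish selected gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .datamodel import DOWN, UNSIGNED, UP, GeneList, ValidationError


def _binom_upper_tail(k: int, n: int, p: float, method: str = "exact") -> float:
    """P(X >= k), X ~ Binomial(n, p); optional normal approximation."""
    if method == "exact":
        return float(scipy.stats.binom.sf(k - 1, n, p))
    if method == "normal":
        mu, sd = n * p, np.sqrt(n * p * (1 - p))
        # continuity-corrected upper tail
        return float(scipy.stats.norm.sf((k - 0.5 - mu) / sd))
    raise ValidationError(f"unknown method: {method!r}")


@dataclass(frozen=True)
class OverlapResult:
    background_n: int
    size_a: int
    size_b: int
    observed: int
    expected: float
    p: float
    concordant_up: int | None = None
    concordant_down: int | None = None
    discordant: int | None = None

    @property
    def concordant_fraction(self) -> float | None:
        if self.concordant_up is None or self.observed == 0:
            return None
        return (self.concordant_up + self.concordant_down) / self.observed


def _check_background(gene_list: GeneList, background: frozenset, label: str) -> None:
    outside = gene_list.symbols - background
    if outside:
        raise ValidationError(
            f"list {label} member(s) outside background: {sorted(outside)[:5]}"
        )


def overlap_test(
    list_a: GeneList, list_b: GeneList, background, method: str = "exact"
) -> OverlapResult:
    """Exact binomial test of the two-list overlap on a common background.

    observed = |A ∩ B|; expected = N (|A|/N)(|B|/N);
    p = P(X >= observed), X ~ Binomial(N, (|A|/N)(|B|/N)).
    When both lists are signed, concordance counts are tallied over the
    overlap.
    """
    background = frozenset(background)
    if not background:
        raise ValidationError("background is empty")
    _check_background(list_a, background, "A")
    _check_background(list_b, background, "B")
    N = len(background)
    inter = list_a.symbols & list_b.symbols
    observed = len(inter)
    rate = (len(list_a) / N) * (len(list_b) / N)
    p = _binom_upper_tail(observed, N, rate, method)
    conc_up = conc_down = disc = None
    if list_a.is_signed and list_b.is_signed:
        conc_up = conc_down = disc = 0
        for s in inter:
            da, db = list_a.direction(s), list_b.direction(s)
            if da == db == UP:
                conc_up += 1
            elif da == db == DOWN:
                conc_down += 1
            else:
                disc += 1
    return OverlapResult(
        background_n=N,
        size_a=len(list_a),
        size_b=len(list_b),
        observed=observed,
        expected=len(list_a) * len(list_b) / N,
        p=p,
        concordant_up=conc_up,
        concordant_down=conc_down,
        discordant=disc,
    )


def directional_agreement(list_a: GeneList, list_b: GeneList) -> tuple[int, int, float]:
    """(n_agree, n_total, fraction) of direction matches over the overlap."""
    for label, gl in (("A", list_a), ("B", list_b)):
        unsigned = [s for s, d in gl.entries.items() if d == UNSIGNED]
        if unsigned:
            raise ValidationError(
                f"list {label} has unsigned entries: {sorted(unsigned)[:5]}"
            )
    inter = list_a.symbols & list_b.symbols
    n_total = len(inter)
    n_agree = sum(1 for s in inter if list_a.direction(s) == list_b.direction(s))
    frac = n_agree / n_total if n_total else float("nan")
    return n_agree, n_total, frac


def multiway_same_direction_test(
    lists: list[GeneList], background
) -> tuple[float, int, float]:
    """Same-direction intersection of m >= 2 signed lists vs chance.

    Under independent selections with equiprobable signs, the expected count
    is N * prod(size_i / N) * 2^(1 - m); the test is the exact upper-tail
    binomial with success probability expected / N.  Returns
    (expected, observed, p).
    """
    if len(lists) < 2:
        raise ValidationError("need at least 2 lists")
    background = frozenset(background)
    if not background:
        raise ValidationError("background is empty")
    for i, gl in enumerate(lists):
        _check_background(gl, background, str(i))
        if not gl.is_signed:
            raise ValidationError(f"list {i} is not fully signed")
    N = len(background)
    m = len(lists)
    common = set.intersection(*(set(gl.symbols) for gl in lists))
    observed = sum(
        1
        for s in common
        if len({gl.direction(s) for gl in lists}) == 1
    )
    expected = N * float(np.prod([len(gl) / N for gl in lists])) * 2.0 ** (1 - m)
    p = _binom_upper_tail(observed, N, expected / N)
    return expected, observed, p


def list_comparison_test(n_selected: int, n_hits: int, baseline_p: float) -> float:
    """Exact binomial test for published selected-gene lists.

    Of ``n_selected`` genes reported by another study (restricted to the
    shared filtered background), ``n_hits`` were significant here with the
    same direction; chance probability per gene is ``baseline_p`` (e.g. the
    fraction significant times 1/2 for direction).  Returns
    P(X >= n_hits), X ~ Binomial(n_selected, baseline_p).
    """
    if not 0 <= n_hits <= n_selected:
        raise ValidationError("need 0 <= n_hits <= n_selected")
    if not 0 < baseline_p < 1:
        raise ValidationError("baseline_p must lie in (0, 1)")
    return _binom_upper_tail(n_hits, n_selected, baseline_p)


def overlap_permutation_p(
    background_n: int,
    size_a: int,
    size_b: int,
    observed: int,
    draws: int = 50_000,
    seed=None,
) -> float:
    """Monte Carlo estimate of the overlap tail under the binomial model.

    Simulates ``draws`` pairs of random lists by marking each background
    gene independently significant with rates size_a/N and size_b/N (so list
    sizes are binomial with the stated expectations) and returns the
    fraction of draws whose overlap count reaches ``observed``.  Converges
    to the exact binomial tail used by :func:`overlap_test`.
    """
    rng = np.random.default_rng(seed)
    pa, pb = size_a / background_n, size_b / background_n
    counts = rng.binomial(background_n, pa * pb, size=draws)
    return float(np.mean(counts >= observed))
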