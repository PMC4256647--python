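"""Co-occurrence and functional-enrichment statistics.

Everything here reduces to a contingency quadruple (N, K, n, k): N background
elements, K background successes, n drawn elements, k drawn successes.  Two
statistics are reported throughout:

* the enrichment ratio ``E = (k/K) / (n/N)`` (or its general two-proportion
  form) — >1 means over-representation;
* the exact hypergeometric tail probability, upper tail P(X >= k) for
  over-representation and lower tail P(X <= k) for under-representation.

The hypergeometric pmf is evaluated in log space via log-gamma so counts up
to ~1e6 cause no overflow; tails are exact sums over the relevant support.
A Yates'-corrected chi-square for 2x2 tables and a generic term-enrichment
scan round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, false_discovery_control

from .io import AnnotationTable


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyCounts:
    """(N, K, n, k): background size, background successes, draws, drawn successes."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        N, K, n, k = self.N, self.K, self.n, self.k
        if not (0 <= K <= N and 0 <= n <= N):
            raise ContractError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
        if not (max(0, n + K - N) <= k <= min(K, n)):
            raise ContractError(
                f"k={k} outside valid support [{max(0, n + K - N)}, {min(K, n)}] "
                f"for N={N}, K={K}, n={n}"
            )


@dataclass(frozen=True)
class FourfoldTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("2x2 cells must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    """An enrichment ratio with its hypergeometric tail probability.

    ``e_ratio`` may be ``inf`` (flagged, never raised) when the reference
    proportion is zero.  ``tail`` records which tail the p-value covers.
    """

    e_ratio: float
    p_value: float
    tail: str
    counts: ContingencyCounts


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_pmf(counts: ContingencyCounts) -> float:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    return float(_log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n))


def hypergeom_tail(counts: ContingencyCounts, tail: str) -> float:
    """Exact tail probability: ``'over'`` -> P(X >= k), ``'under'`` -> P(X <= k)."""
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    lo, hi = max(0, n + K - N), min(K, n)
    if tail == "over":
        ks = np.arange(k, hi + 1)
    elif tail == "under":
        ks = np.arange(lo, k + 1)
    else:
        raise ContractError(f"tail must be 'over' or 'under', got {tail!r}")
    logs = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
    return float(min(1.0, math.exp(logsumexp(logs))))


def e_ratio(k1: float, n1: float, k2: float, n2: float) -> float:
    """Two-proportion enrichment ratio (k1/n1) / (k2/n2).

    A zero reference proportion yields ``inf`` (flagged, not raised); a zero
    focal numerator yields 0.0.
    """
    if n1 <= 0 or n2 <= 0:
        raise ContractError("proportions need positive denominators")
    if k1 == 0:
        return 0.0
    if k2 == 0:
        return math.inf
    return (k1 / n1) / (k2 / n2)


def crosstalk_test(counts: ContingencyCounts, tail: str = "auto") -> EnrichmentResult:
    """E-ratio plus hypergeometric tail for a site-overlap quadruple.

    ``tail='auto'`` follows the ratio: over-representation tail when
    E >= 1, under-representation tail otherwise.
    """
    ratio = e_ratio(counts.k, counts.K, counts.n, counts.N)
    if tail == "auto":
        tail = "over" if ratio >= 1 else "under"
    p = hypergeom_tail(counts, tail)
    return EnrichmentResult(ratio, p, tail, counts)


def yates_chi_square(table: FourfoldTable) -> tuple[float, float]:
    """Yates'-continuity-corrected chi-square for a 2x2 table.

    Returns ``(statistic, p)`` with p from the chi-square(1) survival
    function; a zero margin gives ``(nan, nan)`` (undefined, flagged).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    t = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return (math.nan, math.nan)
    num = max(abs(a * d - b * c) - t / 2, 0.0) ** 2 * t
    stat = num / math.prod(margins)
    return stat, float(chi2.sf(stat, df=1))


@dataclass(frozen=True)
class TermEnrichment:
    term: str
    result: EnrichmentResult
    q_value: float | None = None


def term_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationTable | Mapping[str, set[str]],
    bh_correction: bool = False,
) -> list[TermEnrichment]:
    """Per-term enrichment of a foreground protein set against a background.

    For each term annotating the background: N = |background|, K = annotated
    background proteins, n = |foreground|, k = annotated foreground proteins;
    the E-ratio and auto-tail hypergeometric p are reported, sorted by p.
    ``bh_correction`` adds Benjamini-Hochberg q-values (p-values themselves
    stay unadjusted).
    """
    mapping = annotations.mapping if isinstance(annotations, AnnotationTable) else annotations
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ContractError("foreground must be a subset of the background")
    terms = sorted({t for p in bg for t in mapping.get(p, ())})
    N, n = len(bg), len(fg)
    out: list[TermEnrichment] = []
    for term in terms:
        carriers = {p for p in bg if term in mapping.get(p, ())}
        K = len(carriers)
        k = len(carriers & fg)
        res = crosstalk_test(ContingencyCounts(N, K, n, k))
        out.append(TermEnrichment(term, res))
    out.sort(key=lambda te: (te.result.p_value, te.term))
    if bh_correction and out:
        qs = false_discovery_control([te.result.p_value for te in out])
        out = [TermEnrichment(te.term, te.result, float(q)) for te, q in zip(out, qs)]
    return out


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal rounding as printed in report tables (0.675 -> 0.68)."""
    if not math.isfinite(x):
        return x
    factor = 10**digits
    return math.floor(x * factor + 0.5) / factor
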