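"""Temporal ordering of recorded events from unigram and bigram statistics.

If event A preceded event B, A-then-B bigrams at adjacent edited sites
vastly outnumber B-then-A bigrams.  The decoder initializes an order from
site-1 unigram frequencies and then repeatedly scans adjacent pairs of the
current order, swapping whenever the reverse bigram count strictly exceeds
the forward count, restarting the scan after each swap until a clean pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from dnatape.tape_parse import ParsedRead

__all__ = [
    "BigramMatrix",
    "EventOrder",
    "site_unigrams",
    "bigram_counts",
    "initial_order",
    "refine_order",
    "within_epoch_ratio",
    "ordering_complexity",
]


@dataclass(frozen=True)
class BigramMatrix:
    """Square matrix of adjacent-site symbol transitions.

    ``counts[i, j]`` is the number of times ``symbols[i]`` at site *s* was
    immediately followed by ``symbols[j]`` at site *s+1*, pooled over all
    adjacent site pairs of all reads.
    """

    symbols: Tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.symbols)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be |symbols| x |symbols|")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def get(self, a: str, b: str) -> float:
        return float(self.counts[self.index(a), self.index(b)])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def display_normalized(self) -> np.ndarray:
        """Row-then-column normalized copy, for heatmap display parity only."""
        m = self.counts.astype(float)
        rs = m.sum(axis=1, keepdims=True)
        m = np.divide(m, rs, out=np.zeros_like(m), where=rs > 0)
        cs = m.sum(axis=0, keepdims=True)
        return np.divide(m, cs, out=np.zeros_like(m), where=cs > 0)


@dataclass(frozen=True)
class EventOrder:
    """A permutation of the symbol set with convergence diagnostics."""

    order: Tuple[str, ...]
    converged: bool = True
    passes_used: int = 0


def site_unigrams(
    parsed: Sequence[ParsedRead],
    n_sites: int,
    whitelist: Optional[Sequence[str]] = None,
) -> List[Dict[str, float]]:
    """Per-site normalized symbol frequencies among reads edited at the site."""
    wl = set(whitelist) if whitelist is not None else None
    tables: List[Dict[str, float]] = [dict() for _ in range(n_sites)]
    for p in parsed:
        if not p.valid:
            continue
        for site, sym in enumerate(p.site_symbols()[:n_sites]):
            if sym is None or (wl is not None and sym not in wl):
                continue
            tables[site][sym] = tables[site].get(sym, 0.0) + 1.0
    for t in tables:
        tot = sum(t.values())
        if tot:
            for k in t:
                t[k] /= tot
    return tables


def bigram_counts(
    parsed: Sequence[ParsedRead],
    whitelist: Optional[Sequence[str]] = None,
) -> BigramMatrix:
    """Pool ordered symbol pairs from all adjacent edited site pairs."""
    pairs: Dict[Tuple[str, str], int] = {}
    seen: set = set()
    for p in parsed:
        if not p.valid:
            continue
        syms = p.site_symbols()
        for a, b in zip(syms, syms[1:]):
            if a is None or b is None:
                continue
            seen.update((a, b))
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    if whitelist is not None:
        symbols = tuple(whitelist)
        allowed = set(symbols)
    else:
        symbols = tuple(sorted(seen))
        allowed = seen
    counts = np.zeros((len(symbols), len(symbols)), dtype=float)
    idx = {s: i for i, s in enumerate(symbols)}
    for (a, b), c in pairs.items():
        if a in allowed and b in allowed:
            counts[idx[a], idx[b]] = c
    return BigramMatrix(symbols=symbols, counts=counts)


def initial_order(unigram_table: Mapping[str, float]) -> EventOrder:
    """Symbols by descending site-1 frequency; ties broken lexicographically."""
    if not unigram_table:
        raise ValueError("empty unigram table")
    order = tuple(sorted(unigram_table, key=lambda s: (-unigram_table[s], s)))
    return EventOrder(order=order, converged=True, passes_used=0)


def refine_order(
    init: EventOrder, bg: BigramMatrix, max_passes: Optional[int] = None
) -> EventOrder:
    """Iterative adjacent-swap refinement against the bigram matrix.

    Scans the current order left to right; on the first adjacent pair
    (A, B) with ``counts[B, A] > counts[A, B]`` (strict: ties never swap)
    the pair is swapped and the scan restarts.  Stops after a clean pass or
    ``max_passes`` (default ``n(n-1)/2 + 1``, enough for a full reversal).
    """
    if sorted(init.order) != sorted(bg.symbols):
        raise ValueError("order symbols do not match matrix symbols")
    n = len(init.order)
    if max_passes is None:
        max_passes = n * (n - 1) // 2 + 1
    idx = {s: i for i, s in enumerate(bg.symbols)}
    order = list(init.order)
    passes = 0
    converged = False
    while passes < max_passes:
        passes += 1
        swapped = False
        for k in range(n - 1):
            a, b = order[k], order[k + 1]
            if bg.counts[idx[b], idx[a]] > bg.counts[idx[a], idx[b]]:
                order[k], order[k + 1] = b, a
                swapped = True
                break
        if not swapped:
            converged = True
            break
    return EventOrder(order=tuple(order), converged=converged, passes_used=passes)


def within_epoch_ratio(
    counts: Mapping[str, float],
    efficiency: Mapping[str, float],
    pair: Tuple[str, str],
) -> float:
    """Efficiency-corrected count ratio for a pair of co-introduced symbols.

    Each symbol's total count (summed over all sites) is divided by
    ``2**edit_score`` before taking the ratio ``pair[0] / pair[1]``.
    """
    a, b = pair
    for s in pair:
        if s not in counts:
            raise ValueError(f"symbol {s!r} not observed")
    corr_a = counts[a] / 2.0 ** float(efficiency.get(a, 0.0))
    corr_b = counts[b] / 2.0 ** float(efficiency.get(b, 0.0))
    if corr_b == 0:
        raise ValueError(f"zero corrected count for denominator symbol {b!r}")
    return corr_a / corr_b


def ordering_complexity(n: int) -> Tuple[int, int]:
    """(number of pairwise ordering rules, number of permutations) for n events."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n * n + n) // 2, math.factorial(n)
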