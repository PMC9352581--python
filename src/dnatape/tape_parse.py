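"""Extraction and scoring of ordered insertions from tape amplicon reads.

Reads are assumed to be pre-oriented (merged paired-end or single-end on the
array strand) and trimmed to the array itself, optionally preceded by a
target barcode.  Parsing walks the monomer scaffold; at each junction after
a monomer either the next monomer follows directly (unedited) or a
``barcode + key`` block is found (edited).  Reads carrying a putative
insertion with the wrong key, or not matching the scaffold, are flagged
invalid with a reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

from dnatape.tape_sim import TapeConfig

__all__ = [
    "ParsedRead",
    "EditMetrics",
    "extract_insertions",
    "classify_pattern",
    "editing_metrics",
    "barcode_whitelist",
    "compute_edit_scores",
    "group_long_reads",
]


@dataclass(frozen=True)
class ParsedRead:
    """Result of parsing one amplicon read against a tape scaffold."""

    read_id: str = ""
    target_bc: str = ""
    inserts: Tuple[str, ...] = ()
    n_monomers_observed: int = 0
    pattern: Tuple[bool, ...] = ()
    valid: bool = True
    reason: str = ""
    sequence: str = ""

    @property
    def n_edits(self) -> int:
        return len(self.inserts)

    def site_symbols(self) -> Tuple[Optional[str], ...]:
        """Per-site symbol (None at unedited sites), aligned with ``pattern``."""
        out: List[Optional[str]] = []
        it = iter(self.inserts)
        for edited in self.pattern:
            out.append(next(it) if edited else None)
        return tuple(out)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_insertions(
    read: str,
    config: TapeConfig,
    read_id: str = "",
    max_monomer_mismatch: int = 0,
    max_target_bc_len: int = 32,
) -> ParsedRead:
    """Locate successive monomer copies and record barcode+key insertions.

    Any sequence before the first ``key + monomer`` occurrence is taken as
    the target barcode.  ``max_monomer_mismatch`` (0 or 1) tolerates
    substitution errors inside monomer copies; keys and barcodes are matched
    exactly.
    """
    if max_monomer_mismatch not in (0, 1):
        raise ValueError("max_monomer_mismatch must be 0 or 1")
    mono, key = config.monomer, config.key
    mlen, klen, blen = len(mono), len(key), config.barcode_len

    def mono_at(pos: int) -> bool:
        if pos + mlen > len(read):
            return False
        return _mismatches(read[pos : pos + mlen], mono) <= max_monomer_mismatch

    def fail(reason: str) -> ParsedRead:
        return ParsedRead(
            read_id=read_id, valid=False, reason=reason, sequence=read
        )

    start = -1
    for pos in range(0, min(max_target_bc_len, max(len(read) - klen - mlen, -1)) + 1):
        if read[pos : pos + klen] == key and mono_at(pos + klen):
            start = pos
            break
    if start < 0:
        return fail("no-scaffold")

    target_bc = read[:start]
    pos = start + klen
    inserts: List[str] = []
    pattern: List[bool] = []
    n_monomers = 0
    while pos < len(read):
        if not mono_at(pos):
            return fail("scaffold-mismatch")
        n_monomers += 1
        pos += mlen
        # junction following this monomer
        if pos == len(read):
            pattern.append(False)
            break
        if mono_at(pos):
            pattern.append(False)
            continue
        end = pos + blen + klen
        if end <= len(read) and (end == len(read) or mono_at(end)):
            if read[pos + blen : end] == key:
                inserts.append(read[pos : pos + blen])
                pattern.append(True)
                pos = end
                continue
            return fail("wrong-key")
        return fail("scaffold-mismatch")
    if n_monomers == 0:
        return fail("no-scaffold")
    return ParsedRead(
        read_id=read_id,
        target_bc=target_bc,
        inserts=tuple(inserts),
        n_monomers_observed=n_monomers,
        pattern=tuple(pattern),
        valid=True,
        sequence=read,
    )


def classify_pattern(pattern: Sequence[bool]) -> str:
    """Classify a per-site edited-flag vector.

    ``unedited`` if no site is edited, ``sequential`` if the edited sites
    form a non-empty prefix, ``nonsequential`` otherwise.
    """
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    k = sum(bool(x) for x in pattern)
    if k == 0:
        return "unedited"
    if all(pattern[:k]) and not any(pattern[k:]):
        return "sequential"
    return "nonsequential"


@dataclass(frozen=True)
class EditMetrics:
    """Read-level editing metrics for one parsed amplicon library."""

    efficiency: float
    sequential_error_rate: Optional[float]
    per_site_conditional: Tuple[float, ...]
    read_counts: Dict[str, int]


def editing_metrics(parsed: Sequence[ParsedRead]) -> EditMetrics:
    """Efficiency, sequential error rate and conditional per-site rates.

    efficiency = edited/total valid reads; sequential_error_rate =
    nonsequential/edited (``None`` when nothing is edited);
    ``per_site_conditional[i]`` = fraction of reads edited at site i+1 among
    reads edited at all earlier sites (site 1: among all valid reads).
    """
    valid = [p for p in parsed if p.valid]
    if not valid:
        raise ValueError("need at least one valid read")
    counts = {"unedited": 0, "sequential": 0, "nonsequential": 0,
              "invalid": sum(1 for p in parsed if not p.valid)}
    for p in valid:
        counts[classify_pattern(p.pattern)] += 1
    total = len(valid)
    edited = counts["sequential"] + counts["nonsequential"]
    efficiency = edited / total
    ser = counts["nonsequential"] / edited if edited else None
    n_sites = max(len(p.pattern) for p in valid)
    conditional: List[float] = []
    for i in range(n_sites):
        denom = [p for p in valid
                 if len(p.pattern) > i and all(p.pattern[:i])]
        if not denom:
            break
        conditional.append(sum(p.pattern[i] for p in denom) / len(denom))
    return EditMetrics(
        efficiency=efficiency,
        sequential_error_rate=ser,
        per_site_conditional=tuple(conditional),
        read_counts=counts,
    )


def _two_means_split_1d(values: Sequence[float]) -> Optional[float]:
    """Deterministic 1-D two-means: exhaustive split minimizing within-SS.

    Returns the threshold (midpoint between clusters) or None when the
    values do not separate (all equal).
    """
    xs = sorted(values)
    n = len(xs)
    if n < 2 or xs[0] == xs[-1]:
        return None
    best = (math.inf, None)
    prefix = [0.0]
    prefix_sq = [0.0]
    for x in xs:
        prefix.append(prefix[-1] + x)
        prefix_sq.append(prefix_sq[-1] + x * x)

    def wss(lo: int, hi: int) -> float:  # [lo, hi)
        m = hi - lo
        s = prefix[hi] - prefix[lo]
        sq = prefix_sq[hi] - prefix_sq[lo]
        return sq - s * s / m

    for k in range(1, n):
        if xs[k - 1] == xs[k]:
            continue
        cost = wss(0, k) + wss(k, n)
        if cost < best[0]:
            best = (cost, (xs[k - 1] + xs[k]) / 2.0)
    return best[1]


def barcode_whitelist(
    counts: Mapping[str, int],
    key: Optional[str] = None,
    min_gap: float = 0.0,
) -> Set[str]:
    """Split barcodes into signal/noise by two-means on log10(count+1).

    Barcodes not ending in ``key`` (when given) are excluded beforehand.
    When counts do not separate, all (key-passing) barcodes are returned.
    ``min_gap`` (log10 units) additionally keeps everything unless the two
    cluster means are at least that far apart — useful when the input may
    contain no error species at all.
    """
    items = {bc: c for bc, c in counts.items()
             if key is None or bc.endswith(key)}
    if len(items) < 2:
        return set(items)
    logs = {bc: math.log10(c + 1) for bc, c in items.items()}
    thr = _two_means_split_1d(list(logs.values()))
    if thr is None:
        return set(items)
    if min_gap > 0.0:
        lo = [v for v in logs.values() if v <= thr]
        hi = [v for v in logs.values() if v > thr]
        if sum(hi) / len(hi) - sum(lo) / len(lo) < min_gap:
            return set(items)
    return {bc for bc, v in logs.items() if v > thr}


def compute_edit_scores(
    replicates: Union[Mapping[str, float], Sequence[Mapping[str, float]]],
    abundances: Mapping[str, float],
    pseudo: Optional[float] = None,
) -> Dict[str, float]:
    """Per-barcode edit scores: mean over replicates of log2(freq/abundance).

    Replicates may be raw counts or frequencies; each replicate and the
    abundance table are renormalized to sum to 1.  ``pseudo`` (added to both
    normalized terms) defaults to the half-count correction 0.5/total when a
    replicate looks like counts (sum > 2), else 0 — in which case zero
    frequencies are rejected.
    """
    if isinstance(replicates, Mapping):
        replicates = [replicates]
    if not replicates:
        raise ValueError("need at least one replicate")
    a_tot = float(sum(abundances.values()))
    if a_tot <= 0:
        raise ValueError("abundances must have positive total")
    scores: Dict[str, List[float]] = {}
    for rep in replicates:
        missing = [bc for bc in rep if bc not in abundances]
        if missing:
            raise ValueError(f"barcodes absent from abundances: {missing}")
        tot = float(sum(rep.values()))
        if tot <= 0:
            raise ValueError("replicate must have positive total")
        eps = pseudo if pseudo is not None else (0.5 / tot if tot > 2 else 0.0)
        for bc in abundances:
            f = rep.get(bc, 0.0) / tot
            a = abundances[bc] / a_tot
            if eps == 0.0 and (f == 0.0 or a == 0.0):
                raise ValueError(
                    f"zero frequency for {bc!r} with pseudo=0; pass counts "
                    "or an explicit pseudo"
                )
            scores.setdefault(bc, []).append(math.log2((f + eps) / (a + eps)))
    return {bc: sum(v) / len(v) for bc, v in scores.items()}


def group_long_reads(parsed: Sequence[ParsedRead]) -> Dict[str, ParsedRead]:
    """Pick one representative read per target barcode.

    Reads flagged invalid (scaffold/length inconsistencies) are dropped.
    The representative has the maximum monomer count; ties broken by most
    edits, then by lexicographically smallest sequence (deterministic).
    """
    best: Dict[str, ParsedRead] = {}
    for p in parsed:
        if not p.valid:
            continue
        cur = best.get(p.target_bc)
        if cur is None:
            best[p.target_bc] = p
            continue
        a = (p.n_monomers_observed, p.n_edits)
        b = (cur.n_monomers_observed, cur.n_edits)
        if a > b or (a == b and p.sequence < cur.sequence):
            best[p.target_bc] = p
    return best
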