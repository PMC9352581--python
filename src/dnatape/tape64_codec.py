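"""Base64-style text codec over 3-nt insertion barcodes.

64 three-mers are assigned to a 31-character alphabet (A-Z, four
punctuation marks and whitespace) with two- or four-fold redundancy.  A
message is split into consecutive sets of four characters; within each
transfection epoch the four corresponding plasmids are mixed at a 7:5:3:1
ratio so that within-set order is carried by relative abundance, while
between-set order is carried by the sequential tape itself.

Decoding clusters the bigram profile of whitelisted barcodes into
co-transfected sets (complete-linkage, Euclidean), orders the sets with the
bigram swap decoder, orders barcodes within each set by efficiency-corrected
unigram counts, and maps barcodes back to characters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from dnatape.tape_parse import ParsedRead, barcode_whitelist
from dnatape.event_order import (
    BigramMatrix,
    EventOrder,
    bigram_counts,
    initial_order,
    refine_order,
    site_unigrams,
)

__all__ = [
    "ALPHABET",
    "EncodingTable",
    "MessagePlan",
    "build_table",
    "encode_message",
    "decode_message",
    "score_reconstruction",
]

# 26 letters and 4 punctuation marks at 2-fold redundancy, whitespace at
# 4-fold: 26*2 + 4*2 + 4 = 64 codes.
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_SYMBOLS = ".,!?"
ALPHABET = _LETTERS + _SYMBOLS + " "
_REDUNDANCY = {c: 2 for c in _LETTERS + _SYMBOLS}
_REDUNDANCY[" "] = 4

SET_WEIGHTS = (7.0, 5.0, 3.0, 1.0)


@dataclass(frozen=True)
class EncodingTable:
    """Character <-> barcode map with redundancy."""

    char_to_codes: Dict[str, Tuple[str, ...]]
    code_to_char: Dict[str, str]

    def __post_init__(self) -> None:
        codes = [c for v in self.char_to_codes.values() for c in v]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate barcode in encoding table")
        if len(codes) != 64:
            raise ValueError(f"table must assign all 64 3-mers, got {len(codes)}")
        if any(len(c) != 3 for c in codes):
            raise ValueError("all barcodes must be 3-mers")
        for ch, cs in self.char_to_codes.items():
            for c in cs:
                if self.code_to_char.get(c) != ch:
                    raise ValueError("inverse map inconsistent with forward map")

    def codes(self, char: str) -> Tuple[str, ...]:
        try:
            return self.char_to_codes[char]
        except KeyError:
            raise KeyError(f"character {char!r} not in alphabet") from None


def build_table(
    explicit: Optional[Mapping[str, Sequence[str]]] = None,
) -> EncodingTable:
    """Build the deterministic default table, or wrap an explicit assignment.

    The default assigns the 64 3-mers in lexicographic (A<C<G<T) order to
    the alphabet in order, each character consuming its redundancy quota.
    An explicit character -> barcode-list map (e.g. a published assignment)
    is validated and used as-is.
    """
    if explicit is not None:
        fwd = {ch: tuple(codes) for ch, codes in explicit.items()}
    else:
        pool = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        it = iter(pool)
        fwd = {
            ch: tuple(itertools.islice(it, _REDUNDANCY[ch])) for ch in ALPHABET
        }
    inv = {c: ch for ch, cs in fwd.items() for c in cs}
    return EncodingTable(char_to_codes=fwd, code_to_char=inv)


@dataclass(frozen=True)
class MessagePlan:
    """Per-epoch barcode mixtures encoding a message."""

    epochs: Tuple[Tuple[Tuple[str, float], ...], ...]
    text: str

    def to_programme(self, per_epoch_edit_prob: float = 0.1):
        from dnatape.tape_sim import ProgrammeSpec

        return ProgrammeSpec(self.epochs, per_epoch_edit_prob)


def encode_message(text: str, table: EncodingTable) -> MessagePlan:
    """Split ``text`` into sets of four characters mixed at 7:5:3:1.

    Repeated characters cycle round-robin through their redundant codes; a
    character repeated beyond its redundancy reuses codes, which loses the
    extra occurrences by design.
    """
    bad = sorted({c for c in text if c not in table.char_to_codes})
    if bad:
        raise ValueError(f"unsupported characters: {bad}")
    usage: Dict[str, int] = {}
    epochs: List[Tuple[Tuple[str, float], ...]] = []
    for i in range(0, len(text), 4):
        chunk = text[i : i + 4]
        epoch = []
        for ch, w in zip(chunk, SET_WEIGHTS):
            codes = table.codes(ch)
            k = usage.get(ch, 0)
            usage[ch] = k + 1
            epoch.append((codes[k % len(codes)], w))
        epochs.append(tuple(epoch))
    return MessagePlan(epochs=tuple(epochs), text=text)


def _cut_clusters(Z: np.ndarray, n: int, max_size: int) -> List[List[int]]:
    """Cut a linkage tree so no cluster exceeds ``max_size`` members.

    Equivalent to cutting at the smallest height at which every cluster is
    small enough, then recursively splitting any oversized cluster into its
    two children.
    """
    root = to_tree(Z)
    out: List[List[int]] = []

    def walk(node) -> None:
        if node.count <= max_size or node.is_leaf():
            out.append(sorted(node.pre_order(lambda x: x.id)))
            return
        walk(node.left)
        walk(node.right)

    walk(root)
    return out


def decode_message(
    parsed: Sequence[ParsedRead],
    table: EncodingTable,
    efficiency: Optional[Mapping[str, float]] = None,
    max_set_size: int = 4,
) -> Tuple[str, Dict]:
    """Decode a recorded message from parsed tape reads.

    Pipeline: site-1 whitelist -> pooled bigram matrix -> complete-linkage
    clustering of bigram profiles into co-transfected sets -> between-set
    ordering via the bigram swap decoder -> within-set ordering by
    efficiency-corrected unigram counts -> character mapping.
    """
    eff = dict(efficiency or {})
    valid = [p for p in parsed if p.valid]
    n_sites = max((len(p.pattern) for p in valid), default=0)
    site1_counts: Dict[str, int] = {}
    all_counts: Dict[str, float] = {}
    for p in valid:
        syms = p.site_symbols()
        if syms and syms[0] is not None:
            site1_counts[syms[0]] = site1_counts.get(syms[0], 0) + 1
        for s in syms:
            if s is not None:
                all_counts[s] = all_counts.get(s, 0.0) + 1.0
    # require a 10-fold mean separation before discarding a low cluster, so
    # clean libraries with no error species keep their low-weight codes
    wl = sorted(barcode_whitelist(site1_counts, min_gap=1.0))
    if not wl:
        raise ValueError("empty barcode whitelist; nothing to decode")

    bg = bigram_counts(valid, whitelist=wl)
    n = len(wl)
    if n == 1:
        sets = [[0]]
    else:
        # per-symbol normalized outgoing/incoming profiles: co-transfected
        # symbols share bigram context regardless of their mixing weight
        def _norm_rows(m: np.ndarray) -> np.ndarray:
            s = m.sum(axis=1, keepdims=True)
            return np.divide(m, s, out=np.zeros_like(m, dtype=float), where=s > 0)

        profile = np.hstack(
            [_norm_rows(bg.counts.astype(float)),
             _norm_rows(bg.counts.T.astype(float))]
        )
        Z = linkage(profile, method="complete", metric="euclidean")
        sets = _cut_clusters(Z, n, max_set_size)

    # order barcodes with the swap decoder, then place each set at its
    # members' mean position in that barcode-level order
    unis = site_unigrams(valid, n_sites, whitelist=wl)
    site1_freqs = {bc: unis[0].get(bc, 0.0) for bc in wl}
    barcode_order = refine_order(initial_order(site1_freqs), bg)
    rank = {bc: i for i, bc in enumerate(barcode_order.order)}
    set_keys = [
        (min(rank[wl[k]] for k in s), sum(rank[wl[k]] for k in s) / len(s))
        for s in sets
    ]
    set_order = sorted(range(len(sets)), key=lambda i: set_keys[i])

    corrected = {
        bc: all_counts.get(bc, 0.0) / 2.0 ** float(eff.get(bc, 0.0)) for bc in wl
    }
    ordered_codes: List[str] = []
    for si in set_order:
        members = [wl[k] for k in sets[si]]
        members.sort(key=lambda bc: (-corrected[bc], bc))
        ordered_codes.extend(members)
    text = "".join(table.code_to_char.get(bc, "?") for bc in ordered_codes)
    diagnostics = {
        "whitelist": wl,
        "sets": [[wl[k] for k in s] for s in sets],
        "set_order": set_order,
        "barcode_order": list(barcode_order.order),
        "converged": barcode_order.converged,
        "corrected_counts": corrected,
        "ordered_codes": ordered_codes,
    }
    return text, diagnostics


def score_reconstruction(
    decoded: str, truth: str
) -> Tuple[int, int, int, int]:
    """(correct, deletions, insertions, transpositions) via optimal alignment.

    Unit-cost substitutions, insertions, deletions and adjacent
    transpositions; among minimal-cost alignments the traceback prefers
    match, then transposition, then deletion, then insertion, then
    substitution.  ``correct`` counts exactly matched, correctly ordered
    characters (a transposed pair contributes none).
    """
    t, d = truth, decoded
    nt, nd = len(t), len(d)
    INF = float("inf")
    cost = [[0.0] * (nd + 1) for _ in range(nt + 1)]
    for i in range(nt + 1):
        cost[i][0] = i
    for j in range(nd + 1):
        cost[0][j] = j
    for i in range(1, nt + 1):
        for j in range(1, nd + 1):
            sub = cost[i - 1][j - 1] + (t[i - 1] != d[j - 1])
            dele = cost[i - 1][j] + 1
            ins = cost[i][j - 1] + 1
            best = min(sub, dele, ins)
            if (
                i > 1
                and j > 1
                and t[i - 1] == d[j - 2]
                and t[i - 2] == d[j - 1]
                and t[i - 1] != t[i - 2]
            ):
                best = min(best, cost[i - 2][j - 2] + 1)
            cost[i][j] = best
    # traceback with deterministic operation preference
    i, j = nt, nd
    correct = deletions = insertions = transpositions = 0
    while i > 0 or j > 0:
        c = cost[i][j]
        if (
            i > 0
            and j > 0
            and t[i - 1] == d[j - 1]
            and cost[i - 1][j - 1] == c
        ):
            correct += 1
            i, j = i - 1, j - 1
        elif (
            i > 1
            and j > 1
            and t[i - 1] == d[j - 2]
            and t[i - 2] == d[j - 1]
            and t[i - 1] != t[i - 2]
            and cost[i - 2][j - 2] + 1 == c
        ):
            transpositions += 1
            i, j = i - 2, j - 2
        elif i > 0 and cost[i - 1][j] + 1 == c:
            deletions += 1
            i -= 1
        elif j > 0 and cost[i][j - 1] + 1 == c:
            insertions += 1
            j -= 1
        else:  # substitution
            i, j = i - 1, j - 1
    return correct, deletions, insertions, transpositions
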