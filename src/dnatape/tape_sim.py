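"""Generative models of sequential tape editing.

A *tape* is a tandem array of identical DNA monomers in which only the
5'-most uncompleted site is writable.  Each write deposits a short barcode
followed by a constant key at the junction 3' of the active monomer, which
deactivates the current site and activates the next one, so edits always
occupy a strict prefix of the sites.

This module provides the canonical rendering of a tape state to DNA, single
array programme simulation (epoch-wise transfections), a clonal-expansion
simulator that returns the true genealogy alongside per-cell records, a
substitution-noise model for reads, and exact state-space arithmetic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from skbio import TreeNode

_DNA = frozenset("ACGT")

__all__ = [
    "TapeConfig",
    "TapeState",
    "ProgrammeSpec",
    "CloneSimParams",
    "CellRecord",
    "TapeExhaustedError",
    "render_tape",
    "step_edit",
    "simulate_programme",
    "simulate_clone",
    "add_read_noise",
    "state_space_log10",
    "state_space_log10_bound",
    "default_symbols",
    "symbol_weights",
]


class TapeExhaustedError(RuntimeError):
    """Raised when a write is attempted on a tape with no free sites."""


def _check_dna(seq: str, what: str) -> None:
    if not seq or not set(seq) <= _DNA:
        raise ValueError(f"{what} must be non-empty uppercase DNA, got {seq!r}")


@dataclass(frozen=True)
class TapeConfig:
    """Constants defining one tape chemistry.

    Parameters
    ----------
    monomer : str
        Repeated unit of the array (default: the 14-nt unit used throughout).
    key : str
        Constant 3' suffix of every insertion; completes the next monomer's
        target.  2-4 nt.
    barcode_len : int
        Length of the variable (symbol-identifying) part of each insertion.
    n_sites : int
        Number of writable sites (monomers) on the array.
    name : str
        Free-text label.
    """

    monomer: str = "TGATGGTGAGCACG"
    key: str = "GGA"
    barcode_len: int = 2
    n_sites: int = 5
    name: str = "tape"

    def __post_init__(self) -> None:
        _check_dna(self.monomer, "monomer")
        _check_dna(self.key, "key")
        if not 2 <= len(self.key) <= 4:
            raise ValueError("key must be 2-4 nt")
        if not 2 <= self.barcode_len <= 6:
            raise ValueError("barcode_len must be in [2, 6]")
        if len(self.monomer) < len(self.key) + 3:
            raise ValueError("monomer must be at least key length + 3")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def insert_len(self) -> int:
        return self.barcode_len + len(self.key)


@dataclass(frozen=True)
class TapeState:
    """Ordered insertions on one array plus a reference to its chemistry.

    Invariant: edits occupy a strict prefix of sites, so the state is fully
    described by the ordered list of insertion barcodes.
    """

    config: TapeConfig
    inserts: Tuple[str, ...] = ()
    target_bc: str = ""

    def __post_init__(self) -> None:
        if len(self.inserts) > self.config.n_sites:
            raise ValueError("more inserts than sites")
        for bc in self.inserts:
            if len(bc) != self.config.barcode_len:
                raise ValueError(
                    f"barcode {bc!r} has length {len(bc)}, "
                    f"expected {self.config.barcode_len}"
                )
            _check_dna(bc, "insert barcode")
        if self.target_bc:
            _check_dna(self.target_bc, "target_bc")

    @property
    def n_edits(self) -> int:
        return len(self.inserts)

    @property
    def exhausted(self) -> bool:
        return len(self.inserts) >= self.config.n_sites


def render_tape(state: TapeState, config: Optional[TapeConfig] = None) -> str:
    """Render a tape state to its exact DNA sequence.

    Layout: ``target_bc + key + monomer`` then, for each edited site *i*,
    ``insert_i + key`` at the junction following monomer *i*, with the
    remaining unedited monomers back to back.  Total length is
    ``|target_bc| + |key| + n_sites*|monomer| + n_edits*(barcode_len+|key|)``.
    """
    cfg = config or state.config
    if cfg.barcode_len != state.config.barcode_len:
        raise ValueError("config incompatible with state")
    parts = [state.target_bc, cfg.key]
    for i in range(cfg.n_sites):
        parts.append(cfg.monomer)
        if i < len(state.inserts):
            parts.append(state.inserts[i] + cfg.key)
    return "".join(parts)


def step_edit(state: TapeState, barcode: str) -> TapeState:
    """Append ``barcode`` at the next free site; earlier sites are never touched."""
    if len(barcode) != state.config.barcode_len:
        raise ValueError(
            f"barcode {barcode!r} has wrong length for this tape "
            f"(expected {state.config.barcode_len})"
        )
    if state.exhausted:
        raise TapeExhaustedError(
            f"tape exhausted: all {state.config.n_sites} sites written"
        )
    return replace(state, inserts=state.inserts + (barcode,))


@dataclass(frozen=True)
class ProgrammeSpec:
    """An ordered multi-epoch transfection programme.

    Each epoch is a list of ``(barcode, mix_weight)`` pairs; during an epoch
    a tape gains at most one edit (with probability ``per_epoch_edit_prob``),
    drawn with probability proportional to ``mix_weight * 2**edit_score``.
    """

    epochs: Tuple[Tuple[Tuple[str, float], ...], ...]
    per_epoch_edit_prob: float = 0.1

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("programme must have at least one epoch")
        lens = set()
        for ep in self.epochs:
            if not ep:
                raise ValueError("empty epoch in programme")
            for bc, w in ep:
                _check_dna(bc, "programme barcode")
                lens.add(len(bc))
                if w <= 0:
                    raise ValueError("mix weights must be positive")
        if len(lens) != 1:
            raise ValueError("all programme barcodes must share one length")
        if not 0.0 <= self.per_epoch_edit_prob <= 1.0:
            raise ValueError("per_epoch_edit_prob must be in [0, 1]")

    @classmethod
    def from_lists(
        cls,
        epochs: Sequence[Sequence[Tuple[str, float]]],
        per_epoch_edit_prob: float = 0.1,
    ) -> "ProgrammeSpec":
        return cls(
            tuple(tuple((bc, float(w)) for bc, w in ep) for ep in epochs),
            per_epoch_edit_prob,
        )

    @property
    def barcode_len(self) -> int:
        return len(self.epochs[0][0][0])


def symbol_weights(
    pairs: Sequence[Tuple[str, float]], efficiency: Mapping[str, float]
) -> np.ndarray:
    """Normalized draw probabilities: mix_weight * 2**edit_score."""
    w = np.array([mw * 2.0 ** float(efficiency.get(bc, 0.0)) for bc, mw in pairs])
    return w / w.sum()


def simulate_programme(
    prog: ProgrammeSpec,
    config: TapeConfig,
    n_tapes: int,
    efficiency: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[TapeState]:
    """Simulate ``n_tapes`` tapes through a multi-epoch programme.

    Per epoch and per non-exhausted tape: with probability
    ``per_epoch_edit_prob`` one barcode is appended, drawn with probability
    proportional to ``mix_weight * 2**edit_score``.  Deterministic under a
    fixed seed.
    """
    if prog.barcode_len != config.barcode_len:
        raise ValueError("programme barcode length incompatible with config")
    eff = dict(efficiency or {})
    rng = rng if rng is not None else np.random.default_rng(seed)
    inserts: List[List[str]] = [[] for _ in range(n_tapes)]
    for epoch in prog.epochs:
        barcodes = [bc for bc, _ in epoch]
        p = symbol_weights(epoch, eff)
        edit = rng.random(n_tapes) < prog.per_epoch_edit_prob
        draws = rng.choice(len(barcodes), size=n_tapes, p=p)
        for i in np.nonzero(edit)[0]:
            if len(inserts[i]) < config.n_sites:
                inserts[i].append(barcodes[draws[i]])
    return [TapeState(config=config, inserts=tuple(ins)) for ins in inserts]


@dataclass(frozen=True)
class CellRecord:
    """One cell's tapes: an ordered insert list per target barcode."""

    cell_id: str
    tapes: Dict[str, Tuple[str, ...]]
    capacities: Dict[str, int]

    @property
    def n_edits(self) -> int:
        return sum(len(v) for v in self.tapes.values())


def default_symbols(n: int = 19, length: int = 3) -> Tuple[str, ...]:
    """First ``n`` barcodes of the canonical lexicographic k-mer enumeration."""
    pool = ("".join(p) for p in itertools.product("ACGT", repeat=length))
    out = tuple(itertools.islice(pool, n))
    if len(out) < n:
        raise ValueError(f"cannot make {n} distinct {length}-mers")
    return out


# Default geometry: nine 5-site tapes, three 4-site tapes and one 2-site tape
# (59 writable sites) with ~2 edits per cell per division over 20 divisions.
DEFAULT_TAPE_SITE_COUNTS: Tuple[int, ...] = (5,) * 9 + (4,) * 3 + (2,)
DEFAULT_EDIT_PROB: float = 0.154  # per tape per division; 13*20*0.154 ~ 40 edits


@dataclass(frozen=True)
class CloneSimParams:
    """Parameters for the clonal-expansion lineage simulation."""

    generations: int = 20
    tape_site_counts: Tuple[int, ...] = DEFAULT_TAPE_SITE_COUNTS
    per_tape_per_division_edit_prob: float = DEFAULT_EDIT_PROB
    symbol_set: Tuple[str, ...] = field(default_factory=lambda: default_symbols(19))
    efficiency: Dict[str, float] = field(default_factory=dict)
    sample_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not self.tape_site_counts:
            raise ValueError("need at least one tape")
        if not 0.0 <= self.per_tape_per_division_edit_prob <= 1.0:
            raise ValueError("edit probability must be in [0, 1]")
        if self.sample_size > 2**self.generations:
            raise ValueError(
                f"sample_size {self.sample_size} exceeds "
                f"{2**self.generations} leaves"
            )

    @property
    def total_sites(self) -> int:
        return sum(self.tape_site_counts)


def _random_target_bcs(n: int, rng: np.random.Generator) -> List[str]:
    seen: set = set()
    out: List[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(list("ACGT"), size=8))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_clone(params: CloneSimParams) -> Tuple[TreeNode, List[CellRecord]]:
    """Simulate a clonal expansion and return (true genealogy, sampled cells).

    A founder with all-unedited tapes divides for ``generations`` rounds; at
    each division each daughter independently gains, per non-exhausted tape,
    one edit with probability ``per_tape_per_division_edit_prob``, the symbol
    drawn proportionally to ``2**edit_score``.  ``sample_size`` leaves are
    drawn uniformly without replacement and returned with the induced true
    subtree (branch lengths in divisions).  Edits are simulated only along
    the sampled lineages, which is statistically identical to simulating the
    full exponential pedigree.
    """
    rng = np.random.default_rng(params.seed)
    n_tapes = len(params.tape_site_counts)
    target_bcs = _random_target_bcs(n_tapes, rng)
    capacities = dict(zip(target_bcs, params.tape_site_counts))
    symbols = list(params.symbol_set)
    psym = symbol_weights([(s, 1.0) for s in symbols], params.efficiency)
    p_edit = params.per_tape_per_division_edit_prob
    G = params.generations

    n_leaves = 2**G
    if params.sample_size == n_leaves:
        leaf_ids = np.arange(n_leaves)
    else:
        leaf_ids = np.sort(rng.choice(n_leaves, params.sample_size, replace=False))
    # leaf index bits, MSB first, give the division path from the founder
    paths = [format(int(i), f"0{G}b") if G else "" for i in leaf_ids]
    width = max(5, len(str(max(leaf_ids, default=0))))
    names = {p: f"cell_{int(i):0{width}d}" for p, i in zip(paths, leaf_ids)}

    def evolve(tapes: List[List[str]], divisions: int) -> List[List[str]]:
        tapes = [list(t) for t in tapes]
        for _ in range(divisions):
            for t, cap in zip(tapes, params.tape_site_counts):
                if len(t) < cap and rng.random() < p_edit:
                    t.append(symbols[rng.choice(len(symbols), p=psym)])
        return tapes

    records: List[CellRecord] = []

    def build(
        prefix: str, group: List[str], tapes: List[List[str]], length: int
    ) -> TreeNode:
        # extend along the unary chain while only one subtree is occupied
        while len(prefix) < G:
            left = [p for p in group if p[len(prefix)] == "0"]
            right = [p for p in group if p[len(prefix)] == "1"]
            if left and right:
                node = TreeNode(length=float(length))
                for bit, sub in (("0", left), ("1", right)):
                    child_tapes = evolve(tapes, 1)
                    node.append(build(prefix + bit, sub, child_tapes, 1))
                return node
            prefix += group[0][len(prefix)]
            tapes = evolve(tapes, 1)
            length += 1
        name = names[prefix]
        records.append(
            CellRecord(
                cell_id=name,
                tapes={bc: tuple(t) for bc, t in zip(target_bcs, tapes)},
                capacities=capacities,
            )
        )
        return TreeNode(name=name, length=float(length))

    founder = [[] for _ in range(n_tapes)]
    root = build("", paths, founder, 0)
    records.sort(key=lambda r: r.cell_id)
    return root, records


def add_read_noise(
    seq: str, sub_rate: float, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Per-base independent substitution to a uniformly drawn *different* base."""
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    if not seq:
        return seq
    rng = rng if rng is not None else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < sub_rate
    if hit.any():
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(bases), arr[hit])
        # shift by 1..3 within the 4-letter alphabet: always a different base
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = np.sort(bases)[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def state_space_log10(site_counts: Sequence[int], n_symbols: int) -> float:
    """log10 of the number of joint states under strictly sequential editing.

    Each tape with ``m`` sites can hold any of ``sum_{k=0}^{m} n_symbols**k``
    ordered edit prefixes; tapes are independent, so counts multiply.
    """
    if n_symbols < 1:
        raise ValueError("n_symbols must be >= 1")
    total = 1
    for m in site_counts:
        if m < 0:
            raise ValueError("site counts must be >= 0")
        total *= sum(n_symbols**k for k in range(m + 1))
    return math.log10(total)


def state_space_log10_bound(site_counts: Sequence[int], n_symbols: int) -> float:
    """Simple bound: log10(n_symbols ** total_sites)."""
    if n_symbols < 1:
        raise ValueError("n_symbols must be >= 1")
    return sum(site_counts) * math.log10(n_symbols)
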