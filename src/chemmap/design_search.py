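"""Constrained search for minimal-2'-F modification patterns.

Given a fitted positional map, the predicted activity difference between two
patterns is the sum of the signed per-position coefficients over the
positions where they differ (the model is additive with no positional
interactions).  The design problem formalized here: minimize the total 2'-F
count subject to (i) a cap on the predicted activity loss vs a parent
pattern, (ii) positions pinned to 2'-F or 2'-OMe (e.g. the critical AS2,
AS6, AS14, S11), and (iii) pairs of positions required to share a chemistry
(e.g. the AS8/AS9 pair, where matched F/F or OMe/OMe pairs outperform the
mixed state).

Searches are exhaustive up to a configurable number of free position blocks
(default 22, ~4M candidates) and fall back to a documented greedy otherwise,
flagged non-exhaustive in the output.

Patterns here are mappings ``(strand, position) -> "F"|"OMe"`` with strand
``"S"`` or ``"AS"``; helpers convert to/from the fixed-size
:class:`~chemmap.strands.ChemistryPattern`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

from .strands import ANTISENSE_LENGTH, SENSE_LENGTH, ChemistryPattern

__all__ = [
    "Position",
    "DesignConstraints",
    "DesignProposal",
    "InfeasibleConstraintsError",
    "coefficients_from_map",
    "pattern_to_positions",
    "positions_to_pattern",
    "predict_delta_ln",
    "propose_variants",
]

Position = Tuple[str, int]

#: default exhaustive-search cap on free blocks (2^22 ~ 4M candidates)
EXHAUSTIVE_LIMIT = 22


class InfeasibleConstraintsError(ValueError):
    """Constraint set admits no pattern; carries the list of conflicts."""

    def __init__(self, conflicts):
        self.conflicts = list(conflicts)
        super().__init__("infeasible constraints: " + "; ".join(self.conflicts))


def pattern_to_positions(pattern: ChemistryPattern) -> Dict[Position, str]:
    """Flatten a duplex chemistry pattern into a position->chemistry dict."""
    out = {("S", i + 1): c for i, c in enumerate(pattern.sense_chem)}
    out.update({("AS", i + 1): c for i, c in enumerate(pattern.antisense_chem)})
    return out


def positions_to_pattern(positions: Mapping[Position, str]) -> ChemistryPattern:
    """Assemble a full 21/23 duplex pattern from a position dict."""
    sense = tuple(positions[("S", i)] for i in range(1, SENSE_LENGTH + 1))
    anti = tuple(positions[("AS", i)] for i in range(1, ANTISENSE_LENGTH + 1))
    return ChemistryPattern(sense, anti)


def coefficients_from_map(positional_map: pd.DataFrame) -> Dict[Position, float]:
    """Extract estimable coefficients from a positional-map table.

    Accepts the DataFrame produced by
    :func:`chemmap.positional.extract_positional_map` (columns ``strand,
    position, delta_ln, estimable``).
    """
    strand_code = {"sense": "S", "antisense": "AS", "S": "S", "AS": "AS"}
    out = {}
    for _, row in positional_map.iterrows():
        if "estimable" in positional_map.columns and not row["estimable"]:
            continue
        out[(strand_code[str(row["strand"])], int(row["position"]))] = float(
            row["delta_ln"]
        )
    return out


def _as_positions(pattern) -> Dict[Position, str]:
    if isinstance(pattern, ChemistryPattern):
        return pattern_to_positions(pattern)
    return dict(pattern)


def predict_delta_ln(pattern, coefficients: Mapping[Position, float], reference) -> float:
    """Predicted ln-difference in fraction remaining of ``pattern`` vs ``reference``.

    Sum over positions where the two differ of +coefficient where the
    pattern has 2'-F and the reference 2'-OMe, and -coefficient for the
    reverse.  Negative output predicts better silencing than the reference.
    Raises if a differing position lacks an (estimable) coefficient.
    """
    pat = _as_positions(pattern)
    ref = _as_positions(reference)
    if set(pat) != set(ref):
        raise ValueError("pattern and reference cover different position sets")
    total = 0.0
    for pos, chem in pat.items():
        rchem = ref[pos]
        if chem == rchem:
            continue
        if pos not in coefficients:
            raise ValueError(
                f"position {pos[0]}{pos[1]} differs from the reference but has "
                "no estimable coefficient"
            )
        total += coefficients[pos] if chem == "F" else -coefficients[pos]
    return total


@dataclass(frozen=True)
class DesignConstraints:
    """Positional constraints for the minimal-2'-F search.

    ``paired`` holds groups of positions required to share a chemistry; the
    default pairs AS8 with AS9.
    """

    fixed_F: frozenset = frozenset()
    fixed_OMe: frozenset = frozenset()
    paired: tuple = (frozenset({("AS", 8), ("AS", 9)}),)

    def __post_init__(self):
        object.__setattr__(self, "fixed_F", frozenset(self.fixed_F))
        object.__setattr__(self, "fixed_OMe", frozenset(self.fixed_OMe))
        object.__setattr__(
            self, "paired", tuple(frozenset(p) for p in self.paired)
        )

    def validate(self, positions: Iterable[Position]) -> None:
        posset = set(positions)
        conflicts = []
        overlap = self.fixed_F & self.fixed_OMe
        for pos in sorted(overlap):
            conflicts.append(f"{pos[0]}{pos[1]} fixed to both F and OMe")
        for group in self.paired:
            if group & self.fixed_F and group & self.fixed_OMe:
                names = "/".join(f"{s}{p}" for s, p in sorted(group))
                conflicts.append(f"pair {names} spans fixed-F and fixed-OMe positions")
        for pos in sorted(self.fixed_F | self.fixed_OMe | set().union(*self.paired, set())):
            if pos not in posset:
                conflicts.append(f"constrained position {pos[0]}{pos[1]} not on the duplex")
        if conflicts:
            raise InfeasibleConstraintsError(conflicts)

    def satisfied_by(self, pattern: Mapping[Position, str]) -> bool:
        pat = _as_positions(pattern)
        for pos in self.fixed_F:
            if pat[pos] != "F":
                return False
        for pos in self.fixed_OMe:
            if pat[pos] != "OMe":
                return False
        for group in self.paired:
            if len({pat[pos] for pos in group}) > 1:
                return False
        return True


@dataclass(frozen=True)
class DesignProposal:
    """One ranked pattern from the search."""

    positions: dict
    n_F_total: int
    predicted_delta_ln: float
    rank: int
    exhaustive: bool

    @property
    def pattern(self) -> ChemistryPattern:
        """Full duplex pattern (only for standard 21/23 position sets)."""
        return positions_to_pattern(self.positions)

    def chem_key(self) -> str:
        return "".join(
            "F" if self.positions[pos] == "F" else "M" for pos in sorted(self.positions)
        )


def _build_blocks(positions, constraints):
    """Union-find the free positions into blocks sharing one chemistry.

    Pair groups touching a fixed position force their members to that
    chemistry.  Returns (forced: dict pos->chem, blocks: list of tuples of
    positions).
    """
    forced = {}
    for pos in constraints.fixed_F:
        forced[pos] = "F"
    for pos in constraints.fixed_OMe:
        forced[pos] = "OMe"

    parent = {pos: pos for pos in positions}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for group in constraints.paired:
        members = sorted(group)
        for other in members[1:]:
            union(members[0], other)

    # propagate forcing through pair groups
    changed = True
    while changed:
        changed = False
        for group in constraints.paired:
            chems = {forced[p] for p in group if p in forced}
            if len(chems) == 1:
                chem = next(iter(chems))
                for p in group:
                    if p not in forced:
                        forced[p] = chem
                        changed = True

    blocks = {}
    for pos in positions:
        if pos in forced:
            continue
        blocks.setdefault(find(pos), []).append(pos)
    return forced, [tuple(sorted(b)) for b in sorted(blocks.values())]


def propose_variants(
    coefficients: Mapping[Position, float],
    constraints: DesignConstraints,
    parent,
    max_predicted_loss: float = 0.1,
    top_k: int = 20,
    mode: str = "auto",
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> list:
    """Minimal-2'-F patterns under an activity-loss budget.

    Minimizes the total 2'-F count subject to
    ``predict_delta_ln(pattern, parent) <= max_predicted_loss`` and the
    constraints.  Ties in 2'-F count break by better predicted activity,
    then lexicographic pattern order (F before OMe).  ``mode`` is ``auto``
    (exhaustive up to ``exhaustive_limit`` free blocks), ``exhaustive`` or
    ``greedy``; greedy results carry ``exhaustive=False``.

    Positions without an estimable coefficient can only match the parent
    chemistry (they are treated as fixed to it).
    """
    if max_predicted_loss < 0:
        raise ValueError("max_predicted_loss must be non-negative")
    par = _as_positions(parent)
    positions = sorted(par)
    constraints.validate(positions)

    # positions with no coefficient cannot deviate from the parent
    extra_fixed_F = {p for p in positions if p not in coefficients and par[p] == "F"}
    extra_fixed_OMe = {p for p in positions if p not in coefficients and par[p] == "OMe"}
    eff = DesignConstraints(
        fixed_F=constraints.fixed_F | extra_fixed_F,
        fixed_OMe=constraints.fixed_OMe | extra_fixed_OMe,
        paired=constraints.paired,
    )
    eff.validate(positions)
    forced, blocks = _build_blocks(positions, eff)

    base = {pos: forced.get(pos, par[pos]) for pos in positions}
    # contribution of assigning each block F vs OMe, relative to parent
    cF = []
    cM = []
    for b in blocks:
        f_contrib = sum(coefficients[p] for p in b if par[p] == "OMe")
        m_contrib = sum(-coefficients[p] for p in b if par[p] == "F")
        cF.append(f_contrib)
        cM.append(m_contrib)
    cF = np.asarray(cF)
    cM = np.asarray(cM)
    sizes = np.asarray([len(b) for b in blocks], dtype=int)

    fixed_delta = sum(
        (coefficients[p] if base[p] == "F" else -coefficients[p])
        for p in positions
        if p in forced and base[p] != par[p]
    )
    n_forced_F = sum(1 for p in positions if p in forced and forced[p] == "F")

    k = len(blocks)
    use_exhaustive = mode == "exhaustive" or (mode == "auto" and k <= exhaustive_limit)
    if mode not in ("auto", "exhaustive", "greedy"):
        raise ValueError("mode must be 'auto', 'exhaustive' or 'greedy'")

    proposals = []
    if use_exhaustive:
        codes = np.arange(1 << k, dtype=np.int64)
        if k:
            bits = ((codes[:, None] >> np.arange(k)) & 1).astype(np.int8)
            delta = fixed_delta + bits @ cF + (1 - bits) @ cM
            n_f = n_forced_F + bits @ sizes
        else:
            bits = np.zeros((1, 0), dtype=np.int8)
            delta = np.array([fixed_delta])
            n_f = np.array([n_forced_F])
        feasible = delta <= max_predicted_loss + 1e-12
        if not feasible.any():
            return []
        idx = np.flatnonzero(feasible)
        order = idx[np.lexsort((delta[idx], n_f[idx]))]
        # exact tie-break needs pattern strings; only materialize a slice
        slice_n = min(len(order), max(top_k * 64, 256))
        cand = []
        for i in order[:slice_n]:
            pat = dict(base)
            for j in range(k):
                chem = "F" if bits[i, j] else "OMe"
                for pos in blocks[j]:
                    pat[pos] = chem
            cand.append((int(n_f[i]), float(delta[i]), pat))
        cand.sort(key=lambda t: (t[0], t[1], _lex_key(t[2])))
        chosen = cand[:top_k]
        exhaustive_flag = True
    else:
        chosen = _greedy_search(
            base, blocks, cF, cM, sizes, fixed_delta, n_forced_F,
            par, coefficients, max_predicted_loss, top_k,
        )
        exhaustive_flag = False

    out = []
    for rank, (n_f, d, pat) in enumerate(chosen, start=1):
        if not eff.satisfied_by(pat):  # defensive: every output is re-checked
            raise AssertionError("proposal violates constraints")
        out.append(
            DesignProposal(
                positions=pat,
                n_F_total=n_f,
                predicted_delta_ln=d,
                rank=rank,
                exhaustive=exhaustive_flag,
            )
        )
    return out


def _lex_key(pat):
    return "".join("F" if pat[pos] == "F" else "M" for pos in sorted(pat))


def _greedy_search(base, blocks, cF, cM, sizes, fixed_delta, n_forced_F,
                   par, coefficients, max_loss, top_k):
    """Iteratively demote the least-harmful 2'-F block to 2'-OMe.

    Start from the parent chemistry (constraint-adjusted); while the loss
    budget allows, flip the F block whose conversion yields the lowest
    resulting predicted delta.  Feasible intermediate states are collected
    and ranked like the exhaustive output.
    """
    k = len(blocks)
    state = np.array([1 if par[b[0]] == "F" else 0 for b in blocks], dtype=np.int8)
    # a block is F iff all parent members F? use majority of parent chems
    for j, b in enumerate(blocks):
        n_f = sum(1 for p in b if par[p] == "F")
        state[j] = 1 if n_f * 2 >= len(b) else 0

    def tot_delta(st):
        return fixed_delta + float(st @ cF + (1 - st) @ cM)

    def tot_nf(st):
        return n_forced_F + int(st @ sizes)

    seen = []
    if tot_delta(state) <= max_loss + 1e-12:
        seen.append((tot_nf(state), tot_delta(state), _materialize(base, blocks, state)))
    while True:
        best = None
        for j in range(k):
            if state[j] != 1:
                continue
            trial = state.copy()
            trial[j] = 0
            d = tot_delta(trial)
            if d <= max_loss + 1e-12:
                key = (d, -sizes[j])
                if best is None or key < best[0]:
                    best = (key, j)
        if best is None:
            break
        state[best[1]] = 0
        seen.append((tot_nf(state), tot_delta(state), _materialize(base, blocks, state)))
    seen.sort(key=lambda t: (t[0], t[1], _lex_key(t[2])))
    return seen[:top_k]


def _materialize(base, blocks, state):
    pat = dict(base)
    for j, b in enumerate(blocks):
        chem = "F" if state[j] else "OMe"
        for pos in b:
            pat[pos] = chem
    return pat
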