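"""Pairwise-titration screen design.

A screen over N ligands comprises N single-ligand gradients, N "self-pairs"
(a ligand paired with itself, the saturated-additivity control), and all
C(N,2) distinct pairs -- 65 rows for 10 ligands.  Each row holds a zero-dose
control plus ``n_ratios`` dose pairs sweeping the ligand ratio while keeping
at least one ligand at its saturating (top) concentration, so interactions
are probed where they are strongest.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

__all__ = ["LigandPanel", "ConditionRow", "ratio_concentrations", "enumerate_design"]


@dataclass
class LigandPanel:
    """Ordered ligand identifiers with per-ligand top dose and dilution fold."""

    ligands: list[str]
    top: dict[str, float]
    dilution: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ligands)) != len(self.ligands):
            raise ValueError("ligand identifiers must be unique")
        for lig in self.ligands:
            t = self.top.get(lig)
            if t is None or t <= 0:
                raise ValueError(f"top concentration for {lig} must be positive")
            f = self.dilution.setdefault(lig, 2.0)
            if f <= 1:
                raise ValueError(f"dilution fold for {lig} must exceed 1")


@dataclass
class ConditionRow:
    """One screen row: kind, ligands, and the dose pair at each ratio index.

    ``doses[0]`` is the zero-dose control; ``doses[r]`` for r = 1..R are the
    (dose_a, dose_b) pairs of the sweep.  Gradients carry ligand_b = None and
    dose_b = 0 throughout.
    """

    kind: str  # gradient | self_pair | pair
    ligand_a: str
    ligand_b: str | None
    doses: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind not in ("gradient", "self_pair", "pair"):
            raise ValueError(f"unknown row kind {self.kind!r}")
        if self.kind == "gradient" and self.ligand_b is not None:
            raise ValueError("gradient rows have no second ligand")
        if self.kind == "self_pair" and self.ligand_a != self.ligand_b:
            raise ValueError("self_pair rows must pair a ligand with itself")
        if self.kind == "pair" and self.ligand_a == self.ligand_b:
            raise ValueError("pair rows need two distinct ligands")
        if self.doses[0] != (0.0, 0.0):
            raise ValueError("ratio index 0 must be the zero-dose control")
        if any(da < 0 or db < 0 for da, db in self.doses):
            raise ValueError("doses must be nonnegative")

    @property
    def n_ratios(self) -> int:
        return len(self.doses) - 1

    @property
    def label(self) -> str:
        if self.kind == "gradient":
            return self.ligand_a
        return f"{self.ligand_a}+{self.ligand_b}"


def _ladder(top: float, fold: float, steps: int) -> list[float]:
    """Geometric dilution ladder [top/fold**(steps-1), ..., top/fold, top]."""
    return [top / fold ** (steps - 1 - i) for i in range(steps)]


def ratio_concentrations(
    topA: float,
    topB: float,
    n_ratios: int,
    foldA: float = 2.0,
    floor: float = 1.0,
) -> list[tuple[float, float]]:
    """Trapezoid ratio sweep from A-dominant to B-dominant.

    For n ratios with m = ceil(n/2): positions 1..m hold A at ``topA`` while
    B climbs a geometric ladder from 0 up to ``topB``; positions m..n hold B
    at ``topB`` while A steps down the mirrored ladder to 0.  The center
    position holds both ligands at their top dose, and every position keeps
    max(dA/topA, dB/topB) >= ``floor`` (default 1: at least one ligand at
    saturation), as required for a ratio sweep probing saturated responses.

    ``foldA`` sets the dilution fold for both ladders (the scheme is
    symmetric under A <-> B by construction).
    """
    if n_ratios < 1:
        raise ValueError("n_ratios must be >= 1")
    if topA <= 0 or topB <= 0:
        raise ValueError("top doses must be positive")
    if n_ratios == 1:
        return [(topA, topB)]
    m = math.ceil(n_ratios / 2)
    # B ladder for positions 1..m: 0, then geometric climb to topB
    up = [0.0] + _ladder(topB, foldA, m - 1)
    pairs = [(topA, b) for b in up]
    # positions m+1..n: mirror; A steps down geometrically then to 0
    down = [topA / foldA**t for t in range(1, n_ratios - m)]
    pairs += [(a, topB) for a in down] + [(0.0, topB)]
    assert len(pairs) == n_ratios
    assert all(max(da / topA, db / topB) >= min(floor, 1.0) for da, db in pairs)
    return pairs


def enumerate_design(panel: LigandPanel, n_ratios: int = 9) -> list[ConditionRow]:
    """All rows of the screen: N gradients, N self-pairs, C(N,2) pairs.

    Row order is deterministic: gradients in panel order, then self-pairs,
    then pairs in lexicographic panel order.  Gradient rows reuse the ligand's
    own dilution ladder (top dose at the last ratio index) so that every dose
    appearing on the saturated flank of a pair row has a matching
    single-ligand measurement.
    """
    if not panel.ligands:
        raise ValueError("panel must contain at least one ligand")
    if n_ratios < 1:
        raise ValueError("n_ratios must be >= 1")
    rows: list[ConditionRow] = []
    control = (0.0, 0.0)
    for lig in panel.ligands:
        grad = _ladder(panel.top[lig], panel.dilution[lig], n_ratios)
        rows.append(
            ConditionRow("gradient", lig, None, [control] + [(d, 0.0) for d in grad])
        )
    for lig in panel.ligands:
        sweep = ratio_concentrations(
            panel.top[lig], panel.top[lig], n_ratios, foldA=panel.dilution[lig]
        )
        rows.append(ConditionRow("self_pair", lig, lig, [control] + sweep))
    for la, lb in itertools.combinations(panel.ligands, 2):
        sweep = ratio_concentrations(
            panel.top[la], panel.top[lb], n_ratios, foldA=panel.dilution[la]
        )
        rows.append(ConditionRow("pair", la, lb, [control] + sweep))
    return rows
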