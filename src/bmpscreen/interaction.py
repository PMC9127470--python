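"""The Interaction Coefficient (IC): a linear scale for pairwise ligand responses.

Drug-synergy scores (Loewe, Bliss) presume an additive null that does not
hold for two ligands feeding the same saturable pathway, where the
non-interacting expectation ranges from the stronger individual response
(full saturation) to the sum of the individual responses (linear regime).
The IC instead places the combined response f(A+B) relative to three
references -- the weaker individual response f(A), the stronger f(B), and
their sum -- and normalizes within each regime:

    IC = f(A+B) / (f(A)+f(B))          if f(A+B) >= f(A)+f(B)   (>= 1, synergy at >1)
    IC = f(A+B) / f(B) - 1             if f(A) <= f(A+B) < f(A)+f(B)
    IC = f(A+B) / f(A) - 2             if f(A+B) < f(A)          (suppressive, in [-2,-1))

with f(B) >= f(A) >= 0 enforced by relabeling.  IC = 0 is saturated
additivity (f(A+B) = f(B)), the null for a ligand paired with itself at
saturation; (0, 1] is additive; [-1, 0) antagonistic; < -1 suppressive;
> 1 synergistic.  The scale is dimensionless and invariant to a global
rescaling of the responses.

Because each response is sampled by only a few biological replicates, a
nonzero IC is only *reported* when the replicate ranges supporting the
claim are disjoint by more than a noise threshold theta (the context's
maximum background-subtracted signal / 30, ~3% of dynamic range); claims of
synergy or suppression require the stricter reference (the replicate-paired
sums, or f(A)) to separate as well, otherwise the value falls back to the
best-supported regime.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "InteractionConfig",
    "PairResponse",
    "InteractionRecord",
    "interaction_coefficient",
    "categorize",
    "gated_ic",
    "noise_threshold",
    "summarize_pair",
    "interaction_table",
]


class Category(str, enum.Enum):
    SUPPRESSIVE = "suppressive"
    ANTAGONISTIC = "antagonistic"
    SATURATED_ADDITIVE = "saturated_additive"
    ADDITIVE = "additive"
    SYNERGISTIC = "synergistic"


@dataclass
class InteractionConfig:
    """Gating threshold and classification knobs.

    theta: minimum gap between replicate ranges for a nonzero IC claim
        (response units; computed per context by :func:`noise_threshold`).
    strong_split: |IC| at which antagonism is called strong rather than weak.
    overrides: optional mapping (context, ligand_a, ligand_b) -> override dict
        with keys among {"category", "ic", "ratio_index"}.
    """

    theta: float = 0.0
    strong_split: float = 0.5
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")


@dataclass
class PairResponse:
    """Replicate responses for one ligand pair at one concentration ratio."""

    fA: np.ndarray  # weaker individual ligand, replicate values
    fB: np.ndarray  # stronger individual ligand
    fAB: np.ndarray  # combination
    ratio_index: int = 0
    context: str = ""

    def __post_init__(self) -> None:
        self.fA = np.atleast_1d(np.asarray(self.fA, dtype=float))
        self.fB = np.atleast_1d(np.asarray(self.fB, dtype=float))
        self.fAB = np.atleast_1d(np.asarray(self.fAB, dtype=float))
        # enforce the weaker/stronger ordering on clipped medians
        if _med(self.fB) < _med(self.fA):
            self.fA, self.fB = self.fB, self.fA


@dataclass
class InteractionRecord:
    ligand_a: str
    ligand_b: str
    context: str
    per_ratio_ic: list[float]
    summary_ic: float
    category: Category
    override: bool = False
    summary_ratio_index: int | None = None


def _med(x: np.ndarray) -> float:
    return float(max(np.median(x), 0.0))


def interaction_coefficient(fA: float, fB: float, fAB: float) -> tuple[float, str]:
    """Evaluate the piecewise IC on median responses.

    Inputs are clipped to zero; the weaker/stronger labeling is internal, so
    the result is symmetric in (fA, fB).  Returns ``(IC, regime)`` where the
    regime is the category name of the branch.  The fully degenerate case
    fA = fB = 0 (no signal anywhere) is defined as IC = 0, regime
    "degenerate".
    """
    fA, fB, fAB = max(fA, 0.0), max(fB, 0.0), max(fAB, 0.0)
    if fB < fA:
        fA, fB = fB, fA
    if fA == 0.0 and fB == 0.0:
        return 0.0, "degenerate"
    if fAB >= fA + fB:
        ic = fAB / (fA + fB)
    elif fAB < fA:
        ic = fAB / fA - 2.0
    else:
        ic = fAB / fB - 1.0
    return float(ic), categorize(ic).value


def categorize(ic: float) -> Category:
    """Map an IC value to its interaction category."""
    if ic < -1.0:
        return Category.SUPPRESSIVE
    if ic < 0.0:
        return Category.ANTAGONISTIC
    if ic == 0.0:
        return Category.SATURATED_ADDITIVE
    if ic <= 1.0:
        return Category.ADDITIVE
    return Category.SYNERGISTIC


def _range_gap(x: np.ndarray, y: np.ndarray) -> float:
    """Gap between the ranges of two replicate sets; negative if overlapping."""
    return float(max(np.min(y) - np.max(x), np.min(x) - np.max(y)))


def gated_ic(pr: PairResponse, cfg: InteractionConfig) -> tuple[float, bool]:
    """IC at one ratio after replicate-noise gating.

    Returns ``(ic, warn)``.  A nonzero IC requires the f(A+B) replicate range
    to be disjoint from the f(B) range with gap > theta.  A synergy claim
    additionally requires separation from the replicate-paired sums
    f(A)+f(B); a suppression claim requires separation from f(A).  When only
    the weaker claim is supported the IC is recomputed in the supported
    regime.  With fewer than two replicates in any set gating is impossible
    and the result is 0 with a warning flag.
    """
    if min(pr.fA.size, pr.fB.size, pr.fAB.size) < 2:
        return 0.0, True
    mA, mB, mAB = _med(pr.fA), _med(pr.fB), _med(pr.fAB)
    ic, regime = interaction_coefficient(mA, mB, mAB)
    if ic == 0.0:
        return 0.0, False
    theta = cfg.theta
    if _range_gap(pr.fAB, pr.fB) <= theta:
        return 0.0, False  # cannot distinguish from the saturated-additive null
    if ic > 1.0:
        n = min(pr.fA.size, pr.fB.size)
        sums = np.sort(pr.fA)[:n] + np.sort(pr.fB)[:n]
        if _range_gap(pr.fAB, sums) <= theta:
            # synergy unsupported: report the additive-regime boundary
            return 1.0, False
        return ic, False
    if ic < -1.0:
        if _range_gap(pr.fAB, pr.fA) <= theta:
            # suppression unsupported: report the antagonistic boundary
            return -1.0, False
        return ic, False
    return ic, False


def noise_threshold(values) -> float:
    """Noise gate theta for one context: max background-subtracted signal / 30."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty response table")
    return float(max(arr.max(), 0.0) / 30.0)


def summarize_pair(
    gated: list[float],
    cfg: InteractionConfig,
    ligand_a: str = "A",
    ligand_b: str = "B",
    context: str = "",
) -> InteractionRecord:
    """Summarize one pair by its largest-magnitude gated IC across ratios.

    Ties in |IC| break toward the ratio nearest the center of the sweep
    (closest to 1:1), then toward the negative value.  Manual overrides, when
    present for (context, pair), replace the automatic summary.
    """
    if len(gated) == 0:
        raise ValueError("summarize_pair requires at least one ratio")
    gated = [float(g) for g in gated]
    center = (len(gated) - 1) / 2.0
    best = max(
        range(len(gated)),
        key=lambda i: (abs(gated[i]), -abs(i - center), -np.sign(gated[i])),
    )
    summary = gated[best]
    record = InteractionRecord(
        ligand_a=ligand_a,
        ligand_b=ligand_b,
        context=context,
        per_ratio_ic=gated,
        summary_ic=summary,
        category=categorize(summary),
        summary_ratio_index=best + 1,
    )
    key = (context, *sorted((ligand_a, ligand_b)))
    ov = cfg.overrides.get(key)
    if ov is not None:
        record.override = True
        if "ratio_index" in ov:
            idx = int(ov["ratio_index"]) - 1
            record.summary_ic = gated[idx]
            record.summary_ratio_index = idx + 1
            record.category = categorize(record.summary_ic)
        if "ic" in ov:
            record.summary_ic = float(ov["ic"])
            record.category = categorize(record.summary_ic)
        if "category" in ov:
            record.category = Category(ov["category"])
    return record


def interaction_table(
    processed: pd.DataFrame,
    cfg: InteractionConfig | None = None,
    value_col: str = "response",
) -> pd.DataFrame:
    """Compute gated per-ratio and summary ICs for every pair in one context.

    ``processed`` is a harmonized long table with columns row_kind, ligand_a,
    ligand_b, ratio_index, replicate_id and ``value_col``; gradient rows
    supply the individual-ligand references at matching ratio position.  The
    individual reference for a pair (A, B) at ratio r uses each ligand's
    single-ligand response at the dose it carries at ratio r, which the
    trapezoid design pins at the gradient's top dose on the saturated side.

    Returns a tidy table with one row per (pair, ratio) plus summary columns.
    """
    cfg = cfg or InteractionConfig()
    if "context_id" in processed.columns and processed["context_id"].nunique() > 1:
        raise ValueError("interaction_table processes one context at a time")
    context = str(processed["context_id"].iloc[0]) if "context_id" in processed.columns else ""
    theta = cfg.theta
    if theta == 0.0:
        theta = noise_threshold(processed[value_col])
        cfg = InteractionConfig(theta=theta, strong_split=cfg.strong_split, overrides=cfg.overrides)

    # single-ligand replicate sets keyed by (ligand, dose)
    grads = processed[processed["row_kind"] == "gradient"]
    singles: dict[tuple[str, float], np.ndarray] = {}
    for (lig, dose), grp in grads.groupby(["ligand_a", "conc_a"]):
        singles[(lig, round(float(dose), 9))] = grp[value_col].to_numpy()

    def single(lig: str, dose: float) -> np.ndarray | None:
        if dose <= 0:
            return np.zeros(2)
        return singles.get((lig, round(float(dose), 9)))

    out_rows = []
    pairs = processed[processed["row_kind"].isin(["pair", "self_pair"])]
    for (la, lb), grp in pairs.groupby(["ligand_a", "ligand_b"]):
        pair_rows = []
        for r in sorted(r for r in grp["ratio_index"].unique() if r > 0):
            sub = grp[grp["ratio_index"] == r]
            da, db = float(sub["conc_a"].iloc[0]), float(sub["conc_b"].iloc[0])
            fab = sub[value_col].to_numpy()
            fa, fb = single(la, da), single(lb, db)
            if fa is None or fb is None:
                raise ValueError(
                    f"missing single-ligand reference for pair ({la}, {lb}) at ratio {r}"
                )
            pr = PairResponse(fA=fa, fB=fb, fAB=fab, ratio_index=r, context=context)
            ic, warn = gated_ic(pr, cfg)
            raw_ic, _ = interaction_coefficient(_med(fa), _med(fb), _med(fab))
            pair_rows.append(
                dict(
                    context_id=context, ligand_a=la, ligand_b=lb, ratio_index=r,
                    ic_raw=raw_ic, ic_gated=ic, gating_warning=warn,
                )
            )
        rec = summarize_pair([row["ic_gated"] for row in pair_rows], cfg, la, lb, context)
        for row in pair_rows:
            row["summary_ic"] = rec.summary_ic
            row["category"] = rec.category.value
            row["override_flag"] = rec.override
        out_rows.extend(pair_rows)
    return pd.DataFrame(out_rows)
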