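"""Turn raw well tables into harmonized, background-subtracted responses.

The corrective steps mirror the screen's known nuisance structure in
reverse order of how it was imposed:

1. drop wells with too few cells to trust the median (default < 500);
2. subtract the per-plate background (median of the plate's zero-dose
   control wells) -- reporter autofluorescence is additive;
3. rescale every plate to a reference plate by the single multiplicative
   factor that minimizes total least-squares error over the technical
   replicate conditions the plates share -- plate incubation times differ,
   producing a fold change in accumulated fluorescence;
4. rescale every biological replicate to a reference replicate the same
   way, over all shared conditions.

Negative post-subtraction values are retained unclipped through rescaling
(clipping would bias the least-squares factors) and only clipped at the
point the interaction coefficient is computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_and_subtract",
    "rescale_plates",
    "rescale_replicates",
    "preprocess",
]

_COND_KEYS = ["row_kind", "ligand_a", "ligand_b", "conc_a", "conc_b", "ratio_index"]


def _check_columns(wells: pd.DataFrame) -> None:
    required = {"context_id", "plate_id", "replicate_id", "ratio_index",
                "median_yfp", "cell_count", *_COND_KEYS}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")


def filter_and_subtract(wells: pd.DataFrame, min_cells: int = 500) -> pd.DataFrame:
    """Drop low-count wells and subtract per-plate background.

    Wells with ``cell_count`` strictly below ``min_cells`` are removed (a
    count of exactly ``min_cells`` is retained).  Background is the median
    ``median_yfp`` of the zero-dose control wells on the same
    (context, replicate, plate); a plate whose controls were all dropped is
    an error.  Adds a ``response`` column; raw values are kept.
    """
    if wells.empty:
        raise ValueError("empty well table")
    _check_columns(wells)
    kept = wells[wells["cell_count"] >= min_cells].copy()
    if kept.empty:
        raise ValueError("no wells survive the cell-count filter")
    group = ["context_id", "replicate_id", "plate_id"]
    controls = kept[kept["ratio_index"] == 0]
    bg = controls.groupby(group)["median_yfp"].median().rename("background")
    kept = kept.merge(bg, on=group, how="left")
    missing = kept[kept["background"].isna()]
    if not missing.empty:
        plates = sorted(missing["plate_id"].unique().tolist())
        raise ValueError(f"plates with no surviving zero-dose control wells: {plates}")
    kept["response"] = kept["median_yfp"] - kept["background"]
    sort_keys = ["context_id", "replicate_id", "row_kind", "ligand_a", "ligand_b", "ratio_index"]
    return kept.sort_values(sort_keys, kind="stable").reset_index(drop=True)


def _ls_factor(ref: np.ndarray, other: np.ndarray) -> float:
    """alpha minimizing sum (ref - alpha*other)^2: closed form."""
    denom = float(np.sum(other * other))
    if denom == 0.0:
        raise ValueError("degenerate plate/replicate: all shared values are zero")
    return float(np.sum(ref * other)) / denom


def _shared_means(df: pd.DataFrame, value_col: str) -> pd.Series:
    return df.groupby(_COND_KEYS, dropna=False)[value_col].mean()


def rescale_plates(
    table: pd.DataFrame,
    reference_plate: int | None = None,
    value_col: str = "response",
) -> pd.DataFrame:
    """Linearly rescale each plate to the reference over shared conditions.

    Operates within each (context, replicate).  The reference defaults to
    the plate sharing the most conditions with the others (ties to the
    lowest plate id).  Scale factors are recorded in ``plate_scale``.
    """
    out = []
    for (_ctx, _rep), grp in table.groupby(["context_id", "replicate_id"]):
        plates = sorted(grp["plate_id"].unique())
        conds = {p: _shared_means(grp[grp["plate_id"] == p], value_col) for p in plates}
        if reference_plate is not None:
            ref = reference_plate
        else:
            # plate with most conditions shared with any other plate
            def n_shared(p):
                return sum(
                    len(conds[p].index.intersection(conds[q].index))
                    for q in plates if q != p
                )
            ref = max(plates, key=lambda p: (n_shared(p), -p))
        sub = grp.copy()
        sub["plate_scale"] = 1.0
        for p in plates:
            if p == ref:
                continue
            shared = conds[ref].index.intersection(conds[p].index)
            if len(shared) == 0:
                raise ValueError(f"plate {p} shares no conditions with reference plate {ref}")
            alpha = _ls_factor(conds[ref].loc[shared].to_numpy(),
                               conds[p].loc[shared].to_numpy())
            mask = sub["plate_id"] == p
            sub.loc[mask, value_col] = sub.loc[mask, value_col] * alpha
            sub.loc[mask, "plate_scale"] = alpha
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def rescale_replicates(table: pd.DataFrame, reference_replicate: int | None = None,
                       value_col: str = "response") -> pd.DataFrame:
    """Rescale each biological replicate to the reference by one factor.

    The factor for replicate r minimizes total least-squares error between
    the reference's and r's values over all shared conditions (per-condition
    means within replicate).  Per-replicate values are retained, not
    averaged.  Factors are recorded in ``replicate_scale``.
    """
    out = []
    for _ctx, grp in table.groupby("context_id"):
        reps = sorted(grp["replicate_id"].unique())
        if len(reps) < 2:
            sub = grp.copy()
            sub["replicate_scale"] = 1.0
            out.append(sub)
            continue
        conds = {r: _shared_means(grp[grp["replicate_id"] == r], value_col) for r in reps}
        if reference_replicate is not None:
            ref = reference_replicate
        else:
            def n_shared(r):
                return sum(
                    len(conds[r].index.intersection(conds[q].index))
                    for q in reps if q != r
                )
            ref = max(reps, key=lambda r: (n_shared(r), -r))
        sub = grp.copy()
        sub["replicate_scale"] = 1.0
        for r in reps:
            if r == ref:
                continue
            shared = conds[ref].index.intersection(conds[r].index)
            if len(shared) == 0:
                raise ValueError(f"replicate {r} shares no conditions with reference {ref}")
            alpha = _ls_factor(conds[ref].loc[shared].to_numpy(),
                               conds[r].loc[shared].to_numpy())
            mask = sub["replicate_id"] == r
            sub.loc[mask, value_col] = sub.loc[mask, value_col] * alpha
            sub.loc[mask, "replicate_scale"] = alpha
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def preprocess(wells: pd.DataFrame, min_cells: int = 500) -> pd.DataFrame:
    """Full preprocessing chain: filter, subtract, plate- and replicate-rescale."""
    return rescale_replicates(rescale_plates(filter_and_subtract(wells, min_cells)))
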