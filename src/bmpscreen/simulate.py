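"""Synthetic screen generator.

Emulates the pairwise-titration screen: ground-truth responses come from the
competitive equilibrium model, measurement noise follows the corrective
steps the pipeline implements in reverse -- a multiplicative per-plate
factor (plates incubate for slightly different times, and reporter
fluorescence accumulates roughly linearly in time), a multiplicative
per-biological-replicate factor, per-well multiplicative lognormal noise,
and an additive autofluorescence background.  Wells also carry simulated
cell counts so the low-count filter has something to drop.

Rows are assigned to plates round-robin, six rows per plate (11 plates for a
65-row screen).  Every plate additionally carries technical-replicate wells
of one shared reference condition, which is what makes the per-plate
rescaling identifiable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bmpscreen.design import LigandPanel, enumerate_design
from bmpscreen.equilibrium import ModelParams, ReceptorContext, solve_equilibrium_batch

__all__ = ["NoiseModel", "generate_dataset", "example_panel", "planted_truth",
           "fit_truth"]

ROWS_PER_PLATE = 6


@dataclass
class NoiseModel:
    """Noise and nuisance-factor settings for the generator.

    Defaults emulate the screen's conditions: plate incubation times of
    20-24 h around a 22 h nominal give a roughly +/-10% linear fold change in
    accumulated fluorescence; biological replicates vary a further ~20%;
    per-well noise has a 5% CV; background sits near 30 a.u.; typical wells
    hold a few thousand cells with ~2% of wells falling below the 500-cell
    filter.  The gain maps model output (order 1-30) onto the reporter's
    arbitrary-unit scale so that, as in real data, autofluorescence
    background is a sub-percent fraction of the dynamic range.
    """

    plate_factor_range: tuple[float, float] = (0.9, 1.1)
    replicate_factor_range: tuple[float, float] = (0.8, 1.2)
    well_cv: float = 0.05
    background_level: float = 30.0
    background_sd: float = 3.0
    gain: float = 300.0
    cell_count_mean: float = 5000.0
    cell_count_sd: float = 1500.0
    low_count_fraction: float = 0.02
    low_count_mean: float = 200.0

    def __post_init__(self) -> None:
        for rng in (self.plate_factor_range, self.replicate_factor_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError("factor ranges must be positive and ordered")
        if self.well_cv < 0:
            raise ValueError("well CV must be nonnegative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """Identity noise: fluorescence equals the ground-truth output."""
        return cls(
            plate_factor_range=(1.0, 1.0),
            replicate_factor_range=(1.0, 1.0),
            well_cv=0.0,
            background_level=0.0,
            background_sd=0.0,
            gain=1.0,
            low_count_fraction=0.0,
        )


def generate_dataset(
    panel: LigandPanel,
    contexts: list[ReceptorContext],
    truth: ModelParams,
    noise: NoiseModel | None = None,
    n_replicates: int = 4,
    n_ratios: int = 9,
    seed: int = 0,
    shuffle_rows: bool = False,
    n_tech_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full synthetic well table plus its ground-truth ledger.

    Returns ``(wells, ledger)``.  ``wells`` is the tidy measurement table
    (one row per well); ``ledger`` records the noiseless model output and
    every drawn nuisance factor, so any downstream result can be checked
    against truth.  Identical arguments and seed reproduce both tables
    bit-for-bit.  ``shuffle_rows`` randomizes the row-to-plate assignment
    independently per biological replicate (as the real screen randomized
    row order between repeats); analysis results must not depend on it.
    """
    noise = noise or NoiseModel()
    missing = [l for l in panel.ligands if l not in truth.ligands]
    if missing:
        raise ValueError(f"truth params missing panel ligands: {missing}")
    rows = enumerate_design(panel, n_ratios=n_ratios)
    rng = np.random.default_rng(seed)
    n_plates = (len(rows) + ROWS_PER_PLATE - 1) // ROWS_PER_PLATE

    # shared reference condition duplicated on every plate: the first
    # ligand's gradient at its top dose
    ref_ligand = panel.ligands[0]
    ref_dose = panel.top[ref_ligand]

    lig_index = {l: i for i, l in enumerate(truth.ligands)}

    well_recs: list[dict] = []
    ledger_recs: list[dict] = []
    for ctx in contexts:
        A0, B0 = ctx.totals()
        # noiseless S for every (row, ratio) once per context
        env_rows = []
        env_keys = []
        for ri, row in enumerate(rows):
            for q, (da, db) in enumerate(row.doses):
                L = np.zeros(len(truth.ligands))
                L[lig_index[row.ligand_a]] += da
                if row.ligand_b is not None:
                    L[lig_index[row.ligand_b]] += db
                env_rows.append(L)
                env_keys.append((ri, q))
        _, _, _, S_all, _ = solve_equilibrium_batch(truth, np.array(env_rows), A0, B0)
        S_map = dict(zip(env_keys, S_all))
        L_ref = np.zeros(len(truth.ligands))
        L_ref[lig_index[ref_ligand]] = ref_dose
        _, _, _, S_ref, _ = solve_equilibrium_batch(truth, L_ref[None], A0, B0)
        S_ref = float(S_ref[0])

        for rep in range(1, n_replicates + 1):
            rep_factor = rng.uniform(*noise.replicate_factor_range)
            plate_factors = rng.uniform(*noise.plate_factor_range, size=n_plates)
            order = rng.permutation(len(rows)) if shuffle_rows else np.arange(len(rows))
            plate_of = {int(order[i]): i // ROWS_PER_PLATE for i in range(len(rows))}
            for ri, row in enumerate(rows):
                plate = plate_of[ri]
                for q, (da, db) in enumerate(row.doses):
                    _emit(
                        well_recs, ledger_recs, noise, rng, ctx.name, plate, row,
                        ri, q, da, db, S_map[(ri, q)], rep_factor,
                        plate_factors[plate], rep, shared_ref=False,
                    )
            # shared technical-replicate wells on every plate (reference
            # condition and no-ligand control, in triplicate): these are what
            # identify the per-plate rescaling factor downstream
            ref_row = rows[panel.ligands.index(ref_ligand)]
            for plate in range(n_plates):
                for _tech in range(n_tech_reps):
                    _emit(
                        well_recs, ledger_recs, noise, rng, ctx.name, plate, ref_row,
                        panel.ligands.index(ref_ligand), n_ratios, ref_dose, 0.0,
                        S_ref, rep_factor, plate_factors[plate], rep, shared_ref=True,
                    )
                    _emit(
                        well_recs, ledger_recs, noise, rng, ctx.name, plate, ref_row,
                        panel.ligands.index(ref_ligand), 0, 0.0, 0.0,
                        0.0, rep_factor, plate_factors[plate], rep, shared_ref=True,
                    )
    wells = pd.DataFrame(well_recs)
    ledger = pd.DataFrame(ledger_recs)
    ledger.attrs["seed"] = seed
    return wells, ledger


def _emit(
    well_recs, ledger_recs, noise, rng, ctx_name, plate, row, row_index, q,
    da, db, S, rep_factor, plate_factor, rep, shared_ref,
):
    background = max(rng.normal(noise.background_level, noise.background_sd), 0.0) \
        if noise.background_sd > 0 else noise.background_level
    mult = rng.lognormal(mean=0.0, sigma=noise.well_cv) if noise.well_cv > 0 else 1.0
    yfp = plate_factor * rep_factor * (noise.gain * S + background) * mult
    if noise.low_count_fraction > 0 and rng.uniform() < noise.low_count_fraction:
        count = max(int(rng.normal(noise.low_count_mean, noise.low_count_mean / 4)), 0)
    else:
        count = max(int(rng.normal(noise.cell_count_mean, noise.cell_count_sd)), 0)
    well_recs.append(
        dict(
            context_id=ctx_name, plate_id=plate, row_kind=row.kind,
            ligand_a=row.ligand_a, ligand_b=row.ligand_b if row.ligand_b else "",
            conc_a=da, conc_b=db, ratio_index=q, replicate_id=rep,
            median_yfp=yfp, cell_count=count,
            row_index=row_index, shared_ref=shared_ref,
        )
    )
    ledger_recs.append(
        dict(
            context_id=ctx_name, plate_id=plate, row_index=row_index,
            ratio_index=q, replicate_id=rep, shared_ref=shared_ref,
            S_true=S, plate_factor=plate_factor, replicate_factor=rep_factor,
            background=background, well_noise=mult,
        )
    )


def example_panel(n: int = 10) -> LigandPanel:
    """A 10-ligand panel named after the homodimeric BMP family members.

    Top doses span the sub-ug/mL range typical of recombinant BMP assays;
    dilution folds are modest so the gradient covers the responsive range.
    """
    names = ["BMP2", "BMP4", "BMP5", "BMP6", "BMP7",
             "BMP9", "BMP10", "GDF5", "GDF6", "GDF7"][:n]
    top = {l: 100.0 for l in names}
    fold = {l: 3.0 for l in names}
    return LigandPanel(names, top, fold)


def planted_truth(panel: LigandPanel | None = None) -> tuple[ModelParams, list[ReceptorContext]]:
    """Ground-truth parameters with a planted interaction structure.

    Built on two Type I (I1, I2) and two Type II (II1, II2) receptors.  The
    planted structure covers every interaction category the screen is
    designed to detect:

    * a block of strong, mutually saturated-additive activators
      (BMP2/4/5/6/7 analogs, all signaling through I1/II1);
    * synergy: the BMP9 analog is mostly sequestered in an inactive I2/II1
      sink; any ligand that grabs II1 (the strong group, and especially the
      GDF5/GDF7 analogs) empties the sink and releases BMP9 into its active
      I2/II2 complex, so the combination exceeds the summed responses;
    * suppression: the BMP10 analog signals weakly through I2/II2, which it
      dominates; combined with BMP9 each ligand deprives the other (BMP10
      displaces BMP9 from I2/II2 while BMP9's sink steals I2), dropping the
      combined response below both individual responses;
    * antagonism: non-activating GDF5/GDF7 outcompete the strong group for
      I1/II1; GDF6 binds too weakly to interfere with anything.

    Returns the parameter set and two receptor contexts (a wild-type and an
    I2 knockdown) over the same receptor panel.
    """
    panel = panel or example_panel()
    ligs = panel.ligands
    type1, type2 = ["I1", "I2"], ["II1", "II2"]
    K = np.zeros((len(ligs), 2, 2))
    eps = np.zeros_like(K)

    def set_(lig, j, k, Kv, ev):
        if lig in ligs:
            i = ligs.index(lig)
            K[i, j, k] = Kv
            eps[i, j, k] = ev

    # strong additive activators, all through I1/II1 with equal activity:
    # mutually saturated-additive, one planted equivalence group
    for lig in ("BMP2", "BMP4", "BMP5", "BMP6", "BMP7"):
        set_(lig, 0, 0, 5.0, 8.0)
    # BMP9 analog: mostly held in an inactive I2/II1 sink; weak active I2/II2
    set_("BMP9", 1, 0, 5.0, 0.0)
    set_("BMP9", 1, 1, 0.02, 60.0)
    # BMP10 analog: dominates the I2/II2 complex but signals weakly through it,
    # so BMP9's sink steals I2 from it and the pair is mutually suppressive;
    # a trace of silent I1/II1 binding reflects the family's promiscuity and
    # keeps its combination with the strong group genuinely sub-linear
    set_("BMP10", 1, 1, 100.0, 3.0)
    set_("BMP10", 0, 0, 0.005, 0.0)
    # GDF5/GDF7: non-activators that outcompete the strong group for I1/II1
    # (antagonism) and, by grabbing II1, empty BMP9's sink (synergy);
    # GDF6 binds too weakly to interfere with anything
    set_("GDF5", 0, 0, 30.0, 0.0)
    set_("GDF7", 0, 0, 30.0, 0.0)
    set_("GDF6", 0, 0, 0.001, 0.0)

    params = ModelParams(ligs, type1, type2, K, eps)
    wild_type = ReceptorContext("wild_type", A0=np.array([1.0, 1.0]), B0=np.array([1.0, 1.0]))
    knockdown = ReceptorContext("I2_knockdown", A0=np.array([1.0, 0.05]), B0=np.array([1.0, 1.0]))
    return params, [wild_type, knockdown]


def fit_truth() -> tuple[ModelParams, list[ReceptorContext], LigandPanel]:
    """Five-ligand, five-receptor ground truth for parameter-recovery studies.

    One ligand from each planted behavioral class (a strong activator pair
    BMP4/BMP7, the sink-trapped BMP9 analog, the weakly-signaling
    competitor BMP10, and the non-activating GDF5), over two Type I and
    three Type II receptors.  BMP7 signals through the third Type II
    receptor, so knocking it down separates BMP7 from BMP4.  Returns the
    parameters, four receptor contexts (wild-type plus three knockdowns),
    and a matching panel.
    """
    ligs = ["BMP4", "BMP7", "BMP9", "BMP10", "GDF5"]
    type1, type2 = ["I1", "I2"], ["II1", "II2", "II3"]
    K = np.zeros((5, 2, 3))
    eps = np.zeros_like(K)

    def set_(lig, j, k, Kv, ev):
        i = ligs.index(lig)
        K[i, j, k] = Kv
        eps[i, j, k] = ev

    set_("BMP4", 0, 0, 5.0, 8.0)
    set_("BMP7", 0, 2, 5.0, 8.0)
    set_("BMP9", 1, 0, 5.0, 0.0)
    set_("BMP9", 1, 1, 0.02, 60.0)
    set_("BMP10", 1, 1, 100.0, 3.0)
    set_("GDF5", 0, 0, 30.0, 0.0)

    params = ModelParams(ligs, type1, type2, K, eps)
    contexts = [
        ReceptorContext("wild_type", A0=np.array([1.0, 1.0]), B0=np.array([1.0, 1.0, 1.0])),
        ReceptorContext("I2_knockdown", A0=np.array([1.0, 0.05]), B0=np.array([1.0, 1.0, 1.0])),
        ReceptorContext("II1_knockdown", A0=np.array([1.0, 1.0]), B0=np.array([0.05, 1.0, 1.0])),
        ReceptorContext("II3_knockdown", A0=np.array([1.0, 1.0]), B0=np.array([1.0, 1.0, 0.05])),
    ]
    panel = LigandPanel(ligs, {l: 100.0 for l in ligs}, {l: 3.0 for l in ligs})
    return params, contexts, panel
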