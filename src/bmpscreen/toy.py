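"""A minimal 3-ligand, 2x2-receptor model of signaling-complex redistribution.

Three ligands (pink, blue, gold) compete for two Type I receptors (black_I,
white_I) and two Type II receptors (black_II, white_II).  The parameter set
is constructed so that three qualitative behaviors emerge purely from
competitive redistribution of receptors among complexes of differing
activity:

1. Knocking down the black Type I receptor *decreases* the pink ligand's
   output even though pink signals through a complex that does not contain
   it: the knockdown frees black_II, letting the inactive white_I/black_II
   complex form and sequester white_I away from pink's active
   white_I/white_II complex.
2. Gold suppresses pink in the wild-type context: gold dominates the active
   white_I/white_II complex but signals weakly through it, while pink's
   inactive complexes withhold white_I from gold, so the combination signals
   less than either ligand alone.
3. Pink and blue are interchangeable (saturated additive) in the wild-type
   but antagonistic after the knockdown, because only pink can be trapped in
   the white_I/black_II complex, which then starves blue's active complex.

The numeric values are package constants chosen to realize this structure;
what matters is the topology of strong/weak affinities and active/silent
complexes, not the particular numbers.
"""

from __future__ import annotations

import numpy as np

from bmpscreen.equilibrium import ModelParams, ReceptorContext

__all__ = ["toy_model_factory", "TOY_DOSE"]

TOY_DOSE = 100.0  # saturating dose used in all toy-model environments


def toy_model_factory() -> tuple[ModelParams, dict[str, ReceptorContext], dict[str, dict[str, float]]]:
    """Packaged toy parameters, receptor contexts, and ligand environments.

    Returns ``(params, contexts, environments)`` where contexts are
    ``wild_type`` and ``black_I_knockdown`` and environments cover each
    single ligand plus the pink+gold and pink+blue combinations at the
    saturating dose.
    """
    ligands = ["pink", "blue", "gold"]
    type1 = ["black_I", "white_I"]
    type2 = ["black_II", "white_II"]
    K = np.zeros((3, 2, 2))
    eps = np.zeros((3, 2, 2))

    def set_(lig, t1, t2, Kv, ev):
        i, j, k = ligands.index(lig), type1.index(t1), type2.index(t2)
        K[i, j, k] = Kv
        eps[i, j, k] = ev

    # pink: strong inactive black/black, intermediate inactive white/black,
    # weak active white/white
    set_("pink", "black_I", "black_II", 10.0, 0.0)
    set_("pink", "white_I", "black_II", 10.0, 0.0)
    set_("pink", "white_I", "white_II", 0.01, 100.0)
    # blue mirrors pink but cannot form the white/black trap
    set_("blue", "black_I", "black_II", 10.0, 0.0)
    set_("blue", "white_I", "white_II", 0.01, 100.0)
    # gold: dominates white/white, signals weakly through it
    set_("gold", "white_I", "white_II", 10.0, 2.0)

    params = ModelParams(ligands, type1, type2, K, eps)
    contexts = {
        "wild_type": ReceptorContext("wild_type", A0=[1.0, 1.0], B0=[1.0, 1.0]),
        "black_I_knockdown": ReceptorContext(
            "black_I_knockdown", A0=[0.02, 1.0], B0=[1.0, 1.0]
        ),
    }
    d = TOY_DOSE
    environments = {
        "pink": {"pink": d},
        "blue": {"blue": d},
        "gold": {"gold": d},
        "pink+gold": {"pink": d, "gold": d},
        "pink+blue": {"pink": d, "blue": d},
    }
    return params, contexts, environments
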