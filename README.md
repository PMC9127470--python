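# bmpscreen

Analysis of combinatorial BMP ligand screens: pairwise interaction scoring on
the Interaction Coefficient scale, context-dependent ligand equivalence
groups, and a competitive ligand–receptor equilibrium model that explains
both — with a built-in synthetic screen generator so the whole pipeline runs,
and is tested, without any external data.

## The problem

Bone Morphogenetic Proteins form a family of ~10 homodimeric ligands that all
signal through shared Type I and Type II receptors onto SMAD1/5/8.  Cells see
these ligands in combinations, and the response to a combination is not
predictable from the individual responses: two ligands can be interchangeable
in one cell type and antagonistic in another, purely because receptor
expression differs.  This package is for quantitative biologists who run (or
simulate) pairwise ligand titration screens against reporter cell lines and
want to go from raw per-well measurements to interaction calls, equivalence
groups, and mechanistic model fits.

## The core quantities

**Interaction Coefficient (IC).**  Drug-synergy nulls (Loewe, Bliss) do not
apply to two ligands saturating one pathway, where the non-interacting
expectation ranges from the stronger individual response to the sum of the
two.  The IC places the combined response f(A+B) against three references —
the weaker response f(A), the stronger f(B), and their sum (f(B) ≥ f(A) ≥ 0):

    IC = f(A+B) / (f(A)+f(B))      if f(A+B) ≥ f(A)+f(B)
    IC = f(A+B) / f(B) − 1         if f(A) ≤ f(A+B) < f(A)+f(B)
    IC = f(A+B) / f(A) − 2         if f(A+B) < f(A)

IC = 0 is saturated additivity (the self-pair null), 1 is exact linear
additivity, > 1 synergy, [−1, 0) antagonism, < −1 suppression.  Noisy calls
are gated by replicate-range separation against a per-context threshold
(max signal / 30).

**Equivalence groups.**  Ligands are clustered (complete linkage, cut
strictly below distance 1) on feature vectors of their ICs with every ligand
plus 2×RLS (Relative Ligand Strength), with groups split until every group is
monochromatic — all members share the same interaction category with each
outside ligand.

**Equilibrium model.**  One-step formation of trimeric complexes
T_ijk = K_ijk·L_i·A_j·B_k from conserved receptor pools, with pathway output
S = Σ ε_ijk·T_ijk.  Competition for shared receptors redistributes ligands
and receptors among complexes of different activity, which is the mechanism
behind synergy, suppression, and their context dependence.  The model is
solved by a damped fixed point + batched Newton scheme, checked against a
kinetic-relaxation oracle, and fit to data by bounded multi-start least
squares with qualitative (category-match) solution filtering.

## Worked example

```python
from bmpscreen import interaction_coefficient, solve_equilibrium
from bmpscreen.toy import toy_model_factory

print(interaction_coefficient(300, 700, 1000))   # (1.0, 'additive')
print(interaction_coefficient(400, 800, 200))    # (-1.5, 'suppressive')

params, contexts, envs = toy_model_factory()
for cname in ("wild_type", "black_I_knockdown"):
    for ename in ("pink", "gold", "pink+gold", "blue", "pink+blue"):
        S = solve_equilibrium(params, envs[ename], contexts[cname]).S
        print(f"{cname:20s} {ename:10s} S = {S:8.3f}")
```

```
wild_type            pink       S =   24.536
wild_type            gold       S =    1.938
wild_type            pink+gold  S =    1.895
wild_type            blue       S =   38.197
wild_type            pink+blue  S =   37.716
black_I_knockdown    pink       S =    2.664
black_I_knockdown    gold       S =    1.938
black_I_knockdown    pink+gold  S =    1.059
black_I_knockdown    blue       S =   38.197
black_I_knockdown    pink+blue  S =    4.146
```

Three redistribution behaviors are visible in these numbers.  Knocking down
the black Type I receptor collapses pink's output (24.5 → 2.7) even though
pink signals through a complex that does not contain that receptor — the
knockdown frees black Type II subunits into a silent trap that sequesters the
white Type I receptor pink needs.  Gold suppresses pink in the wild-type: the
combination (1.895) is below *both* individual responses, because gold
displaces pink from its active complex while pink's trap withholds receptors
from gold.  And pink+blue is saturated-additive in the wild-type (37.7 ≈
blue's 38.2, IC ≈ 0) but antagonistic after the knockdown (4.1 falls between
the individual responses, IC ≈ −0.9): equivalence is a property of the
receptor context, not of the ligands alone.

The full pipeline runs from the command line on synthetic data:

```
bmpscreen run --seed 1 --out-dir out \
    --stages simulate,preprocess,doseresponse,interactions,equivalence,toy
```

writing tidy CSV artifacts (wells, harmonized responses, Hill fits and RLS,
gated ICs with categories, equivalence groups, toy-model outputs) plus a
run manifest; identical configuration and seed reproduce identical files.

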