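"""Competitive ligand-receptor equilibrium model of BMP pathway activation.

The model describes one-step assembly of trimeric signaling complexes: a
dimeric ligand ``L_i`` binds one Type I receptor ``A_j`` and one Type II
receptor ``B_k`` with affinity ``K_ijk``, forming a complex ``T_ijk`` that
phosphorylates SMAD1/5/8 with activity ``eps_ijk``.  Ligand is supplied by a
large media reservoir and is held constant; receptors are conserved.  At
binding equilibrium,

    T_ijk = K_ijk * L_i0 * A_j * B_k
    A_j0  = A_j + sum_ik T_ijk
    B_k0  = B_k + sum_ij T_ijk
    S     = sum_ijk eps_ijk * T_ijk

where ``A_j``/``B_k`` are free receptor levels and ``S`` is total pathway
output.  The limited receptor pools couple all complexes: adding one ligand
redistributes every other ligand and receptor among complexes of differing
activity, which is the mechanism behind context-dependent synergy,
antagonism and suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "ReceptorContext",
    "EquilibriumState",
    "solve_equilibrium",
    "solve_equilibrium_batch",
    "steady_state_oracle",
    "complex_output_decomposition",
    "ligand_output_attribution",
]


@dataclass
class ModelParams:
    """Affinities ``K_ijk`` and activities ``eps_ijk`` over all complexes.

    Arrays are indexed ``[ligand, type1, type2]`` in the order of the
    component name lists.
    """

    ligands: list[str]
    type1: list[str]
    type2: list[str]
    K: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.ligands), len(self.type1), len(self.type2))
        self.K = np.asarray(self.K, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.K.shape != shape or self.eps.shape != shape:
            raise ValueError(
                f"K and eps must have shape {shape}; got {self.K.shape} and {self.eps.shape}"
            )
        for name, arr in (("K", self.K), ("eps", self.eps)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (ligand, type1, type2, K, epsilon)."""
        rows = []
        for i, li in enumerate(self.ligands):
            for j, aj in enumerate(self.type1):
                for k, bk in enumerate(self.type2):
                    rows.append((li, aj, bk, self.K[i, j, k], self.eps[i, j, k]))
        return pd.DataFrame(rows, columns=["ligand", "type1", "type2", "K", "epsilon"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModelParams":
        ligands = list(dict.fromkeys(df["ligand"]))
        type1 = list(dict.fromkeys(df["type1"]))
        type2 = list(dict.fromkeys(df["type2"]))
        K = np.zeros((len(ligands), len(type1), len(type2)))
        eps = np.zeros_like(K)
        seen = set()
        for rec in df.itertuples(index=False):
            i, j, k = ligands.index(rec.ligand), type1.index(rec.type1), type2.index(rec.type2)
            K[i, j, k] = rec.K
            eps[i, j, k] = rec.epsilon
            seen.add((rec.ligand, rec.type1, rec.type2))
        for li in ligands:
            for aj in type1:
                for bk in type2:
                    if (li, aj, bk) not in seen:
                        raise ValueError(f"missing parameter entry for ({li}, {aj}, {bk})")
        return cls(ligands, type1, type2, K, eps)


@dataclass
class ReceptorContext:
    """Total receptor expression for one cell context (relative units).

    ``rho1``/``rho2`` are optional per-receptor rescaling factors in
    [1/3, 3] applied multiplicatively to the measured expression, absorbing
    qPCR quantification uncertainty.
    """

    name: str
    A0: np.ndarray
    B0: np.ndarray
    rho1: np.ndarray | None = None
    rho2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A0 = np.asarray(self.A0, dtype=float)
        self.B0 = np.asarray(self.B0, dtype=float)
        if np.any(self.A0 < 0) or np.any(self.B0 < 0):
            raise ValueError("receptor expression must be nonnegative")
        for rho in (self.rho1, self.rho2):
            if rho is not None:
                rho = np.asarray(rho, dtype=float)
                if np.any(rho < 1 / 3 - 1e-12) or np.any(rho > 3 + 1e-12):
                    raise ValueError("rho factors must lie in [1/3, 3]")

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective totals after rho rescaling."""
        a0 = self.A0 if self.rho1 is None else self.A0 * np.asarray(self.rho1, dtype=float)
        b0 = self.B0 if self.rho2 is None else self.B0 * np.asarray(self.rho2, dtype=float)
        return a0, b0


@dataclass
class EquilibriumState:
    """Solved equilibrium: free receptors, complexes, and total output."""

    A: np.ndarray
    B: np.ndarray
    T: np.ndarray
    S: float
    iterations: int = 0
    residual: float = 0.0
    method: str = "fixed_point"
    ligands: list[str] = field(default_factory=list)
    type1: list[str] = field(default_factory=list)
    type2: list[str] = field(default_factory=list)


def _env_vector(params: ModelParams, env: dict[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(env, dict):
        unknown = set(env) - set(params.ligands)
        if unknown:
            raise ValueError(f"environment names ligands absent from params: {sorted(unknown)}")
        L = np.array([float(env.get(l, 0.0)) for l in params.ligands])
    else:
        L = np.asarray(env, dtype=float)
        if L.shape != (len(params.ligands),):
            raise ValueError("ligand vector length mismatch")
    if np.any(L < 0) or not np.all(np.isfinite(L)):
        raise ValueError("ligand concentrations must be finite and nonnegative")
    return L


def solve_equilibrium_batch(
    params: ModelParams,
    L: np.ndarray,
    A0: np.ndarray,
    B0: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Solve many ligand environments against one receptor context at once.

    ``L`` has shape (n_env, n_ligands).  Returns ``(A, B, T, S, iterations)``
    with leading environment axis.  Damped fixed-point iteration on the
    free-receptor update

        a_j <- A_j0 / (1 + sum_ik K_ijk L_i b_k)
        b_k <- B_k0 / (1 + sum_j K_ijk L_i a_j)

    (a monotone contraction for this competitive binding network; damping 0.5
    engages only if the iterates oscillate) takes the solution into the basin
    of a batched Newton iteration on the conservation relations, which then
    converges quadratically.  Environments where Newton misbehaves simply
    continue with the fixed point.  Convergence is declared when the
    conservation residuals fall below ``tol`` relative to the receptor
    totals.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    n_env = L.shape[0]
    K = params.K
    nJ, nK = A0.size, B0.size
    # per-environment coupling matrix C_jk = sum_i K_ijk * L_i
    C = np.einsum("ijk,ei->ejk", K, L)
    a = np.broadcast_to(A0, (n_env, nJ)).copy()
    b = np.broadcast_to(B0, (n_env, nK)).copy()
    scale = max(A0.max(initial=0.0), B0.max(initial=0.0))
    if scale == 0.0:  # no receptors anywhere: trivial solution
        T = np.zeros((n_env,) + K.shape)
        return a, b, T, np.zeros(n_env), 0

    def residual(a, b):
        fa = a * (1.0 + np.einsum("ejk,ek->ej", C, b)) - A0
        fb = b * (1.0 + np.einsum("ejk,ej->ek", C, a)) - B0
        return fa, fb

    def res_norm(a, b):
        fa, fb = residual(a, b)
        return np.maximum(np.max(np.abs(fa), axis=1), np.max(np.abs(fb), axis=1)) / scale

    damping = np.zeros(n_env, dtype=bool)
    prev_delta = np.full(n_env, np.inf)
    it = 0
    warm_tol = 1e-3
    for it in range(1, max_iter + 1):
        a_new = A0 / (1.0 + np.einsum("ejk,ek->ej", C, b))
        b_new = B0 / (1.0 + np.einsum("ejk,ej->ek", C, a_new))
        sc = np.maximum(np.max(np.abs(a_new), axis=1), np.max(np.abs(b_new), axis=1))
        sc = np.where(sc > 0, sc, 1.0)
        delta = np.maximum(
            np.max(np.abs(a_new - a), axis=1), np.max(np.abs(b_new - b), axis=1)
        ) / sc
        damping |= delta > prev_delta  # oscillation heuristic
        w = np.where(damping, 0.5, 1.0)[:, None]
        a = (1 - w) * a + w * a_new
        b = (1 - w) * b + w * b_new
        prev_delta = delta
        if np.all(delta < warm_tol) or it >= 500:
            break

    # batched Newton on F(a, b) = 0
    n = nJ + nK
    upper = np.concatenate([np.broadcast_to(A0, (n_env, nJ)),
                            np.broadcast_to(B0, (n_env, nK))], axis=1)
    newton_ok = True
    for _nit in range(60):
        fa, fb = residual(a, b)
        rn = np.maximum(np.max(np.abs(fa), axis=1), np.max(np.abs(fb), axis=1)) / scale
        if np.all(rn < tol):
            break
        J = np.zeros((n_env, n, n))
        diag_a = 1.0 + np.einsum("ejk,ek->ej", C, b)
        diag_b = 1.0 + np.einsum("ejk,ej->ek", C, a)
        J[:, :nJ, :nJ] = np.eye(nJ) * diag_a[:, :, None]
        J[:, nJ:, nJ:] = np.eye(nK) * diag_b[:, :, None]
        J[:, :nJ, nJ:] = a[:, :, None] * C
        J[:, nJ:, :nJ] = (b[:, :, None] * np.swapaxes(C, 1, 2))
        F = np.concatenate([fa, fb], axis=1)
        try:
            step = np.linalg.solve(J, F[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            newton_ok = False
            break
        x = np.clip(np.concatenate([a, b], axis=1) - step, 0.0, upper)
        a, b = x[:, :nJ], x[:, nJ:]
        it += 1
    else:
        newton_ok = False

    if not newton_ok or np.any(res_norm(a, b) >= tol):
        # pure fixed point to full tolerance for the stragglers
        for it2 in range(1, max_iter + 1):
            a_new = A0 / (1.0 + np.einsum("ejk,ek->ej", C, b))
            b_new = B0 / (1.0 + np.einsum("ejk,ej->ek", C, a_new))
            w = np.where(damping, 0.5, 1.0)[:, None]
            a = (1 - w) * a + w * a_new
            b = (1 - w) * b + w * b_new
            it += 1
            if it2 % 50 == 0 and np.all(res_norm(a, b) < tol):
                break
        else:
            raise RuntimeError(
                f"equilibrium solve did not converge in {max_iter} iterations "
                f"(max conservation residual {res_norm(a, b).max():.3e})"
            )
    T = K[None] * L[:, :, None, None] * a[:, None, :, None] * b[:, None, None, :]
    S = np.einsum("ijk,eijk->e", params.eps, T)
    return a, b, T, S, it


def solve_equilibrium(
    params: ModelParams,
    env: dict[str, float] | np.ndarray,
    ctx: ReceptorContext,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Solve one ligand environment in one receptor context.

    Falls back to a bounded least-squares root find on the conservation
    relations if the fixed point fails to converge.
    """
    L = _env_vector(params, env)
    A0, B0 = ctx.totals()
    try:
        a, b, T, S, it = solve_equilibrium_batch(
            params, L[None], A0, B0, tol=tol, max_iter=max_iter
        )
        a, b, T, S = a[0], b[0], T[0], float(S[0])
        method = "fixed_point"
    except RuntimeError:
        a, b, it = _root_fallback(params, L, A0, B0)
        T = params.K * L[:, None, None] * a[None, :, None] * b[None, None, :]
        S = float(np.einsum("ijk,ijk->", params.eps, T))
        method = "least_squares_root"
    res_a = np.abs(a + T.sum(axis=(0, 2)) - A0)
    res_b = np.abs(b + T.sum(axis=(0, 1)) - B0)
    residual = float(max(res_a.max(initial=0.0), res_b.max(initial=0.0)))
    return EquilibriumState(
        A=a, B=b, T=T, S=S, iterations=it, residual=residual, method=method,
        ligands=list(params.ligands), type1=list(params.type1), type2=list(params.type2),
    )


def _root_fallback(params, L, A0, B0, max_iter: int = 200):
    from scipy.optimize import least_squares

    nJ, nK = A0.size, B0.size

    def resid(x):
        a, b = x[:nJ], x[nJ:]
        T = params.K * L[:, None, None] * a[None, :, None] * b[None, None, :]
        return np.concatenate(
            [a + T.sum(axis=(0, 2)) - A0, b + T.sum(axis=(0, 1)) - B0]
        )

    x0 = np.concatenate([A0, B0]) * 0.5
    sol = least_squares(
        resid, x0, bounds=(np.zeros(nJ + nK), np.concatenate([A0, B0]) + 1e-30),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_iter * (nJ + nK),
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8 * max(A0.max(initial=1), B0.max(initial=1)):
        raise RuntimeError(
            f"equilibrium root fallback failed: status={sol.status}, "
            f"max residual={np.max(np.abs(sol.fun)):.3e}"
        )
    return sol.x[:nJ], sol.x[nJ:], sol.nfev


def steady_state_oracle(
    params: ModelParams,
    env: dict[str, float] | np.ndarray,
    ctx: ReceptorContext,
    koff: float = 1.0,
    tol: float = 1e-10,
    max_time: float = 1e7,
) -> EquilibriumState:
    """Independent check: relax the mass-action kinetics to steady state.

    Integrates ``dT_ijk/dt = koff * (K_ijk L_i0 a_j b_k - T_ijk)`` with free
    receptors obtained from conservation, until the relative change of T over
    a time chunk falls below ``tol``.  Agrees with :func:`solve_equilibrium`
    to ~1e-6 relative; disagreement flags a solver defect.
    """
    from scipy.integrate import solve_ivp

    if koff <= 0:
        raise ValueError("koff must be positive")
    L = _env_vector(params, env)
    A0, B0 = ctx.totals()
    shape = params.K.shape

    def rhs(_t, y):
        T = y.reshape(shape)
        a = np.clip(A0 - T.sum(axis=(0, 2)), 0.0, None)
        b = np.clip(B0 - T.sum(axis=(0, 1)), 0.0, None)
        return (koff * (params.K * L[:, None, None] * a[None, :, None] * b[None, None, :] - T)).ravel()

    T = np.zeros(shape)
    t, chunk = 0.0, 10.0 / koff
    while t < max_time:
        sol = solve_ivp(rhs, (0.0, chunk), T.ravel(), method="LSODA", rtol=1e-12, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"kinetic relaxation failed: {sol.message}")
        T_new = sol.y[:, -1].reshape(shape)
        scale = max(np.max(np.abs(T_new)), 1e-300)
        change = np.max(np.abs(T_new - T)) / scale
        T = T_new
        t += chunk
        if change < tol:
            break
    else:
        raise RuntimeError("kinetic relaxation did not reach steady state")
    a = A0 - T.sum(axis=(0, 2))
    b = B0 - T.sum(axis=(0, 1))
    S = float(np.einsum("ijk,ijk->", params.eps, T))
    res = max(
        np.max(np.abs(a + T.sum(axis=(0, 2)) - A0), initial=0.0),
        np.max(np.abs(b + T.sum(axis=(0, 1)) - B0), initial=0.0),
    )
    return EquilibriumState(
        A=a, B=b, T=T, S=S, iterations=int(t / chunk), residual=float(res),
        method="kinetic_relaxation",
        ligands=list(params.ligands), type1=list(params.type1), type2=list(params.type2),
    )


def complex_output_decomposition(state: EquilibriumState, params: ModelParams) -> pd.DataFrame:
    """Per-complex abundance and output shares plus the cumulative-output curve.

    Complexes are sorted by descending abundance share; ``cumulative_output``
    along that order shows how concentrated the signal is in rare complexes.
    """
    Ttot = state.T.sum()
    rows = []
    for i, li in enumerate(params.ligands):
        for j, aj in enumerate(params.type1):
            for k, bk in enumerate(params.type2):
                out = params.eps[i, j, k] * state.T[i, j, k]
                rows.append((li, aj, bk, state.T[i, j, k], out))
    df = pd.DataFrame(rows, columns=["ligand", "type1", "type2", "T", "output"])
    df["abundance_share"] = df["T"] / Ttot if Ttot > 0 else np.nan
    if state.S > 0:
        df["output_share"] = df["output"] / state.S
        df["output_undefined"] = False
    else:
        df["output_share"] = np.nan
        df["output_undefined"] = True
    df = df.sort_values("abundance_share", ascending=False, kind="stable").reset_index(drop=True)
    df["cumulative_output"] = df["output_share"].cumsum()
    return df


def ligand_output_attribution(
    params: ModelParams,
    envs: dict[str, dict[str, float]],
    ctx: ReceptorContext,
) -> pd.DataFrame:
    """Attribute total output to each ligand and Type I receptor per environment.

    ``envs`` maps an environment label to a ligand-concentration dict.  Output
    attributed to ligand i is ``sum_jk eps_ijk T_ijk``; to Type I receptor j,
    ``sum_ik eps_ijk T_ijk``.
    """
    rows = []
    for label, env in envs.items():
        st = solve_equilibrium(params, env, ctx)
        per_ligand = np.einsum("ijk,ijk->i", params.eps, st.T)
        per_type1 = np.einsum("ijk,ijk->j", params.eps, st.T)
        for li, v in zip(params.ligands, per_ligand):
            rows.append((label, "ligand", li, v, st.S))
        for aj, v in zip(params.type1, per_type1):
            rows.append((label, "type1", aj, v, st.S))
    return pd.DataFrame(rows, columns=["environment", "kind", "component", "output", "total_S"])


def percent_change(individual: float, combined: float) -> float:
    """Percent change of a ligand's attributed output between conditions.

    Undefined (NaN) when the individual output is zero.
    """
    if individual == 0:
        return float("nan")
    return 100.0 * (combined - individual) / individual
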