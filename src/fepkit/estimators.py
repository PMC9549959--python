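"""Free-energy estimation: MBAR, BAR, edge assembly, and convergence series.

MBAR (multistate Bennett acceptance ratio) finds per-state reduced free
energies f_k solving the self-consistent equations

    f_i = -ln sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n)),

which are the stationarity conditions of a convex objective; the
implementation minimizes that objective (L-BFGS, analytic gradient) and
then polishes by self-consistent iteration.  Uncertainties come from the
standard asymptotic covariance of the weight matrix.  BAR is the two-state
special case, solved from forward/reverse work values by root bracketing;
it serves as an independent oracle for MBAR's K=2 limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize as _scipy_minimize
from scipy.special import logsumexp

from .constants import KB_KCAL

__all__ = [
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "EdgeEstimate",
    "mbar_solve",
    "bar_solve",
    "exponential_averaging",
    "assemble_edge",
    "convergence_series",
    "statistical_inefficiency",
    "subsample_matrix",
]


@dataclass
class ReducedPotentialMatrix:
    """u_kn: every sample n evaluated in every state k (dimensionless),
    with N_k samples drawn from state k, sum(N_k) = N, ordered state-major."""

    u_kn: np.ndarray
    N_k: np.ndarray
    temperature: float | None = None

    def __post_init__(self):
        self.u_kn = np.asarray(self.u_kn, float)
        self.N_k = np.asarray(self.N_k, int)
        K, N = self.u_kn.shape
        if K < 2:
            raise ValueError("need at least two states")
        if np.any(self.N_k < 0) or self.N_k.sum() != N:
            raise ValueError("N_k must be >= 0 and sum to the sample count")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    def state_slice(self, k: int) -> slice:
        start = int(self.N_k[:k].sum())
        return slice(start, start + int(self.N_k[k]))


@dataclass
class FreeEnergyResult:
    """Per-state reduced free energies (f[0] = 0) with the end-to-end
    difference and its statistical uncertainty, in units of kT."""

    f_k: np.ndarray
    theta: np.ndarray | None = None
    temperature: float | None = None
    n_iterations: int = 0
    overlap_scalar: float | None = None

    def __post_init__(self):
        self.f_k = np.asarray(self.f_k, float)

    @property
    def delta_f(self) -> float:
        return float(self.f_k[-1] - self.f_k[0])

    @property
    def d_delta_f(self) -> float:
        return self.uncertainty(0, len(self.f_k) - 1)

    def uncertainty(self, i: int, j: int) -> float:
        if self.theta is None:
            return 0.0
        var = self.theta[i, i] + self.theta[j, j] - 2.0 * self.theta[i, j]
        return float(np.sqrt(max(var, 0.0)))

    def delta_f_kcal(self, temperature: float | None = None) -> tuple[float, float]:
        T = temperature if temperature is not None else self.temperature
        if T is None:
            raise ValueError("temperature required for kcal/mol conversion")
        kt = KB_KCAL * T
        return self.delta_f * kt, self.d_delta_f * kt


@dataclass
class EdgeEstimate:
    """One perturbation-network edge: ddG = dG(complex leg) - dG(solvent
    leg), in kcal/mol, with root-sum-square uncertainty."""

    ligand_a: str
    ligand_b: str
    ddg: float
    uncertainty: float = 0.0
    dg_complex: float | None = None
    dg_solvent: float | None = None
    target: str | None = None


def _mbar_weights(u_kn: np.ndarray, N_k: np.ndarray, f_k: np.ndarray):
    """log-denominator and weight matrix W_nk = exp(f_k - u_kn)/D_n."""
    sampled = N_k > 0
    log_num = f_k[:, None] - u_kn  # K x N
    log_D = logsumexp(log_num[sampled] + np.log(N_k[sampled])[:, None], axis=0)
    W = np.exp(log_num - log_D[None, :])  # K x N
    return log_D, W


def mbar_solve(
    matrix: ReducedPotentialMatrix,
    tol: float = 1e-10,
    max_iter: int = 10000,
    overlap_warning_threshold: float = 1e-6,
) -> FreeEnergyResult:
    """Solve the MBAR equations for per-state reduced free energies.

    States with N_k = 0 are evaluated by one-shot reweighting after the
    sampled states converge.  Raises on non-convergence; warns when the
    overlap scalar (1 - second eigenvalue of the overlap matrix) indicates
    a poorly connected ladder.
    """
    u_kn, N_k = matrix.u_kn, matrix.N_k
    K, N = u_kn.shape
    if N == 0:
        raise ValueError("no samples")
    sampled = np.flatnonzero(N_k > 0)
    if len(sampled) == 0:
        raise ValueError("no state contributed samples")
    us = u_kn[sampled]
    Ns = N_k[sampled]
    logNs = np.log(Ns)

    # convex objective over sampled states, gauge f[first sampled] = 0
    def objective(f_free):
        f = np.concatenate([[0.0], f_free])
        log_D = logsumexp(logNs[:, None] + f[:, None] - us, axis=0)
        val = log_D.sum() + float(Ns @ (-f))
        W = np.exp(f[:, None] - us - log_D[None, :])
        grad = (Ns * W.sum(axis=1) - Ns)[1:]
        return val, grad

    f0 = np.zeros(len(sampled) - 1)
    n_iter = 0
    if len(sampled) > 1:
        res = _scipy_minimize(objective, f0, jac=True, method="L-BFGS-B",
                              options={"maxiter": max_iter, "ftol": 1e-16,
                                       "gtol": 1e-12})
        f_s = np.concatenate([[0.0], res.x])
        n_iter = int(res.nit)
    else:
        f_s = np.zeros(1)

    # self-consistent polish on the sampled states
    for it in range(max_iter):
        log_D = logsumexp(logNs[:, None] + f_s[:, None] - us, axis=0)
        f_new = -logsumexp(-us - log_D[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f_s))
        f_s = f_new
        n_iter += 1
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"MBAR did not converge in {max_iter} iterations (residual {delta:.3e})"
        )

    # all states (including unsampled) by one-shot reweighting
    log_D = logsumexp(logNs[:, None] + f_s[:, None] - us, axis=0)
    f_k = -logsumexp(-u_kn - log_D[None, :], axis=1)
    f_k = f_k - f_k[0]

    theta, overlap = _mbar_covariance(u_kn, N_k, f_k)
    if overlap is not None and overlap < overlap_warning_threshold:
        O = _overlap_matrix(u_kn, N_k, f_k)
        sym = O + O.T
        np.fill_diagonal(sym, np.inf)
        i, j = np.unravel_index(np.argmin(sym), sym.shape)
        warnings.warn(
            f"poor phase-space overlap (overlap scalar {overlap:.2e}); "
            f"weakest link between states {i} and {j}",
            RuntimeWarning,
        )
    return FreeEnergyResult(f_k=f_k, theta=theta, temperature=matrix.temperature,
                            n_iterations=n_iter, overlap_scalar=overlap)


def _overlap_matrix(u_kn, N_k, f_k) -> np.ndarray:
    """Row-stochastic overlap matrix O_ij = sum_n W_ni N_j W_nj."""
    _, W = _mbar_weights(u_kn, N_k, f_k)  # K x N
    Wn = W.T  # N x K
    return Wn.T @ (Wn * N_k[None, :].astype(float))


def _mbar_covariance(u_kn, N_k, f_k):
    """Asymptotic covariance of the f_k estimates (SVD form) and the overlap
    scalar 1 - lambda_2 of the overlap matrix restricted to sampled states
    (1 for perfectly overlapping states, 0 for a disconnected ladder)."""
    _, W = _mbar_weights(u_kn, N_k, f_k)
    Wn = W.T  # N x K, columns of sampled states sum to ~1
    try:
        U, S, Vt = np.linalg.svd(Wn, full_matrices=False)
        V = Vt.T
        Ndiag = np.diag(N_k.astype(float))
        inner = np.eye(len(S)) - np.diag(S) @ Vt @ Ndiag @ V @ np.diag(S)
        theta = V @ np.diag(S) @ np.linalg.pinv(inner, rcond=1e-12) @ np.diag(S) @ Vt
    except np.linalg.LinAlgError:
        return None, None
    O = _overlap_matrix(u_kn, N_k, f_k)
    sampled = N_k > 0
    Osub = O[np.ix_(sampled, sampled)]
    if Osub.shape[0] < 2:
        return theta, 1.0
    try:
        # O is similar to a symmetric matrix; its spectrum is real in [0, 1]
        eigs = np.sort(np.linalg.eigvals(Osub).real)[::-1]
        overlap = float(1.0 - eigs[1])
    except np.linalg.LinAlgError:
        overlap = None
    return theta, overlap


def exponential_averaging(delta_u: np.ndarray) -> float:
    """Zwanzig forward estimator: Δf = -ln < exp(-Δu) > over samples of the
    reference state."""
    delta_u = np.asarray(delta_u, float)
    if delta_u.size == 0:
        raise ValueError("no work values")
    return float(-(logsumexp(-delta_u) - np.log(delta_u.size)))


def bar_solve(
    w_forward: np.ndarray,
    w_reverse: np.ndarray,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Bennett acceptance ratio from forward/reverse reduced work values.

    ``w_forward`` holds u_1 - u_0 on samples from state 0; ``w_reverse``
    holds u_0 - u_1 on samples from state 1.  Solves the Bennett implicit
    equation  sum_F fermi(M + w_F - Δf) = sum_R fermi(-M + w_R + Δf)  with
    M = ln(n_F/n_R) and fermi(x) = 1/(1+exp(x)) by bracketing root search;
    returns (Δf, uncertainty).  This is the exact stationarity condition of
    the two-state MBAR problem, so it matches ``mbar_solve`` at K = 2.
    """
    wf = np.asarray(w_forward, float)
    wr = np.asarray(w_reverse, float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both work arrays must be non-empty")
    M = np.log(wf.size / wr.size)

    def fermi(x):
        return 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))

    def g(df):
        return fermi(M + wf - df).sum() - fermi(-M + wr + df).sum()

    lo = min(exponential_averaging(wf), -exponential_averaging(wr)) - 10.0
    hi = max(exponential_averaging(wf), -exponential_averaging(wr)) + 10.0
    for _ in range(200):
        if g(lo) < 0 < g(hi):
            break
        lo -= 50.0
        hi += 50.0
    else:
        raise RuntimeError("could not bracket the BAR root")
    df = brentq(g, lo, hi, xtol=tol)

    ff = fermi(M + wf - df)
    fr = fermi(-M + wr + df)
    var = (np.mean(ff ** 2) / np.mean(ff) ** 2 - 1.0) / wf.size \
        + (np.mean(fr ** 2) / np.mean(fr) ** 2 - 1.0) / wr.size
    return float(df), float(np.sqrt(max(var, 0.0)))


def assemble_edge(
    complex_leg: FreeEnergyResult,
    solvent_leg: FreeEnergyResult,
    temperature: float,
    ligand_a: str = "A",
    ligand_b: str = "B",
) -> EdgeEstimate:
    """Combine the two alchemical legs into a relative binding free energy:
    ddG (kcal/mol) = kT * (Δf_complex − Δf_solvent); uncertainties add in
    quadrature."""
    for leg in (complex_leg, solvent_leg):
        if leg.temperature is not None and abs(leg.temperature - temperature) > 1e-9:
            raise ValueError(
                f"leg temperature {leg.temperature} K != {temperature} K"
            )
    kt = KB_KCAL * temperature
    ddg = (complex_leg.delta_f - solvent_leg.delta_f) * kt
    sigma = np.hypot(complex_leg.d_delta_f, solvent_leg.d_delta_f) * kt
    return EdgeEstimate(ligand_a, ligand_b, float(ddg), float(sigma),
                        dg_complex=complex_leg.delta_f * kt,
                        dg_solvent=solvent_leg.delta_f * kt)


def convergence_series(
    matrix: ReducedPotentialMatrix,
    n_blocks: int = 20,
    block_time: float | None = None,
    sample_interval: float | None = None,
    tol: float = 1e-10,
) -> list[tuple[float, float, float]]:
    """Re-estimate Δf on growing prefixes of the (time-ordered) samples.

    Returns (cumulative time or fraction, delta_f, uncertainty) rows on a
    uniform grid; the final row uses all data.  When ``block_time`` and
    ``sample_interval`` are given (same time unit) the grid spacing is
    block_time, otherwise the data are split into ``n_blocks`` equal blocks
    and the axis is the fraction of data used.
    """
    N_k = matrix.N_k
    n_min = int(N_k[N_k > 0].min())
    if block_time is not None:
        if sample_interval is None or sample_interval <= 0:
            raise ValueError("block_time requires a positive sample_interval")
        per_block = max(int(round(block_time / sample_interval)), 1)
        n_blocks_eff = max(n_min // per_block, 1)
    else:
        per_block = max(n_min // n_blocks, 1)
        n_blocks_eff = max(n_min // per_block, 1)

    rows = []
    for b in range(1, n_blocks_eff + 1):
        n_use = per_block * b if b < n_blocks_eff else n_min
        cols = []
        for k in range(matrix.n_states):
            sl = matrix.state_slice(k)
            take = min(n_use, int(N_k[k]))
            cols.extend(range(sl.start, sl.start + take))
        sub = ReducedPotentialMatrix(
            u_kn=matrix.u_kn[:, cols],
            N_k=np.array([min(n_use, int(nk)) for nk in N_k]),
            temperature=matrix.temperature,
        )
        res = mbar_solve(sub, tol=tol)
        axis = (n_use * sample_interval) if block_time is not None else n_use / n_min
        rows.append((float(axis), res.delta_f, res.d_delta_f))
    return rows


def statistical_inefficiency(x: np.ndarray, mintime: int = 3) -> float:
    """g = 1 + 2 * sum of the normalized autocorrelation function, truncated
    at its first negative value (after ``mintime``); g >= 1."""
    x = np.asarray(x, float)
    n = x.size
    if n < 4:
        return 1.0
    dx = x - x.mean()
    var = float(dx @ dx) / n
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = float(dx[:-t] @ dx[t:]) / ((n - t) * var)
        if c <= 0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def subsample_matrix(matrix: ReducedPotentialMatrix) -> ReducedPotentialMatrix:
    """Decorrelate: within each state, keep every ceil(g)-th sample, where g
    is the statistical inefficiency of that state's own reduced potential."""
    cols: list[int] = []
    new_Nk = []
    for k in range(matrix.n_states):
        sl = matrix.state_slice(k)
        nk = int(matrix.N_k[k])
        if nk == 0:
            new_Nk.append(0)
            continue
        series = matrix.u_kn[k, sl]
        stride = max(int(np.ceil(statistical_inefficiency(series))), 1)
        keep = list(range(sl.start, sl.stop, stride))
        cols.extend(keep)
        new_Nk.append(len(keep))
    return ReducedPotentialMatrix(matrix.u_kn[:, cols], np.array(new_Nk),
                                  matrix.temperature)
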