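"""HKA and maximum-likelihood HKA tests of polymorphism/divergence ratios.

The classical test compares, across loci, the number of segregating sites
S_i in a species sample against the divergence count D_i to an outgroup.
Under neutrality both are proportional to the locus mutation rate, so the
polymorphism/divergence ratio should be homogeneous across loci. A ploidy
factor x_i (1 for autosomal/pseudoautosomal loci, 0.75 for X-linked)
adjusts the effective population size of sex-linked loci.

Model moments per locus i (theta_i = per-locus population mutation rate,
tau = scaled species divergence time, a_n = sum 1/i, b_n = sum 1/i^2 over
i < n):

    E[S_i] = x_i theta_i a_{n_i},   Var[S_i] = E[S_i] + (x_i theta_i)^2 b_{n_i}
    E[D_i] = theta_i (tau + x_i),   Var[D_i] = E[D_i] + theta_i^2

The goodness-of-fit statistic X^2 sums squared standardised deviations of
S and D over loci and is referred to a chi-square with (#loci - 1) degrees
of freedom.

The ML variant assigns selected loci a selection parameter k scaling both
polymorphism and the ancestral-polymorphism component of divergence
(k > 1: balancing selection), with independent Poisson likelihoods

    S_i ~ Poisson(k_i x_i theta_i a_{n_i}),  D_i ~ Poisson(theta_i (tau + k_i x_i))

and a likelihood-ratio test of k = 1. theta_i has a closed-form profile
MLE, so only (tau, k_selected) are optimised numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

log = logging.getLogger("parshift")

PLOIDY_AUTOSOMAL = 1.0
PLOIDY_X_LINKED = 0.75


@dataclass
class HkaLocus:
    """Per-locus polymorphism/divergence counts.

    S: segregating (4-fold) sites in the species sample; n: number of
    sampled alleles; L: analysed sites; D: divergence count to the
    outgroup over the same sites; x: ploidy factor.
    """

    locus_id: str
    S: int
    n: int
    L: int
    D: float
    x: float = PLOIDY_AUTOSOMAL

    def __post_init__(self) -> None:
        if not (0 <= self.S <= self.L):
            raise ValueError(f"{self.locus_id}: S must be in [0, L]")
        if self.D < 0 or self.D > self.L:
            raise ValueError(f"{self.locus_id}: D must be in [0, L]")
        if self.n < 2:
            raise ValueError(f"{self.locus_id}: need n >= 2 sampled alleles")


@dataclass
class HkaResult:
    theta: np.ndarray
    tau: float
    x2: float
    df: int
    p: float


@dataclass
class MlhkaResult:
    theta: np.ndarray
    tau: float
    k: dict[str, float]
    lnl_null: float
    lnl_alt: float
    lrt: float
    df: int
    p: float


def harmonic(n: int, power: int = 1) -> float:
    """a_n (power=1) or b_n (power=2): sum over 1..n-1 of 1/i^power."""
    return float(sum(1.0 / i**power for i in range(1, n)))


def chisq_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if x < 0 or df < 1:
        raise ValueError("require x >= 0 and df >= 1")
    return float(stats.chi2.sf(x, df))


def _x2(loci: list[HkaLocus], theta: np.ndarray, tau: float) -> float:
    total = 0.0
    for i, loc in enumerate(loci):
        a = harmonic(loc.n, 1)
        b = harmonic(loc.n, 2)
        es = loc.x * theta[i] * a
        vs = es + (loc.x * theta[i]) ** 2 * b
        ed = theta[i] * (tau + loc.x)
        vd = ed + theta[i] ** 2
        total += (loc.S - es) ** 2 / vs + (loc.D - ed) ** 2 / vd
    return total


def _moment_thetas(loci: list[HkaLocus], tau: float) -> np.ndarray:
    """theta estimates given tau: per-locus totals S_i + D_i pin theta_i
    for the first L-1 loci; the last theta balances the total-S equation."""
    L = len(loci)
    a = np.array([harmonic(l.n, 1) for l in loci])
    x = np.array([l.x for l in loci])
    S = np.array([float(l.S) for l in loci])
    D = np.array([float(l.D) for l in loci])
    theta = np.empty(L)
    theta[: L - 1] = (S[: L - 1] + D[: L - 1]) / (x[: L - 1] * a[: L - 1] + tau + x[: L - 1])
    theta[L - 1] = (S.sum() - np.sum(x[: L - 1] * theta[: L - 1] * a[: L - 1])) / (x[L - 1] * a[L - 1])
    return theta


def hka_test(loci: list[HkaLocus], n_restarts: int = 10, seed: int = 0) -> HkaResult:
    """Classical HKA goodness-of-fit test over >= 2 loci.

    Parameters follow the classical moment equations: total segregating
    sites and total divergence match their expectations and the per-locus
    totals S_i + D_i match for all but the last locus; tau is the root of
    the total-divergence equation (monotone, solved by bracketing). X^2 is
    then evaluated at these estimates and referred to chi-square with
    L - 1 degrees of freedom. Degenerate systems (no valid root or a
    negative theta) fall back to direct numerical minimisation of X^2.
    """
    if len(loci) < 2:
        raise ValueError("HKA requires at least two loci")
    Ls = len(loci)
    x = np.array([l.x for l in loci])
    D = np.array([float(l.D) for l in loci])

    def total_divergence_gap(tau: float) -> float:
        theta = _moment_thetas(loci, tau)
        return float(np.sum(theta * (tau + x)) - D.sum())

    theta_hat = tau_hat = None
    try:
        lo, hi = 1e-9, 1e6
        if total_divergence_gap(lo) < 0 < total_divergence_gap(hi):
            tau_hat = float(optimize.brentq(total_divergence_gap, lo, hi, xtol=1e-12))
            theta_hat = _moment_thetas(loci, tau_hat)
            if np.any(theta_hat <= 0):
                theta_hat = tau_hat = None
    except ValueError:
        theta_hat = tau_hat = None

    if theta_hat is None:
        theta_hat, tau_hat = _minimise_x2(loci, n_restarts=n_restarts, seed=seed)

    x2 = _x2(loci, theta_hat, tau_hat)
    df = Ls - 1
    return HkaResult(theta=theta_hat, tau=tau_hat, x2=x2, df=df, p=chisq_upper_tail(x2, df))


def _minimise_x2(loci: list[HkaLocus], n_restarts: int = 10, seed: int = 0) -> tuple[np.ndarray, float]:
    """Fallback estimation: numerical minimisation of X^2 (log-parameterised
    Nelder-Mead with seeded multi-start)."""
    Ls = len(loci)
    a = np.array([harmonic(l.n, 1) for l in loci])
    x = np.array([l.x for l in loci])
    S = np.array([float(l.S) for l in loci])
    D = np.array([float(l.D) for l in loci])
    theta0 = np.maximum(S, 0.5) / (x * a)
    tau0 = max(np.sum(D) / np.sum(theta0) - np.mean(x), 0.05)

    def objective(params: np.ndarray) -> float:
        return _x2(loci, np.exp(params[:Ls]), float(np.exp(params[Ls])))

    rng = np.random.default_rng(seed)
    best = None
    p0 = np.log(np.concatenate([theta0, [tau0]]))
    for r in range(n_restarts):
        start = p0 if r == 0 else p0 + rng.normal(0, 0.5, size=len(p0))
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("HKA estimation failed to converge; inspect input counts")
    return np.exp(best.x[:Ls]), float(np.exp(best.x[Ls]))


# ---------------------------------------------------------------------------
# ML-HKA
# ---------------------------------------------------------------------------

def _profile_loglik(loci: list[HkaLocus], tau: float, k: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood with theta_i profiled out in closed form.

    For fixed (tau, k): d lnL / d theta_i = (S_i + D_i)/theta_i -
    (k_i x_i a_i + tau + k_i x_i) = 0, so theta_i = (S_i + D_i) /
    (k_i x_i a_i + tau + k_i x_i).
    """
    lnl = 0.0
    thetas = np.empty(len(loci))
    for i, loc in enumerate(loci):
        a = harmonic(loc.n, 1)
        denom = k[i] * loc.x * a + tau + k[i] * loc.x
        theta = (loc.S + loc.D) / denom if (loc.S + loc.D) > 0 else 1e-12
        thetas[i] = theta
        lam = k[i] * loc.x * theta * a
        mu = theta * (tau + k[i] * loc.x)
        for obs, rate in ((loc.S, lam), (loc.D, mu)):
            if rate <= 0:
                if obs > 0:
                    return -np.inf, thetas
                continue
            lnl += obs * np.log(rate) - rate
    return lnl, thetas


def _maximise(loci: list[HkaLocus], sel_idx: list[int], seed: int, n_restarts: int = 10):
    """Maximise the profile likelihood over (log tau, log k_selected)."""
    n_free = 1 + len(sel_idx)
    k_base = np.ones(len(loci))

    def negll(params: np.ndarray) -> float:
        tau = np.exp(params[0])
        k = k_base.copy()
        for j, i in enumerate(sel_idx):
            k[i] = np.exp(params[1 + j])
        lnl, _ = _profile_loglik(loci, tau, k)
        return -lnl

    S = np.array([float(l.S) for l in loci])
    D = np.array([float(l.D) for l in loci])
    a = np.array([harmonic(l.n, 1) for l in loci])
    x = np.array([l.x for l in loci])
    theta0 = np.maximum(S, 0.5) / (x * a)
    tau0 = max(np.sum(D) / np.sum(theta0) - np.mean(x), 0.05)
    p0 = np.concatenate([[np.log(tau0)], np.zeros(len(sel_idx))])
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        start = p0 if r == 0 else p0 + rng.normal(0, 0.7, size=n_free)
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    tau_hat = float(np.exp(best.x[0]))
    k_hat = k_base.copy()
    for j, i in enumerate(sel_idx):
        k_hat[i] = float(np.exp(best.x[1 + j]))
    lnl, thetas = _profile_loglik(loci, tau_hat, k_hat)
    return lnl, tau_hat, k_hat, thetas


def mlhka_fit(loci: list[HkaLocus], selected_ids: list[str], seed: int = 0, n_restarts: int = 10) -> MlhkaResult:
    """Maximum-likelihood HKA: free selection parameters k at selected loci.

    The null model constrains k = 1 everywhere; the alternative frees one
    k per selected locus. Requires at least one non-selected (neutral
    reference) locus. The LRT statistic 2(lnL_alt - lnL_null) is referred
    to chi-square with #selected degrees of freedom.
    """
    ids = [l.locus_id for l in loci]
    unknown = set(selected_ids) - set(ids)
    if unknown:
        raise ValueError(f"selected loci not present: {sorted(unknown)}")
    sel_idx = [ids.index(s) for s in selected_ids]
    if len(sel_idx) == len(loci):
        raise ValueError("at least one neutral reference locus is required")
    lnl_null, tau_null, _, _ = _maximise(loci, [], seed=seed)
    lnl_alt, tau_alt, k_hat, thetas = _maximise(loci, sel_idx, seed=seed + 1)
    if lnl_alt < lnl_null:  # numerical: alt nests null
        lnl_alt, tau_alt = lnl_null, tau_null
        k_hat = np.ones(len(loci))
        _, thetas = _profile_loglik(loci, tau_alt, k_hat)
    for j, i in enumerate(sel_idx):
        if k_hat[i] < 1e-6 and loci[i].S > 0:
            raise ValueError(f"{loci[i].locus_id}: boundary solution k -> 0 with S > 0 (inconsistent input)")
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    df = len(sel_idx)
    return MlhkaResult(
        theta=thetas,
        tau=tau_alt,
        k={ids[i]: float(k_hat[i]) for i in sel_idx},
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        lrt=lrt,
        df=df,
        p=chisq_upper_tail(lrt, df) if df >= 1 else 1.0,
    )


def concatenate_loci(loci: list[HkaLocus], locus_id: str = "concat") -> HkaLocus:
    """Sum S, L and D over genes; n is the minimum per-gene sample size.

    All constituent loci must share the ploidy factor.
    """
    if not loci:
        raise ValueError("cannot concatenate an empty locus list")
    xs = {l.x for l in loci}
    if len(xs) > 1:
        raise ValueError("cannot concatenate loci with mixed ploidy factors")
    return HkaLocus(
        locus_id=locus_id,
        S=sum(l.S for l in loci),
        n=min(l.n for l in loci),
        L=sum(l.L for l in loci),
        D=sum(l.D for l in loci),
        x=loci[0].x,
    )
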