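"""Multi-environment variance components, heritability and line BLUPs.

The model is the standard randomised multi-environment trial decomposition

    Y_ikm = mu + g_i + tau_k + (g tau)_ik + delta_(k)m + eps_ikm

with genotype g, environment tau, genotype-by-environment interaction,
replicate-within-environment delta, and residual eps, each an independent
zero-mean normal effect. Variance components are estimated by REML
(restricted maximum likelihood, optimised through Henderson's mixed-model
equations); for balanced tables a closed-form expected-mean-squares
estimator is provided as an independent cross-check. Broad-sense
heritability on a line-mean basis is

    H2 = Vg / (Vg + V_GL/L + Ve/(L*R))

with L environments and R replicates per environment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

RANDOM_TERMS = ("line", "env", "line:env", "env:rep")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components of one trait.

    ``L`` and ``R`` are the environment and replicate counts used in the
    heritability denominator; ``loglik`` is the restricted log-likelihood
    up to an additive constant.
    """

    Vg: float
    V_env: float
    V_GL: float
    V_rep: float
    Ve: float
    L: int
    R: int
    n_lines: int
    mu: float
    converged: bool
    loglik: float
    method: str = "reml"

    @property
    def H2(self) -> float:
        return heritability(self)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = Vg / (Vg + V_GL/L + Ve/(L*R))."""
    if vc.L < 1 or vc.R < 1:
        raise ValueError("L and R must be >= 1")
    for name in ("Vg", "V_GL", "Ve"):
        if getattr(vc, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    denom = vc.Vg + vc.V_GL / vc.L + vc.Ve / (vc.L * vc.R)
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return vc.Vg / denom


# ---------------------------------------------------------------------------
# model frame and design matrices


def _model_frame(table: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    df = table
    if "trait" in df.columns and trait is not None:
        df = df[df["trait"] == trait]
    if len(df) == 0:
        raise ValueError(f"no observations for trait {trait!r}")
    df = df.dropna(subset=["value"])
    n_dropped = (len(table[table["trait"] == trait]) - len(df)
                 if "trait" in table.columns and trait is not None else 0)
    if n_dropped:
        logger.info("dropped %d missing observations", n_dropped)
    if df["line"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    if df["env"].nunique() < 2:
        raise ValueError(
            "single environment: genotype-by-environment variance is "
            "inestimable; fit a reduced (single-environment) model instead"
        )
    return df


def _designs(df: pd.DataFrame) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Intercept column plus one-hot random-effect design matrices."""
    n = len(df)
    X = np.ones((n, 1))
    Zs, names = [], []
    line = pd.Categorical(df["line"])
    env = pd.Categorical(df["env"])
    ge = pd.Categorical(df["line"].astype(str) + "\x1f" + df["env"].astype(str))
    rep = pd.Categorical(df["env"].astype(str) + "\x1f" + df["rep"].astype(str))
    for name, cat in zip(RANDOM_TERMS, (line, env, ge, rep)):
        q = len(cat.categories)
        Z = np.zeros((n, q))
        Z[np.arange(n), cat.codes] = 1.0
        Zs.append(Z)
        names.append(name)
    return X, Zs, names


def _neg2_reml(log_sigma: np.ndarray, M: np.ndarray, Wy: np.ndarray,
               yy: float, n: int, q_sizes: list[int]) -> float:
    """-2 x restricted log-likelihood via the mixed-model equations.

    With R = sigma_e^2 I and G block-diagonal,
    -2 l_R = n log sigma_e^2 + sum_j q_j log sigma_j^2 + log|C| + y'Py.
    """
    sig = np.exp(log_sigma)
    s_e = sig[-1]
    C = M / s_e
    pos = 1
    val = n * np.log(s_e)
    for qj, sj in zip(q_sizes, sig[:-1]):
        idx = np.arange(pos, pos + qj)
        C[idx, idx] += 1.0 / sj
        val += qj * np.log(sj)
        pos += qj
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return 1e12
    val += 2.0 * float(np.sum(np.log(np.diag(chol))))
    rhs = Wy / s_e
    theta = np.linalg.solve(C, rhs)
    val += yy / s_e - float(rhs @ theta)
    return val


def fit_variance_components(table: pd.DataFrame, trait: str | None = None,
                            max_iter: int = 500) -> VarianceComponents:
    """REML estimates of (Vg, V_env, V_GL, V_rep, Ve) for one trait.

    The restricted likelihood is maximised over log-variances (which
    enforces non-negativity; estimates pinned at the lower bound are
    projected to zero). Accepts mildly unbalanced tables; raises on a
    single environment or non-convergence.
    """
    df = _model_frame(table, trait)
    y = df["value"].to_numpy(float)
    n = len(y)
    X, Zs, _ = _designs(df)
    W = np.hstack([X] + Zs)
    M = W.T @ W
    Wy = W.T @ y
    yy = float(y @ y)
    q_sizes = [Z.shape[1] for Z in Zs]

    vy = max(float(np.var(y)), 1e-12)
    x0 = np.log(np.full(5, vy / 5.0))
    mom = None
    if _is_balanced(df):
        mom = _moments_raw(df)
        x0 = np.log(np.clip(np.array(mom), vy * 1e-4, None))
    lo, hi = np.log(vy * 1e-10), np.log(vy * 1e6)
    res = optimize.minimize(
        _neg2_reml, np.clip(x0, lo, hi),
        args=(M, Wy, yy, n, q_sizes),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * 5,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not res.success:
        # L-BFGS-B line searches can break down when a component sits on the
        # boundary; polish with bounded derivative-free Powell from there
        res = optimize.minimize(
            _neg2_reml, res.x, args=(M, Wy, yy, n, q_sizes),
            method="Powell", bounds=[(lo, hi)] * 5,
            options={"maxiter": max_iter, "xtol": 1e-10, "ftol": 1e-13},
        )
    if not res.success:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations: {res.message}"
        )
    sig = np.exp(res.x)
    sig[sig <= vy * 1e-8] = 0.0  # boundary projection
    mu_hat = _mu_hat(sig, M, Wy, q_sizes)
    L = int(df["env"].nunique())
    R = int(round(len(df) / (df["line"].nunique() * L)))
    return VarianceComponents(
        Vg=float(sig[0]), V_env=float(sig[1]), V_GL=float(sig[2]),
        V_rep=float(sig[3]), Ve=float(sig[4]),
        L=L, R=max(R, 1), n_lines=int(df["line"].nunique()),
        mu=mu_hat, converged=True, loglik=-0.5 * float(res.fun),
        method="reml",
    )


def _mu_hat(sig: np.ndarray, M: np.ndarray, Wy: np.ndarray,
            q_sizes: list[int]) -> float:
    s_e = max(sig[-1], 1e-12)
    C = M / s_e
    pos = 1
    for qj, sj in zip(q_sizes, sig[:-1]):
        idx = np.arange(pos, pos + qj)
        C[idx, idx] += 1.0 / max(sj, 1e-12) if sj > 0 else 1e12
        pos += qj
    theta = np.linalg.solve(C, Wy / s_e)
    return float(theta[0])


# ---------------------------------------------------------------------------
# balanced-design expected-mean-squares (method-of-moments) oracle


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["line", "env"], observed=True).size()
    full = df["line"].nunique() * df["env"].nunique()
    return len(counts) == full and counts.nunique() == 1


def moments_estimates(table: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Closed-form ANOVA (expected-mean-squares) estimates, balanced data.

    Equates observed mean squares of the genotype, environment, G x E,
    replicate-within-environment and residual strata to their expectations.
    Estimates may be negative (no projection) — this is the independent
    oracle the REML fit is checked against, not the production estimator.
    """
    df = _model_frame(table, trait)
    if not _is_balanced(df):
        raise ValueError("moments estimator requires a balanced table")
    vg, venv, vgl, vrep, ve = _moments_raw(df)
    L = int(df["env"].nunique())
    R = int(len(df) / (df["line"].nunique() * L))
    return VarianceComponents(
        Vg=vg, V_env=venv, V_GL=vgl, V_rep=vrep, Ve=ve,
        L=L, R=R, n_lines=int(df["line"].nunique()),
        mu=float(df["value"].mean()), converged=True, loglik=float("nan"),
        method="moments",
    )


def _moments_raw(df: pd.DataFrame) -> tuple[float, float, float, float, float]:
    g = df["line"].nunique()
    L = df["env"].nunique()
    R = int(len(df) / (g * L))
    y = df["value"].to_numpy(float)
    grand = y.mean()
    m_i = df.groupby("line", observed=True)["value"].mean()
    m_k = df.groupby("env", observed=True)["value"].mean()
    m_ik = df.groupby(["line", "env"], observed=True)["value"].mean()
    m_km = df.groupby(["env", "rep"], observed=True)["value"].mean()

    ss_g = L * R * float(((m_i - grand) ** 2).sum())
    ss_e = g * R * float(((m_k - grand) ** 2).sum())
    ge_dev = (m_ik
              - m_i.reindex(m_ik.index.get_level_values(0)).to_numpy()
              - m_k.reindex(m_ik.index.get_level_values(1)).to_numpy()
              + grand)
    ss_ge = R * float((ge_dev ** 2).sum())
    rep_dev = m_km - m_km.index.get_level_values(0).map(m_k).to_numpy()
    ss_rep = g * float((rep_dev ** 2).sum())

    fitted = (m_ik.reindex(pd.MultiIndex.from_frame(df[["line", "env"]])).to_numpy()
              + m_km.reindex(pd.MultiIndex.from_frame(df[["env", "rep"]])).to_numpy()
              - df["env"].map(m_k).to_numpy())
    ss_err = float(((y - fitted) ** 2).sum())

    ms_g = ss_g / (g - 1)
    ms_e = ss_e / (L - 1)
    ms_ge = ss_ge / ((g - 1) * (L - 1))
    ms_rep = ss_rep / (L * (R - 1)) if R > 1 else float("nan")
    df_err = L * (g - 1) * (R - 1)
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    if R > 1:
        ve = ms_err
        vrep = (ms_rep - ms_err) / g
    else:
        ve = ms_ge  # residual confounded with G x E at R = 1
        vrep = 0.0
        ms_err = ms_ge
    vgl = (ms_ge - ms_err) / R
    vg = (ms_g - ms_ge) / (L * R)
    venv = (ms_e - ms_ge - (ms_rep - ms_err if R > 1 else 0.0)) / (g * R)
    return vg, venv, vgl, vrep, ve


# ---------------------------------------------------------------------------
# BLUP / BLUE of line values


def compute_blups(table: pd.DataFrame, vc: VarianceComponents,
                  trait: str | None = None, mode: str = "blup") -> pd.DataFrame:
    """Per-line genetic values at the fitted variance components.

    ``mode="blup"`` treats genotype as random and returns the shrunken line
    deviations g_i (columns ``blup`` and ``line_value`` = mu + g_i);
    ``mode="blue"`` treats genotype as fixed (generalised least squares
    against the same random environment/interaction/replicate structure)
    and returns unshrunken line means in ``line_value``.
    """
    if not vc.converged:
        raise ValueError("variance components did not converge; refusing BLUP")
    if mode not in ("blup", "blue"):
        raise ValueError("mode must be 'blup' or 'blue'")
    df = _model_frame(table, trait)
    y = df["value"].to_numpy(float)
    n = len(y)
    lines = pd.Categorical(df["line"])
    line_names = list(lines.categories)

    X, Zs, names = _designs(df)
    sigmas = [vc.Vg, vc.V_env, vc.V_GL, vc.V_rep]
    if mode == "blue":
        # genotype becomes fixed: move its design into X (cell-means coding)
        X = Zs[0]
        Zs = Zs[1:]
        sigmas = sigmas[1:]
        names = names[1:]
    keep = [i for i, s in enumerate(sigmas) if s > 0]
    Zs = [Zs[i] for i in keep]
    sigmas = [sigmas[i] for i in keep]
    s_e = max(vc.Ve, 1e-12)

    W = np.hstack([X] + Zs) if Zs else X
    p = X.shape[1]
    C = (W.T @ W) / s_e
    pos = p
    for Z, s in zip(Zs, sigmas):
        idx = np.arange(pos, pos + Z.shape[1])
        C[idx, idx] += 1.0 / s
        pos += Z.shape[1]
    theta = np.linalg.solve(C, (W.T @ y) / s_e)

    if mode == "blue":
        vals = theta[:p]
        out = pd.DataFrame({"line": line_names, "line_value": vals})
        out["deviation"] = out["line_value"] - out["line_value"].mean()
        return out
    mu_hat = float(theta[0])
    if vc.Vg > 0:
        g_hat = theta[1:1 + len(line_names)]
    else:
        g_hat = np.zeros(len(line_names))
    return pd.DataFrame({
        "line": line_names,
        "blup": g_hat,
        "line_value": mu_hat + g_hat,
    })
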