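"""Bayesian GBLUP by Gibbs sampling: linear and liability-threshold models.

Model 1 (linear):  y = Xb + g + e,  g ~ N(0, G sigma_g^2),  e ~ N(0, I sigma_e^2),
with a flat prior on the fixed effects b and independent scaled
inverse-chi-square priors on both variances (degree of belief -2 and scale 0
by default, i.e. flat on the variance).

Model 2 (threshold): an unobserved liability eta = Xb + g + e with
sigma_e^2 = 1 generates the ordinal score through ordered thresholds; eta is
data-augmented with truncated-normal draws, the first threshold is fixed at 0
and the rest are updated uniformly between the flanking liability order
statistics. The binary variant fixes the single threshold at 0.

The genetic effects are sampled in the eigenbasis of G (one symmetric
eigendecomposition per G, reused across chains): because the eigenvectors are
orthonormal, the coordinates are conditionally independent univariate
normals, which is mathematically identical to the joint multivariate draw.
A closed-form GLS/BLUP solver is provided as an independent oracle for
testing the sampler with fixed variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.special import ndtr, ndtri

from .panels import GRMatrix


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignMatrix:
    """Full-column-rank fixed-effect design: intercept, factors, age, age^2."""

    matrix: np.ndarray
    columns: list[str]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_design(phenos: pd.DataFrame) -> tuple[DesignMatrix, np.ndarray]:
    """Design matrix and response from a phenotype table.

    Treatment coding with the first (sorted) level of each factor dropped;
    age enters as raw months and months squared. A factor with a single
    level contributes no columns (warning); a rank-deficient design raises
    an error naming the collinear columns.
    """
    required = {"value", "market", "year", "age_months"}
    missing = required - set(phenos.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    if phenos[list(required)].isna().any().any():
        raise ValueError("missing covariate or trait values are not allowed")

    n = len(phenos)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for factor in ("market", "year"):
        levels = sorted(phenos[factor].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(f"factor '{factor}' has a single level; omitted", stacklevel=2)
            continue
        for lv in levels[1:]:
            cols.append((phenos[factor].astype(str) == lv).to_numpy(float))
            names.append(f"{factor}[{lv}]")
    age = phenos["age_months"].to_numpy(float)
    cols.extend([age, age**2])
    names.extend(["age_months", "age_months_sq"])

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    y = phenos["value"].to_numpy(float)
    return DesignMatrix(matrix=X, columns=names), y


# ---------------------------------------------------------------------------
# Chain / prior configuration and posterior container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainConfig:
    """MCMC protocol. Defaults: 110,000 samples, 10,000 burn-in, thin 10."""

    n_iter: int = 110_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    fixed_variances: tuple[float, float] | None = None  # (sigma_g2, sigma_e2)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PriorConfig:
    """Scaled inverse-chi-square priors; nu=-2, S=0 is flat on the variance."""

    nu_g: float = -2.0
    S_g: float = 0.0
    nu_e: float = -2.0
    S_e: float = 0.0


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of the variance parameters and per-animal GEBVs."""

    mean: dict[str, float]
    sd: dict[str, float]
    mc_se: dict[str, float]
    gebv: np.ndarray
    gebv_sd: np.ndarray
    gebv_mc_se: np.ndarray
    fixed_effects: np.ndarray
    fixed_effect_names: list[str] | None
    n_retained: int
    converged: bool


def mc_standard_error(x: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of the mean of a chain."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 2 * n_batches:
        n_batches = max(2, n // 2)
    size = n // n_batches
    means = x[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def summarize_chain(
    samples: dict[str, np.ndarray], burn_in: int = 0, thin: int = 1
) -> dict[str, dict[str, float]]:
    """Posterior mean/SD/MC-SE per parameter over retained samples.

    If both variance components are present, the phenotypic variance and the
    heritability-like ratio are derived per retained sample (never as a
    ratio of means) before summarizing.
    """
    out: dict[str, dict[str, float]] = {}
    retained = {k: np.asarray(v, float)[burn_in::thin] for k, v in samples.items()}
    n = {len(v) for v in retained.values()}
    if not n or min(n) < 2:
        raise ValueError("too few retained samples to summarize")
    if "sigma_g2" in retained and "sigma_e2" in retained:
        sg, se = retained["sigma_g2"], retained["sigma_e2"]
        retained.setdefault("sigma_p2", sg + se)
        retained.setdefault("ratio", sg / (sg + se))
    for key, vals in retained.items():
        out[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "mc_se": mc_standard_error(vals),
        }
    return out


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------


def gls_oracle(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    grm: GRMatrix,
    sigma_g2: float,
    sigma_e2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form GLS fixed effects and BLUP genetic values at known variances.

    V = G sigma_g^2 + I sigma_e^2;  b = (X'V^-1 X)^-1 X'V^-1 y;
    g = sigma_g^2 G V^-1 (y - Xb).
    """
    if sigma_g2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variances must be positive")
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, float)
    Gv = grm.values
    n = len(y)
    V = Gv * sigma_g2 + np.eye(n) * sigma_e2
    cho = sla.cho_factor(V)
    ViX = sla.cho_solve(cho, Xm)
    Viy = sla.cho_solve(cho, y)
    XtViX = Xm.T @ ViX
    try:
        b = sla.solve(XtViX, Xm.T @ Viy, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular X'V^-1X; check the design matrix") from exc
    resid = y - Xm @ b
    g = sigma_g2 * (Gv @ sla.cho_solve(cho, resid))
    return b, g


# ---------------------------------------------------------------------------
# Shared Gibbs machinery
# ---------------------------------------------------------------------------


class _GrmEigen:
    """Cached eigendecomposition of a GRM (one per matrix, reused by chains)."""

    def __init__(self, grm: GRMatrix):
        w, U = np.linalg.eigh(grm.values)
        if w.min() <= 0:
            raise ValueError(
                "G matrix is not positive definite; increase the diagonal jitter"
            )
        self.w = w
        self.U = U


def _draw_scaled_inv_chi2(
    rng: np.random.Generator, df: float, sum_sq: float
) -> float:
    return sum_sq / rng.chisquare(df)


class _RunningStats:
    """Streaming mean/SD and batch means for a vector-valued chain."""

    def __init__(self, dim: int, n_total: int, n_batches: int = 20):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)
        self.n_batches = min(n_batches, max(2, n_total))
        self.batch_sums = np.zeros((self.n_batches, dim))
        self.batch_counts = np.zeros(self.n_batches, dtype=int)
        self.n_total = n_total

    def update(self, x: np.ndarray) -> None:
        b = min(self.n * self.n_batches // self.n_total, self.n_batches - 1)
        self.batch_sums[b] += x
        self.batch_counts[b] += 1
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.m2 / max(self.n - 1, 1))

    @property
    def mc_se(self) -> np.ndarray:
        ok = self.batch_counts > 0
        means = self.batch_sums[ok] / self.batch_counts[ok, None]
        k = ok.sum()
        return means.std(axis=0, ddof=1) / np.sqrt(k)


def _check_converged(chain: np.ndarray) -> bool:
    """Geweke-style check: first vs last half agree within 3 joint MC SEs."""
    half = len(chain) // 2
    if half < 4:
        return True
    a, b = chain[:half], chain[half:]
    se = np.hypot(mc_standard_error(a), mc_standard_error(b))
    if se == 0:
        return True
    return bool(abs(a.mean() - b.mean()) / se < 3.0)


# ---------------------------------------------------------------------------
# Model 1: linear Gibbs sampler
# ---------------------------------------------------------------------------


def gibbs_model1(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    grm: GRMatrix,
    chain: ChainConfig,
    prior: PriorConfig = PriorConfig(),
    eigen: "_GrmEigen | None" = None,
) -> PosteriorSummary:
    """Gibbs sampler for the linear model y = Xb + g + e.

    Full conditionals: b is multivariate normal around the weighted LS
    solution (flat prior); the eigen-coordinates of g are independent
    normals; each variance is scaled inverse chi-square. With
    ``chain.fixed_variances`` set, the variance updates are skipped (oracle
    mode for testing against closed-form BLUP).
    """
    names = X.columns if isinstance(X, DesignMatrix) else None
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = Xm.shape
    q = grm.n_individuals
    if len(y) != n or q != n:
        raise ValueError("y, X and G dimensions disagree")
    if n < p + 3:
        raise ValueError("need at least ncol(X) + 3 records")
    df_g = q + prior.nu_g
    df_e = n + prior.nu_e
    if chain.fixed_variances is None and (df_g < 1 or df_e < 1):
        raise ValueError("posterior degrees of freedom must be >= 1")

    eig = eigen if eigen is not None else _GrmEigen(grm)
    w, U = eig.w, eig.U
    XtX_cho = sla.cho_factor(Xm.T @ Xm)
    L = sla.cholesky(Xm.T @ Xm, lower=True)

    rng = np.random.default_rng(chain.seed)
    fixed = chain.fixed_variances is not None
    if fixed:
        sg2, se2 = chain.fixed_variances
        if sg2 <= 0 or se2 <= 0:
            raise ValueError("fixed variances must be positive")
    else:
        sg2 = max(y.var() / 2.0, 1e-8)
        se2 = max(y.var() / 2.0, 1e-8)

    b = np.zeros(p)
    g = np.zeros(n)

    n_ret = chain.n_retained
    sg2_chain = np.empty(n_ret)
    se2_chain = np.empty(n_ret)
    b_chain = np.empty((n_ret, p))
    g_stats = _RunningStats(n, n_ret)

    kept = 0
    for it in range(chain.n_iter):
        # b | g, sigma_e2 (flat prior)
        b_mean = sla.cho_solve(XtX_cho, Xm.T @ (y - g))
        b = b_mean + np.sqrt(se2) * sla.solve_triangular(
            L.T, rng.standard_normal(p), lower=False
        )
        # g | b, variances — independent normals in G's eigenbasis
        r = y - Xm @ b
        t = U.T @ r
        v = 1.0 / (1.0 / se2 + 1.0 / (w * sg2))
        alpha = v * t / se2 + np.sqrt(v) * rng.standard_normal(n)
        g = U @ alpha
        if not fixed:
            ss_g = float(np.sum(alpha * alpha / w)) + prior.nu_g * prior.S_g
            sg2 = _draw_scaled_inv_chi2(rng, df_g, ss_g)
            e = r - g
            ss_e = float(e @ e) + prior.nu_e * prior.S_e
            se2 = _draw_scaled_inv_chi2(rng, df_e, ss_e)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            sg2_chain[kept] = sg2
            se2_chain[kept] = se2
            b_chain[kept] = b
            g_stats.update(g)
            kept += 1

    summ = summarize_chain({"sigma_g2": sg2_chain, "sigma_e2": se2_chain})
    converged = fixed or _check_converged(sg2_chain)
    return PosteriorSummary(
        mean={k: v["mean"] for k, v in summ.items()},
        sd={k: v["sd"] for k, v in summ.items()},
        mc_se={k: v["mc_se"] for k, v in summ.items()},
        gebv=g_stats.mean.copy(),
        gebv_sd=g_stats.sd.copy(),
        gebv_mc_se=g_stats.mc_se.copy(),
        fixed_effects=b_chain.mean(axis=0),
        fixed_effect_names=list(names) if names is not None else None,
        n_retained=kept,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model 2: liability threshold Gibbs sampler
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mu: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Unit-variance truncated normal draws via inverse-CDF."""
    a = ndtr(lo - mu)
    b = ndtr(hi - mu)
    u = a + (b - a) * rng.random(len(mu))
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return mu + ndtri(u)


def binary_classes(scores: np.ndarray, split: int = 6) -> np.ndarray:
    """Collapse ordinal scores into two classes: <= split vs > split.

    The default split groups marbling scores 2–6 against 7–12.
    """
    return (np.asarray(scores) > split).astype(np.int64)


def gibbs_model2(
    scores: np.ndarray,
    X: DesignMatrix | np.ndarray,
    grm: GRMatrix,
    chain: ChainConfig,
    mode: str = "ordinal",
    binary_split: int = 6,
    prior: PriorConfig = PriorConfig(),
    eigen: "_GrmEigen | None" = None,
) -> PosteriorSummary:
    """Data-augmentation Gibbs sampler for the liability threshold model.

    The residual variance on the liability scale is fixed at 1, so the
    reported 'ratio' is sigma_g^2 / (sigma_g^2 + 1). In binary mode the
    single threshold is fixed at 0; in ordinal mode the first threshold is
    fixed at 0 and the others are sampled uniformly between the flanking
    liability order statistics. Threshold-model chains can mix very slowly;
    a convergence heuristic is reported in ``converged`` and a warning is
    raised when a threshold update interval collapses.
    """
    if mode not in ("binary", "ordinal"):
        raise ValueError("mode must be 'binary' or 'ordinal'")
    names = X.columns if isinstance(X, DesignMatrix) else None
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, float)
    scores = np.asarray(scores)
    n, p = Xm.shape
    if len(scores) != n or grm.n_individuals != n:
        raise ValueError("scores, X and G dimensions disagree")

    if mode == "binary":
        cat = binary_classes(scores, binary_split)
    else:
        observed = np.unique(scores)
        cat = np.searchsorted(observed, scores)
        full_range = np.arange(observed.min(), observed.max() + 1)
        if len(observed) != len(full_range):
            warnings.warn(
                "empty interior score categories were merged with neighbours",
                stacklevel=2,
            )
    n_cat = int(cat.max()) + 1
    if n_cat < 2:
        raise ValueError("need at least two observed categories")
    df_g = n + prior.nu_g
    if df_g < 1:
        raise ValueError("posterior degrees of freedom must be >= 1")

    eig = eigen if eigen is not None else _GrmEigen(grm)
    w, U = eig.w, eig.U
    XtX_cho = sla.cho_factor(Xm.T @ Xm)
    L = sla.cholesky(Xm.T @ Xm, lower=True)
    rng = np.random.default_rng(chain.seed)

    # thresholds: tau[k] separates category k from k+1; tau[0] fixed at 0
    freqs = np.bincount(cat, minlength=n_cat) / n
    cum = np.cumsum(freqs)[:-1]
    tau = ndtri(np.clip(cum, 1e-6, 1 - 1e-6))
    tau = tau - tau[0]  # anchor first threshold at 0
    for k in range(1, len(tau)):
        if tau[k] <= tau[k - 1]:
            tau[k] = tau[k - 1] + 1e-6

    def bounds(tau_now: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        edges = np.concatenate([[-np.inf], tau_now, [np.inf]])
        return edges[cat], edges[cat + 1]

    lo, hi = bounds(tau)
    eta = np.clip((lo + hi) / 2.0, lo + 0.5, hi - 0.5)
    eta = np.where(np.isfinite(eta), eta, 0.0)

    b = np.zeros(p)
    g = np.zeros(n)
    sg2 = 0.5
    slow_mixing_warned = False

    n_ret = chain.n_retained
    sg2_chain = np.empty(n_ret)
    b_chain = np.empty((n_ret, p))
    g_stats = _RunningStats(n, n_ret)

    kept = 0
    for it in range(chain.n_iter):
        # liabilities | rest: truncated normals within each record's interval
        mu = Xm @ b + g
        eta = _truncated_normal(rng, mu, lo, hi)
        # thresholds (ordinal only; tau[0] stays 0)
        if mode == "ordinal" and len(tau) > 1:
            for k in range(1, len(tau)):
                lo_k = eta[cat == k].max() if np.any(cat == k) else tau[k - 1]
                hi_k = eta[cat == k + 1].min() if np.any(cat == k + 1) else tau[k]
                if hi_k <= lo_k:
                    if not slow_mixing_warned:
                        warnings.warn(
                            "threshold update interval collapsed; expect very "
                            "slow mixing",
                            stacklevel=2,
                        )
                        slow_mixing_warned = True
                    continue
                tau[k] = rng.uniform(lo_k, hi_k)
            lo, hi = bounds(tau)
        # b | eta, g (sigma_e2 = 1)
        b_mean = sla.cho_solve(XtX_cho, Xm.T @ (eta - g))
        b = b_mean + sla.solve_triangular(L.T, rng.standard_normal(p), lower=False)
        # g | eta, b
        r = eta - Xm @ b
        t = U.T @ r
        v = 1.0 / (1.0 + 1.0 / (w * sg2))
        alpha = v * t + np.sqrt(v) * rng.standard_normal(n)
        g = U @ alpha
        # sigma_g2 | g
        ss_g = float(np.sum(alpha * alpha / w)) + prior.nu_g * prior.S_g
        sg2 = _draw_scaled_inv_chi2(rng, df_g, ss_g)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            sg2_chain[kept] = sg2
            b_chain[kept] = b
            g_stats.update(g)
            kept += 1

    ratio_chain = sg2_chain / (sg2_chain + 1.0)
    summ = summarize_chain({"sigma_g2": sg2_chain, "ratio": ratio_chain})
    converged = _check_converged(ratio_chain)
    if not converged:
        warnings.warn(
            "threshold-model chain failed the convergence heuristic; "
            "consider a much longer diagnostic chain",
            stacklevel=2,
        )
    return PosteriorSummary(
        mean={k: v["mean"] for k, v in summ.items()},
        sd={k: v["sd"] for k, v in summ.items()},
        mc_se={k: v["mc_se"] for k, v in summ.items()},
        gebv=g_stats.mean.copy(),
        gebv_sd=g_stats.sd.copy(),
        gebv_mc_se=g_stats.mc_se.copy(),
        fixed_effects=b_chain.mean(axis=0),
        fixed_effect_names=list(names) if names is not None else None,
        n_retained=kept,
        converged=converged,
    )
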