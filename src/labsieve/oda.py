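"""Bayesian variable selection by Orthogonal Data Augmentation (ODA).

The question the pipeline answers per analyte is "with what posterior
probability does this analyte enter a predictive model for the diagnosis?"
under Bayesian Model Averaging over all 2^p subsets of a probit regression

    P(y_i = 1) = Phi(alpha + x_i' beta),    beta_j | gamma_j=1 ~ N(0, tau2),
    gamma_j ~ Bernoulli(pi),                beta_j | gamma_j=0 = 0,

with standardized predictor columns and an always-included intercept under a
vague prior.  Direct Gibbs sampling over (gamma, beta) mixes poorly when
predictors are correlated; ODA augments the n observed rows with p pseudo
rows X_a chosen so that the combined Gram matrix X_o'X_o + X_a'X_a is
diagonal.  Conditional on the complete (observed + augmented) latent
responses the coordinates decouple: each gamma_j, beta_j has an exact
closed-form conditional driven by a scalar least-squares estimate
beta_hat_j, so the whole inclusion vector is updated in one shot per
iteration.  The binary outcome is handled by the standard latent-utility
augmentation: Z_i ~ N(alpha + x_i' beta, 1) truncated to the side given by
y_i, which makes the probit conditionals exactly Gaussian.

Inclusion probabilities are reported Rao-Blackwellized: the average over
post-burn iterations of the *conditional* inclusion probability rho_j,
rather than the raw frequency of gamma_j = 1, which reduces Monte-Carlo
variance at no cost.

The model-size penalty ("Occam shrinkage") is implicit in the marginal
likelihood ratio: a noise coordinate's conditional inclusion odds fall
below the prior odds because the slab must spread its mass.  An explicit
Occam's-window pruning of the visited model list is provided as a
secondary, stricter read-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit, ndtr, ndtri

from .records import LabMatrix

__all__ = [
    "DesignMatrix",
    "AugmentedDesign",
    "SelectionPrior",
    "ModelPosterior",
    "standardize",
    "orthogonal_augment",
    "conditional_inclusion_prob",
    "run_oda_probit",
    "run_oda_linear",
    "occams_window",
]


@dataclass
class DesignMatrix:
    """Standardized n × p design plus the outcome vector.

    Columns have mean 0 and variance 1 (population scaling); the per-column
    (mean, sd) pairs are kept so effects can be reported in native units.
    """

    X: np.ndarray
    y: np.ndarray
    analytes: list[str]
    means: np.ndarray
    sds: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class AugmentedDesign:
    X_a: np.ndarray  # p × p upper-triangular completion rows
    D: np.ndarray  # diagonal of the combined Gram matrix
    epsilon: float


@dataclass
class SelectionPrior:
    """Spike-and-slab selection prior on standardized coefficients."""

    pi: float = 0.5
    tau2: float = 1.0
    intercept_var: float = 1e6

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")


@dataclass
class ModelPosterior:
    rho: np.ndarray  # Rao-Blackwellized inclusion probability per analyte
    gamma_draws: np.ndarray  # (n_kept, p) uint8 inclusion indicators
    model_counts: dict[str, int]  # bitstring -> visit count (post-burn)
    n_iter: int
    n_burn: int
    seed: int
    analytes: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_iter - self.n_burn

    def model_probs(self) -> dict[str, float]:
        total = sum(self.model_counts.values())
        return {m: c / total for m, c in self.model_counts.items()}

    def model_list_text(self) -> str:
        """Visited models as delimited text: bitstring, count, probability."""
        probs = self.model_probs()
        lines = ["model\tcount\tprobability"]
        for m, c in sorted(self.model_counts.items(), key=lambda t: -t[1]):
            lines.append(f"{m}\t{c}\t{probs[m]:.6f}")
        return "\n".join(lines) + "\n"


def standardize(
    values: np.ndarray | LabMatrix, y: np.ndarray, analytes: list[str] | None = None
) -> DesignMatrix:
    """Center and scale columns to mean 0, variance 1 (population sd)."""
    if isinstance(values, LabMatrix):
        analytes = list(values.analytes)
        values = values.values
    X = np.asarray(values, dtype=float)
    if analytes is None:
        analytes = [f"x{j}" for j in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s): {[analytes[j] for j in bad]}")
    Xs = (X - means) / sds
    return DesignMatrix(X=Xs, y=np.asarray(y, dtype=float), analytes=analytes, means=means, sds=sds)


def orthogonal_augment(X_o: np.ndarray, epsilon: float | None = None) -> AugmentedDesign:
    """Pseudo rows making the combined Gram matrix diagonal.

    D is the scalar diagonal (lambda_max(X_o'X_o) + epsilon) * I — the
    smallest uniform diagonal dominating the Gram matrix, inflated by
    epsilon (default 0.001 * lambda_max) so the positive-semidefinite
    completion diag(D) - X_o'X_o is strictly factorizable.  X_a is its
    upper-triangular Cholesky square root (p rows).
    """
    X_o = np.asarray(X_o, dtype=float)
    p = X_o.shape[1]
    if p < 1:
        raise ValueError("need at least one predictor column")
    gram = X_o.T @ X_o
    lam_max = float(np.linalg.eigvalsh(gram)[-1])
    eps = 1e-3 * lam_max if epsilon is None else float(epsilon)
    for attempt in range(2):
        D = np.full(p, lam_max + eps)
        A = np.diag(D) - gram
        try:
            X_a = linalg.cholesky(A, lower=False)
            return AugmentedDesign(X_a=X_a, D=D, epsilon=eps)
        except linalg.LinAlgError:
            eps *= 10.0
    raise linalg.LinAlgError("PSD completion failed even after inflating epsilon")


def conditional_inclusion_prob(
    beta_hat: np.ndarray | float, d: np.ndarray | float, prior: SelectionPrior
) -> np.ndarray | float:
    """Posterior inclusion probability of one coordinate given its scalar
    least-squares estimate.

    With unit residual variance, beta_hat_j | beta_j ~ N(beta_j, 1/d_j);
    marginalizing the slab gives m1 = N(beta_hat; 0, 1/d + tau2) against the
    spike's m0 = N(beta_hat; 0, 1/d), and

        rho = pi m1 / (pi m1 + (1 - pi) m0),

    evaluated in log space for numerical range.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (np.all(np.isfinite(beta_hat)) and np.all(np.isfinite(d)) and np.all(d > 0)):
        raise ValueError("beta_hat must be finite and d positive")
    v0 = 1.0 / d
    v1 = v0 + prior.tau2
    log_m1 = -0.5 * (np.log(2 * np.pi * v1) + beta_hat**2 / v1)
    log_m0 = -0.5 * (np.log(2 * np.pi * v0) + beta_hat**2 / v0)
    log_odds = np.log(prior.pi / (1.0 - prior.pi)) + log_m1 - log_m0
    rho = expit(log_odds)
    return rho if np.ndim(rho) else float(rho)


def _truncnorm_latent(eta: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent probit utilities: N(eta, 1) truncated positive (y=1) / negative (y=0).

    Inverse-CDF sampling phrased through ndtr/ndtri in whichever tail keeps
    full floating-point accuracy for large |eta|.
    """
    u = rng.uniform(size=eta.shape)
    t = np.empty_like(eta)
    pos = y > 0.5
    # y=1: standard-normal part T > -eta, sampled via the upper tail
    t[pos] = -ndtri(u[pos] * ndtr(eta[pos]))
    # y=0: T < -eta, sampled via the lower tail
    t[~pos] = ndtri(u[~pos] * ndtr(-eta[~pos]))
    return eta + t


def _oda_gibbs(
    design: DesignMatrix,
    aug: AugmentedDesign,
    prior: SelectionPrior,
    n_iter: int,
    n_burn: int,
    seed: int,
    probit: bool,
) -> ModelPosterior:
    if not n_iter > n_burn >= 0:
        raise ValueError("need n_iter > n_burn >= 0")
    X_o, y = design.X, design.y
    X_a, D = aug.X_a, aug.D
    n, p = X_o.shape
    rng = np.random.default_rng(seed)

    tau2 = prior.tau2
    v_cond = 1.0 / (D + 1.0 / tau2)  # beta_j | gamma_j=1 conditional variance
    va = 1.0 / (n + 1.0 / prior.intercept_var)  # intercept conditional variance

    beta = np.zeros(p)
    alpha = float(ndtri(np.clip(y.mean(), 1e-3, 1 - 1e-3))) if probit else 0.0
    mu = X_o @ beta
    Xoty = X_o.T @ y  # reused every iteration in the linear case

    rho_acc = np.zeros(p)
    kept = np.empty((n_iter - n_burn, p), dtype=np.uint8)
    model_counts: dict[str, int] = {}

    for it in range(n_iter):
        if probit:
            z = _truncnorm_latent(alpha + mu, y, rng)
            s_obs = X_o.T @ z  # columns are centered, so alpha drops out
            z_sum = float(z.sum())
        else:
            z = y
            s_obs = Xoty
            z_sum = float(y.sum())
        z_a = X_a @ beta + rng.standard_normal(p)
        beta_hat = (s_obs + X_a.T @ z_a) / D

        rho = conditional_inclusion_prob(beta_hat, D, prior)
        gamma = rng.uniform(size=p) < rho
        beta = np.where(
            gamma,
            v_cond * D * beta_hat + np.sqrt(v_cond) * rng.standard_normal(p),
            0.0,
        )
        mu = X_o @ beta
        alpha = va * z_sum + np.sqrt(va) * rng.standard_normal()
        if not np.all(np.isfinite(beta)):
            raise FloatingPointError(f"sampler state diverged at iteration {it}")

        if it >= n_burn:
            rho_acc += rho
            g8 = gamma.astype(np.uint8)
            kept[it - n_burn] = g8
            key = g8.tobytes()
            model_counts[key] = model_counts.get(key, 0) + 1

    counts = {
        "".join(map(str, np.frombuffer(k, dtype=np.uint8))): c
        for k, c in model_counts.items()
    }
    return ModelPosterior(
        rho=rho_acc / (n_iter - n_burn),
        gamma_draws=kept,
        model_counts=counts,
        n_iter=n_iter,
        n_burn=n_burn,
        seed=seed,
        analytes=list(design.analytes),
    )


def run_oda_probit(
    design: DesignMatrix,
    aug: AugmentedDesign | None = None,
    prior: SelectionPrior | None = None,
    n_iter: int = 20000,
    n_burn: int = 5000,
    seed: int = 0,
) -> ModelPosterior:
    """ODA Gibbs sampler for probit variable selection (binary outcome)."""
    if not np.isin(design.y, (0.0, 1.0)).all():
        raise ValueError("probit sampler needs a 0/1 outcome")
    aug = aug or orthogonal_augment(design.X)
    prior = prior or SelectionPrior()
    return _oda_gibbs(design, aug, prior, n_iter, n_burn, seed, probit=True)


def run_oda_linear(
    design: DesignMatrix,
    aug: AugmentedDesign | None = None,
    prior: SelectionPrior | None = None,
    n_iter: int = 20000,
    n_burn: int = 5000,
    seed: int = 0,
) -> ModelPosterior:
    """Linear-outcome variant (unit residual variance, y pre-scaled).

    Identical Gibbs cycle minus the latent-utility step; used for oracle
    validation against exhaustive enumeration.
    """
    aug = aug or orthogonal_augment(design.X)
    prior = prior or SelectionPrior()
    return _oda_gibbs(design, aug, prior, n_iter, n_burn, seed, probit=False)


def occams_window(posterior: ModelPosterior, C: float = 20.0) -> dict[str, float]:
    """Models whose estimated posterior probability is within a factor C of
    the best visited model's (C >= 1; C = 1 keeps only the top models)."""
    if C < 1:
        raise ValueError("C must be >= 1")
    probs = posterior.model_probs()
    if not probs:
        raise ValueError("no visited models")
    best = max(probs.values())
    return {m: q for m, q in probs.items() if q >= best / C}
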