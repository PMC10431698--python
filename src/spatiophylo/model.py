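"""Bayesian linear mixed models with structured Gaussian random effects.

The model for a standardized trait score ``y`` over n taxa is

    y = alpha + X beta + sum_k u_k + eps,
    u_k ~ N(0, sigma_k^2 C_k),   eps ~ N(0, sigma_e^2 I),

where each ``C_k`` is a standardized covariance structure (phylogenetic
Brownian, spatial Matern, area blocks, or an RW2 smoother).  Every SD
carries a penalized-complexity prior, operationalized as an exponential
prior calibrated by P(sigma > u) = alpha.

Inference is a deterministic nested approximation in the spirit of
integrated nested Laplace approximation: fixed effects are marginalized
analytically under a flat prior, the low-dimensional posterior of the
log-SDs is evaluated on a Laplace-anchored grid, and latent effects are
drawn from their exact Gaussian conditional at sampled grid nodes.
Posterior draws are therefore Monte-Carlo summaries of a deterministic
approximation; the seed affects only quantile noise, not the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .covariance import CovarianceStructure
from .errors import AlignmentError, NumericalError

log = logging.getLogger(__name__)

GRID_HALFWIDTH = 3.5  # grid extent in posterior-SD units of the log-SD scale
GRID_POINTS = {1: 41, 2: 15, 3: 9, 4: 7}  # per-dimension node counts by dim


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PCPrior:
    """Penalized-complexity prior on an SD: P(sigma > u) = alpha.

    Realized as sigma ~ Exponential(rate) with rate = -ln(alpha) / u,
    which shrinks the component toward zero (the simpler model) at a
    constant rate — the PC prior for a Gaussian random-effect SD.
    """

    u: float = 1.0
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("threshold u must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("tail probability alpha must be in (0, 1)")

    @property
    def rate(self) -> float:
        return -np.log(self.alpha) / self.u

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.exponential(scale=1.0 / self.rate, size=size)


def pc_prior_rate(p: PCPrior) -> float:
    """Exponential rate such that P(sigma > u) = alpha."""
    return p.rate


#: the prior sensitivity grid: tail probabilities at threshold u = 1
SENSITIVITY_ALPHAS = (0.01, 0.10, 0.50, 0.99)


# ---------------------------------------------------------------------------
# WAIC


@dataclass(frozen=True)
class WAICResult:
    waic: float
    p_eff: float
    lppd: float

    def __float__(self) -> float:
        return self.waic


def waic(pointwise_loglik) -> WAICResult:
    """Widely applicable information criterion from pointwise log-likelihoods.

    ``pointwise_loglik`` is draws x observations.  WAIC =
    -2 * sum_i [ log mean_s exp(ll_si) - var_s(ll_si) ] with the
    variance-based effective-parameter penalty (sample variance, n-1).
    """
    ll = np.asarray(pointwise_loglik, float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be draws x observations")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    S = ll.shape[0]
    if S < 100:
        log.warning("WAIC from only %d draws; penalty estimate is noisy", S)
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(ll.shape[1])
    return WAICResult(
        waic=float(-2.0 * np.sum(lppd_i - p_i)),
        p_eff=float(p_i.sum()),
        lppd=float(lppd_i.sum()),
    )


# ---------------------------------------------------------------------------
# RW2 nonlinear effects


def second_difference_matrix(n_bins: int) -> np.ndarray:
    """(n_bins-2) x n_bins second-difference operator; rank n_bins - 2."""
    D = np.zeros((n_bins - 2, n_bins))
    for i in range(n_bins - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


@dataclass
class RW2Structure:
    """A second-order random-walk latent effect over covariate bins.

    The covariate is cut into ``n_bins`` equal-width bins; the latent
    bin vector has the intrinsic RW2 (second-difference) penalty.  The
    improper null space is handled by dropping the constant direction
    (sum-to-zero) and giving the linear direction a large finite
    variance equal to the largest penalized principal variance, so the
    smoother properly nests linear trends.
    """

    name: str
    structure: CovarianceStructure
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    bin_index: np.ndarray  # per-observation bin assignment
    bin_cov: np.ndarray  # nb x nb prior covariance on the same scale as structure
    n_bins: int


def rw2_structure(covariate, n_bins: int = 25, name: str = "rw2") -> RW2Structure:
    """Build the RW2 latent-effect structure for a continuous covariate."""
    x = np.asarray(covariate, float)
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    if len(np.unique(x)) < n_bins:
        raise ValueError(
            f"covariate has {len(np.unique(x))} distinct values; "
            f"use fewer bins than {n_bins}"
        )
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    mid = (edges[:-1] + edges[1:]) / 2.0

    D = second_difference_matrix(n_bins)
    R = D.T @ D
    w, U = np.linalg.eigh(R)
    pos = w > 1e-10 * w.max()
    Cz = (U[:, pos] / w[pos]) @ U[:, pos].T
    grid = np.arange(n_bins, dtype=float)
    lin = grid - grid.mean()
    lin /= np.linalg.norm(lin)
    tau_lin = float((1.0 / w[pos]).max())
    Cz = Cz + tau_lin * np.outer(lin, lin)

    B = np.zeros((len(x), n_bins))
    B[np.arange(len(x)), idx] = 1.0
    Cobs = B @ Cz @ B.T
    scale = float(np.diag(Cobs).mean())
    if scale <= 0:
        raise NumericalError("degenerate RW2 structure (all observations in one bin?)")
    struct = CovarianceStructure(
        name=name, kind="rw2",
        taxa=[f"obs{i}" for i in range(len(x))],
        matrix=Cobs / scale, standardized=True,
    )
    return RW2Structure(
        name=name, structure=struct, bin_edges=edges, bin_mid=mid,
        bin_index=idx, bin_cov=Cz / scale, n_bins=n_bins,
    )


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed`` terms are covariate names; a term spelled ``"a:b"`` is the
    raw product of the two columns (used for the speakers-by-vehicularity
    interaction, which enters as a lone product term).  ``rw2`` terms
    are (covariate name, n_bins) pairs.  ``random`` names refer to
    covariance structures supplied at fit time.
    """

    response: str = "z_score"
    fixed: tuple = ()
    rw2: tuple = ()
    random: tuple = ()
    priors: dict | None = None
    seed: int = 0
    draws: int = 400

    def label(self) -> str:
        parts = list(self.random) + list(self.fixed)
        parts += [f"rw2({c})" for c, _ in self.rw2]
        return " + ".join(parts) if parts else "intercept-only"


def build_design(covariates: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix columns for fixed-effect terms (no intercept)."""
    cols = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            for c in (a, b):
                if c not in covariates.columns:
                    raise KeyError(f"unknown covariate {c!r} in term {term!r}")
            cols[term] = covariates[a].to_numpy(float) * covariates[b].to_numpy(float)
        else:
            if term not in covariates.columns:
                raise KeyError(f"unknown covariate {term!r}")
            cols[term] = covariates[term].to_numpy(float)
    return pd.DataFrame(cols, index=covariates.index)


# ---------------------------------------------------------------------------
# the model object


class SpatioPhyloLMM:
    """Gaussian mixed model with structured random effects over taxa.

    Parameters
    ----------
    y : Series or array
        Response (typically a standardized complexity score).  If a
        Series, its index is taken as the taxon order.
    X : DataFrame or None
        Fixed-effect columns (no intercept; one is always added).
    structures : sequence of CovarianceStructure
        Standardized covariance structures; unstandardized inputs are
        standardized on entry.  Taxon order must match ``y`` when both
        carry labels.
    priors : dict, optional
        Per-component :class:`PCPrior`, keyed by structure name, plus
        ``"resid"``; missing keys get PCPrior(u=1, alpha=0.1).
    rw2 : sequence of RW2Structure, optional
    """

    def __init__(self, y, X=None, structures=(), priors=None, rw2=()):
        if isinstance(y, pd.Series):
            self.taxa = [str(t) for t in y.index]
            self.y = y.to_numpy(float)
        else:
            self.y = np.asarray(y, float)
            self.taxa = None
        n = len(self.y)
        if np.isnan(self.y).any():
            raise ValueError("response contains missing values")

        if X is None:
            Xm = np.empty((n, 0))
            xnames: list[str] = []
        else:
            if isinstance(X, pd.DataFrame):
                xnames = [str(c) for c in X.columns]
                if self.taxa is not None and list(map(str, X.index)) != self.taxa:
                    if set(map(str, X.index)) == set(self.taxa):
                        X = X.loc[[t for t in self.taxa]]
                    else:
                        diff = sorted(set(self.taxa) ^ set(map(str, X.index)))
                        raise AlignmentError(f"y/X taxa mismatch: {diff[:5]}")
                Xm = X.to_numpy(float)
            else:
                Xm = np.atleast_2d(np.asarray(X, float))
                if Xm.shape[0] != n:
                    Xm = Xm.T
                xnames = [f"x{j}" for j in range(Xm.shape[1])]
        if Xm.shape[0] != n:
            raise AlignmentError("design matrix rows do not match response length")
        self.X = np.column_stack([np.ones(n), Xm])
        self.term_names = ["Intercept"] + xnames

        comps: list[CovarianceStructure] = []
        for s in structures:
            if self.taxa is not None and s.taxa != self.taxa:
                if set(s.taxa) >= set(self.taxa):
                    s = s.subset(self.taxa)
                else:
                    diff = sorted(set(self.taxa) - set(s.taxa))
                    raise AlignmentError(
                        f"structure {s.name!r} missing taxa: {diff[:5]}"
                    )
            if not s.standardized:
                s = s.standardize_and_invert(invert=False)
            comps.append(s)
        self.rw2_terms = list(rw2)
        for r in self.rw2_terms:
            if r.structure.n != n:
                raise AlignmentError(f"rw2 term {r.name!r} has wrong length")
            comps.append(r.structure)
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate component names: {names}")
        self.components = comps
        self.comp_names = names

        priors = dict(priors or {})
        self.priors = {
            name: priors.get(name, priors.get("default", PCPrior()))
            for name in names + ["resid"]
        }

        self._eigen_cache = None

    # -- likelihood machinery ----------------------------------------------

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k_components(self) -> int:
        return len(self.components)

    def _eigen(self):
        """Eigen path for models with at most one structured component."""
        if self._eigen_cache is None:
            if self.k_components == 0:
                w = np.zeros(self.n)
                yt, Xt = self.y, self.X
            else:
                w, U = self.components[0].eigen()
                yt, Xt = U.T @ self.y, U.T @ self.X
                self._U = U
            self._eigen_cache = (w, yt, Xt)
        return self._eigen_cache

    def _marginal_loglik(self, sigmas: np.ndarray):
        """Log p(y | theta) with beta integrated under a flat prior.

        Returns (loglik, aux) where aux caches what draws need.
        """
        n, p = self.X.shape
        s2 = sigmas**2
        if self.k_components <= 1:
            w, yt, Xt = self._eigen()
            coef = s2[0] if self.k_components == 1 else 0.0
            d = coef * w + s2[-1]
            if np.min(d) <= 0:
                return -np.inf, None
            Xd = Xt / d[:, None]
            A = Xt.T @ Xd
            bvec = Xd.T @ yt
            try:
                LA = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                return -np.inf, None
            z = np.linalg.solve(LA, bvec)
            quad = float(yt**2 @ (1.0 / d)) - float(z @ z)
            logdet_V = float(np.log(d).sum())
            logdet_A = float(2.0 * np.log(np.diag(LA)).sum())
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_A + quad)
            aux = {"mode": "eigen", "d": d, "LA": LA, "bvec": bvec}
            return float(ll), aux
        V = s2[-1] * np.eye(n)
        for s2k, comp in zip(s2[:-1], self.components):
            V += s2k * comp.matrix
        try:
            cF = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        Vi_X = cho_solve(cF, self.X, check_finite=False)
        Vi_y = cho_solve(cF, self.y, check_finite=False)
        A = self.X.T @ Vi_X
        bvec = self.X.T @ Vi_y
        try:
            LA = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return -np.inf, None
        z = np.linalg.solve(LA, bvec)
        quad = float(self.y @ Vi_y) - float(z @ z)
        logdet_V = float(2.0 * np.log(np.diag(cF[0])).sum())
        logdet_A = float(2.0 * np.log(np.diag(LA)).sum())
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_A + quad)
        aux = {"mode": "dense", "cF": cF, "LA": LA, "bvec": bvec, "Vi_y": Vi_y}
        return float(ll), aux

    def _log_posterior(self, theta: np.ndarray) -> float:
        sigmas = np.exp(theta)
        if np.any(sigmas > 1e6) or np.any(sigmas < 1e-8):
            return -np.inf
        ll, _ = self._marginal_loglik(sigmas)
        if not np.isfinite(ll):
            return -np.inf
        lp = ll
        for name, sig, th in zip(
            self.comp_names + ["resid"], sigmas, theta
        ):
            rate = self.priors[name].rate
            lp += np.log(rate) - rate * sig + th  # Jacobian d sigma / d theta
        return float(lp)

    # -- fitting -------------------------------------------------------------

    def fit(self, seed: int = 0, draws: int = 400) -> "LMMResults":
        """Run the grid approximation and return posterior summaries."""
        K = self.k_components
        dim = K + 1
        sd_y = max(float(np.std(self.y)), 1e-3)
        theta0 = np.log(np.full(dim, 0.5 * sd_y))
        opt = optimize.minimize(
            lambda th: -self._log_posterior(th), theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 250 * dim},
        )
        mode = opt.x
        H = _neg_hessian(self._log_posterior, mode)
        cov_theta = _safe_inverse(H, dim)

        g = GRID_POINTS.get(dim, 5)
        wH, UH = np.linalg.eigh(cov_theta)
        axes = UH * np.sqrt(np.clip(wH, 1e-4, None))
        zs = np.linspace(-GRID_HALFWIDTH, GRID_HALFWIDTH, g)
        mesh = np.meshgrid(*([zs] * dim), indexing="ij")
        Z = np.stack([m.ravel() for m in mesh], axis=1)
        nodes = mode[None, :] + Z @ axes.T
        logp = np.array([self._log_posterior(th) for th in nodes])
        finite = np.isfinite(logp)
        if not finite.any():
            raise NumericalError("posterior grid entirely degenerate")
        wts = np.zeros(len(nodes))
        wts[finite] = np.exp(logp[finite] - logp[finite].max())
        wts /= wts.sum()
        edge = np.abs(Z).max(axis=1) >= zs[-1] - 1e-12
        boundary_mass = float(wts[edge].sum())
        if boundary_mass > 0.05:
            log.warning("grid boundary carries %.1f%% posterior mass",
                        100 * boundary_mass)

        rng = np.random.default_rng(seed)
        # sample hyperparameter nodes from the highest-weight subset
        # covering 99.9% of the grid mass (caps O(n^3) work per fit)
        order = np.argsort(wts)[::-1]
        csum = np.cumsum(wts[order])
        m_keep = min(int(np.searchsorted(csum, 0.999)) + 1, 80)
        keep = order[:m_keep]
        wk = wts[keep] / wts[keep].sum()
        node_draws = keep[rng.choice(m_keep, size=draws, p=wk)]
        S = draws
        p = self.X.shape[1]
        n = self.n
        beta_draws = np.empty((S, p))
        sd_draws = np.empty((S, dim))
        pointwise = np.empty((S, n))
        for node in np.unique(node_draws):
            sel = np.where(node_draws == node)[0]
            sigmas = np.exp(nodes[node])
            _, aux = self._marginal_loglik(sigmas)
            if aux is None:
                # numerically degenerate node with (vanishing) weight
                sigmas = np.exp(mode)
                _, aux = self._marginal_loglik(sigmas)
            self._draw_at_node(rng, sigmas, aux, sel,
                               beta_draws, sd_draws, pointwise)
        result = LMMResults(
            model=self,
            beta_draws=beta_draws,
            sd_draws=sd_draws,
            sd_names=self.comp_names + ["resid"],
            pointwise_loglik=pointwise,
            theta_mode=mode,
            grid_nodes=nodes,
            grid_weights=wts,
            diagnostics={
                "mode_converged": bool(opt.success),
                "boundary_mass": boundary_mass,
                "n_grid": len(nodes),
                "n_nodes_sampled": int(len(np.unique(node_draws))),
                "seed": seed,
            },
        )
        if not opt.success:
            log.warning("posterior mode search did not report convergence")
        return result

    def _draw_at_node(self, rng, sigmas, aux, sel,
                      beta_draws, sd_draws, pointwise) -> None:
        n, p = self.X.shape
        m = len(sel)
        s2e = sigmas[-1] ** 2
        LA, bvec = aux["LA"], aux["bvec"]
        beta_hat = np.linalg.solve(LA.T, np.linalg.solve(LA, bvec))
        zb = rng.standard_normal((m, p))
        betas = beta_hat[None, :] + np.linalg.solve(LA.T, zb.T).T
        if aux["mode"] == "eigen":
            w, yt, Xt = self._eigen()
            wtil = (sigmas[0] ** 2) * w if self.k_components == 1 else np.zeros(n)
            d = aux["d"]
            cv = np.clip(wtil - wtil**2 / d, 0.0, None)
            resid_t = yt[None, :] - betas @ Xt.T
            means = (wtil / d)[None, :] * resid_t
            u_t = means + np.sqrt(cv)[None, :] * rng.standard_normal((m, n))
            u = u_t @ self._U.T if self.k_components == 1 else u_t
            eta = betas @ self.X.T + u
        else:
            # with W = V - s2e*I the conditional of u_total given (y, beta) is
            #   mean = W V^{-1} r = r - s2e V^{-1} r
            #   cov  = W - W V^{-1} W = s2e (I - s2e V^{-1})
            P = cho_solve(aux["cF"], np.eye(n), check_finite=False)
            Scond = s2e * (np.eye(n) - s2e * P)
            Scond = (Scond + Scond.T) / 2.0
            jitter = 1e-10 * max(np.trace(Scond) / n, 1.0)
            LS = np.linalg.cholesky(Scond + jitter * np.eye(n))
            resid = self.y[None, :] - betas @ self.X.T
            means = resid - s2e * (resid @ P)
            u = means + rng.standard_normal((m, n)) @ LS.T
            eta = betas @ self.X.T + u
        ll = (
            -0.5 * np.log(2 * np.pi * s2e)
            - 0.5 * (self.y[None, :] - eta) ** 2 / s2e
        )
        beta_draws[sel] = betas
        sd_draws[sel] = sigmas[None, :]
        pointwise[sel] = ll


def _neg_hessian(f, x0: np.ndarray, h: float = 0.05) -> np.ndarray:
    dim = len(x0)
    H = np.zeros((dim, dim))
    f0 = f(x0)
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = h
            ej = np.zeros(dim); ej[j] = h
            if i == j:
                val = -(f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h**2
            else:
                val = -(
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h**2)
            H[i, j] = H[j, i] = val
    return H


def _safe_inverse(H: np.ndarray, dim: int) -> np.ndarray:
    try:
        w, U = np.linalg.eigh(H)
        if np.all(w > 0):
            return (U / w) @ U.T
    except np.linalg.LinAlgError:
        pass
    diag = np.abs(np.diag(H))
    diag[diag < 1e-6] = 1.0
    log.info("Hessian not positive definite; using diagonal fallback")
    return np.diag(1.0 / diag)


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class EffectSummary:
    name: str
    q025: float
    q50: float
    q975: float
    substantial: bool


@dataclass
class LMMResults:
    """Posterior summaries of a fitted spatiophylogenetic mixed model."""

    model: SpatioPhyloLMM
    beta_draws: np.ndarray
    sd_draws: np.ndarray
    sd_names: list[str]
    pointwise_loglik: np.ndarray
    theta_mode: np.ndarray
    grid_nodes: np.ndarray
    grid_weights: np.ndarray
    diagnostics: dict
    _waic: WAICResult | None = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return self.model.term_names

    def _draws_for(self, term: str) -> np.ndarray:
        if term in self.term_names:
            return self.beta_draws[:, self.term_names.index(term)]
        key = term.removeprefix("sd_")
        if key in self.sd_names:
            return self.sd_draws[:, self.sd_names.index(key)]
        raise KeyError(
            f"unknown term {term!r}; have {self.term_names + self.sd_names}"
        )

    def summarize_effect(self, term: str) -> EffectSummary:
        d = self._draws_for(term)
        q025, q50, q975 = np.quantile(d, [0.025, 0.5, 0.975])
        return EffectSummary(term, float(q025), float(q50), float(q975),
                             bool(q025 > 0 or q975 < 0))

    @property
    def waic(self) -> WAICResult:
        if self._waic is None:
            object.__setattr__(self, "_waic", waic(self.pointwise_loglik))
        return self._waic

    def variance_partition(self, use_mean: bool = False) -> dict[str, float]:
        """Posterior-median variance fractions per component (plus residual)."""
        est = np.mean if use_mean else np.median
        var = {name: float(est(self.sd_draws[:, j] ** 2))
               for j, name in enumerate(self.sd_names)}
        total = sum(var.values())
        fr = {name.replace("resid", "residual"): v / total for name, v in var.items()}
        return fr

    def all_effects(self) -> list[EffectSummary]:
        return [self.summarize_effect(t) for t in self.term_names] + [
            self.summarize_effect(s) for s in self.sd_names
        ]

    def summary(self) -> str:
        lines = [
            "Spatiophylogenetic linear mixed model "
            f"(n = {self.model.n}, draws = {self.beta_draws.shape[0]})",
            f"random effects: {', '.join(self.model.comp_names) or 'none'}",
            f"{'term':<22}{'2.5%':>9}{'50%':>9}{'97.5%':>9}  substantial",
        ]
        for eff in self.all_effects():
            lines.append(
                f"{eff.name:<22}{eff.q025:>9.3f}{eff.q50:>9.3f}"
                f"{eff.q975:>9.3f}  {'*' if eff.substantial else ''}"
            )
        w = self.waic
        lines.append(f"WAIC = {w.waic:.2f} (p_eff = {w.p_eff:.1f})")
        fr = self.variance_partition()
        lines.append(
            "variance fractions: "
            + ", ".join(f"{k} {100 * v:.1f}%" for k, v in fr.items())
        )
        diag = self.diagnostics
        lines.append(
            f"diagnostics: mode_converged={diag['mode_converged']}, "
            f"boundary_mass={diag['boundary_mass']:.3f}"
        )
        return "\n".join(lines)

    def rw2_curve(self, name: str, n_draw_nodes: int = 40, seed: int = 0):
        """Posterior mean and 95% band of an RW2 bin-effect curve.

        Evaluated by mixing the exact Gaussian conditional of the bin
        vector over the highest-weight grid nodes.
        """
        terms = {r.name: r for r in self.model.rw2_terms}
        if name not in terms:
            raise KeyError(f"no rw2 term {name!r}")
        r = terms[name]
        j = self.model.comp_names.index(name)
        model = self.model
        n = model.n
        B = np.zeros((n, r.n_bins))
        B[np.arange(n), r.bin_index] = 1.0
        top = np.argsort(self.grid_weights)[::-1][:n_draw_nodes]
        wsel = self.grid_weights[top]
        wsel = wsel / wsel.sum()
        rng = np.random.default_rng(seed)
        draws = []
        beta_mean = self.beta_draws.mean(axis=0)
        resid = model.y - model.X @ beta_mean
        for node, wt in zip(top, wsel):
            sigmas = np.exp(self.grid_nodes[node])
            s2 = sigmas**2
            V = s2[-1] * np.eye(n)
            for s2k, comp in zip(s2[:-1], model.components):
                V += s2k * comp.matrix
            Sz = s2[j] * r.bin_cov
            Cov_zy = Sz @ B.T  # cov(z, y)
            Vi = np.linalg.inv(V)
            mean_z = Cov_zy @ Vi @ resid
            cov_z = Sz - Cov_zy @ Vi @ Cov_zy.T
            cov_z = (cov_z + cov_z.T) / 2 + 1e-10 * np.eye(r.n_bins)
            L = np.linalg.cholesky(cov_z)
            m = max(1, int(round(wt * 400)))
            zdraws = mean_z[None, :] + rng.standard_normal((m, r.n_bins)) @ L.T
            draws.append(zdraws - zdraws.mean(axis=1, keepdims=True))
        Z = np.vstack(draws)
        lo, med, hi = np.quantile(Z, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {"bin_mid": r.bin_mid, "q025": lo, "q50": med, "q975": hi}
        )

    def plot_effects(self, ax=None):
        """Forest plot of fixed-effect posterior intervals and medians."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.5 * len(self.term_names) + 1))
        effs = [self.summarize_effect(t) for t in self.term_names]
        ys = np.arange(len(effs))[::-1]
        for y0, e in zip(ys, effs):
            color = "crimson" if e.substantial and e.q50 > 0 else (
                "navy" if e.substantial else "gray")
            ax.plot([e.q025, e.q975], [y0, y0], color=color, lw=2)
            ax.plot(e.q50, y0, "o", color=color)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_yticks(ys)
        ax.set_yticklabels([e.name for e in effs])
        ax.set_xlabel("posterior (2.5%, 50%, 97.5%)")
        return ax


# ---------------------------------------------------------------------------
# spec-driven convenience front end


def fit(spec: ModelSpec, scores, covariates=None, structures=None) -> LMMResults:
    """Fit a :class:`ModelSpec` against a score table and covariates.

    ``scores`` may be a score DataFrame (columns ``taxon`` and the
    response) or a Series indexed by taxon.  ``structures`` maps names
    to :class:`CovarianceStructure` objects.
    """
    structures = structures or {}
    if isinstance(scores, pd.DataFrame):
        y = scores.set_index("taxon")[spec.response]
    else:
        y = scores
    X = None
    rw2_terms = []
    if spec.fixed or spec.rw2:
        if covariates is None:
            raise ValueError("fixed/rw2 terms given but no covariate table")
        cov = covariates.set_index("taxon") if "taxon" in covariates.columns else covariates
        cov = cov.loc[[t for t in y.index]]
        if spec.fixed:
            X = build_design(cov, spec.fixed)
        for cname, nb in spec.rw2:
            rw2_terms.append(
                rw2_structure(cov[cname].to_numpy(float), nb, name=f"rw2_{cname}")
            )
    comps = []
    for rname in spec.random:
        if rname not in structures:
            raise KeyError(f"unknown random structure {rname!r}")
        comps.append(structures[rname])
    mdl = SpatioPhyloLMM(y, X=X, structures=comps, priors=spec.priors, rw2=rw2_terms)
    return mdl.fit(seed=spec.seed, draws=spec.draws)


def variance_partition(f: LMMResults, use_mean: bool = False) -> dict[str, float]:
    return f.variance_partition(use_mean=use_mean)


def summarize_effect(f: LMMResults, term: str) -> EffectSummary:
    return f.summarize_effect(term)
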