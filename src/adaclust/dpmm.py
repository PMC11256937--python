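"""Dirichlet process Gaussian mixture over the latent space.

Truncated stick-breaking representation with Normal–Wishart component
priors. Fitting uses mean-field variational EM with closed-form conjugate
updates; the evidence lower bound (ELBO) is tracked every iteration and is
non-decreasing up to floating point noise.

The fitted state exposes point estimates (posterior means) of the stick
fractions, mixture weights, component means and precisions; these drive the
differentiable mixture-density loss that shapes the encoder during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import digamma, gammaln, logsumexp

from .errors import DomainError, ValidationError

__all__ = [
    "StickBreaking",
    "MixtureWeights",
    "ComponentParams",
    "NWHyper",
    "DPMMState",
    "stick_to_weights",
    "component_loglik",
    "log_prior_S",
    "fit_S",
    "loss_z",
    "loss_z_grad",
    "responsibilities",
    "effective_cluster_count",
    "default_hyper",
]

_EPS = 1e-300


@dataclass
class StickBreaking:
    """Stick-breaking fractions and the concentration that generated them."""

    delta: np.ndarray  # in (0, 1), length K_max
    alpha: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if self.alpha <= 0:
            raise DomainError(f"concentration must be positive, got {self.alpha}")
        if np.any(self.delta <= 0) or np.any(self.delta >= 1):
            raise DomainError("stick fractions must lie strictly inside (0, 1)")


@dataclass
class MixtureWeights:
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise DomainError("weights must lie in [0, 1]")
        if self.pi.sum() > 1 + 1e-12:
            raise DomainError("truncated stick weights cannot exceed total mass 1")

    def normalized(self) -> np.ndarray:
        total = self.pi.sum()
        if total <= 0:
            raise DomainError("all mixture weights are zero")
        return self.pi / total


@dataclass
class ComponentParams:
    """Point estimates of component means and precision matrices."""

    means: np.ndarray       # (K, D)
    precisions: np.ndarray  # (K, D, D), symmetric positive definite

    def __post_init__(self) -> None:
        for k, lam in enumerate(self.precisions):
            if not np.allclose(lam, lam.T, atol=1e-8):
                raise DomainError(f"precision {k} is not symmetric")


@dataclass
class NWHyper:
    """Normal–Wishart hyperparameters.

    ``sigma`` is the prior mean location, ``kappa0`` the mean-precision
    scale, ``nu0`` the Wishart degrees of freedom and ``zeta`` an SPD matrix
    interpreted as the expected component covariance (so the Wishart scale
    matrix is ``inv(nu0 * zeta)``, making ``E[Lambda] = inv(zeta)``).
    """

    sigma: np.ndarray
    kappa0: float
    nu0: float
    zeta: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.zeta = np.asarray(self.zeta, dtype=np.float64)
        d = self.sigma.size
        if self.kappa0 <= 0:
            raise DomainError("kappa0 must be positive")
        if self.nu0 < d:
            raise DomainError(f"degrees of freedom {self.nu0} below dimension {d}")
        try:
            cholesky(self.zeta)
        except np.linalg.LinAlgError as exc:
            raise DomainError("zeta must be symmetric positive definite") from exc

    @property
    def wishart_scale(self) -> np.ndarray:
        return np.linalg.inv(self.nu0 * self.zeta)


@dataclass
class DPMMState:
    """Fitted mixture state: sticks, weights, components, responsibilities."""

    sticks: StickBreaking
    weights: MixtureWeights
    components: ComponentParams
    responsibilities: np.ndarray
    hard_labels: np.ndarray
    hyper: NWHyper | None = None
    elbo_trace: np.ndarray | None = field(default=None, repr=False)
    # variational posterior internals kept for warm starts
    posterior: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = self.responsibilities
        if not np.allclose(r.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("responsibility rows must sum to 1")
        if not np.array_equal(self.hard_labels, r.argmax(axis=1)):
            raise ValidationError("hard_labels must be the row argmax of responsibilities")

    @property
    def k_max(self) -> int:
        return self.components.means.shape[0]


def default_hyper(Z: np.ndarray, var_floor: float = 1e-6) -> NWHyper:
    """Empirical hyperparameters: location = mean(Z), scale = diag variance of Z."""
    Z = np.asarray(Z, dtype=np.float64)
    d = Z.shape[1]
    var = Z.var(axis=0) + var_floor
    return NWHyper(sigma=Z.mean(axis=0), kappa0=1.0, nu0=float(d), zeta=np.diag(var))


def stick_to_weights(sticks: StickBreaking) -> MixtureWeights:
    """pi_k = delta_k * prod_{j<k}(1 - delta_j)."""
    delta = sticks.delta
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - delta[:-1])])
    return MixtureWeights(pi=delta * remaining)


def component_loglik(z: np.ndarray, mu: np.ndarray, lam: np.ndarray) -> float:
    """Multivariate normal log-density with precision parameterization."""
    z = np.asarray(z, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    d = z.size
    if mu.size != d or lam.shape != (d, d):
        raise ValidationError("dimension mismatch between z, mu and precision")
    if not np.allclose(lam, lam.T, atol=1e-8):
        raise DomainError("precision must be symmetric")
    try:
        chol = cholesky(lam, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DomainError("precision must be positive definite") from exc
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    diff = z - mu
    quad = diff @ lam @ diff
    return float(0.5 * logdet - 0.5 * d * np.log(2 * np.pi) - 0.5 * quad)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    return (gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1) * np.log(x) + (b - 1) * np.log1p(-x))


def _wishart_logpdf(lam: np.ndarray, df: float, scale: np.ndarray) -> float:
    d = lam.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(scale)
    sign_l, logdet_l = np.linalg.slogdet(lam)
    if sign_l <= 0:
        raise DomainError("precision must be positive definite")
    log_b = (-0.5 * df * logdet_s - 0.5 * df * d * np.log(2.0)
             - 0.25 * d * (d - 1) * np.log(np.pi)
             - gammaln(0.5 * (df + 1 - np.arange(1, d + 1))).sum())
    trace = np.trace(np.linalg.solve(scale, lam))
    return float(log_b + 0.5 * (df - d - 1) * logdet_l - 0.5 * trace)


def log_prior_S(state: DPMMState, hyper: NWHyper, alpha: float) -> float:
    """Joint log-prior of the mixture latent variables.

    Sum of Beta(1, alpha) log-densities of the stick fractions, Normal–Wishart
    log-densities of the component parameters and the categorical log-mass of
    the hard assignments under the stick weights.
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    delta = state.sticks.delta
    total = sum(_beta_logpdf(dk, 1.0, alpha) for dk in delta)
    w0 = hyper.wishart_scale
    for mu, lam in zip(state.components.means, state.components.precisions):
        total += _wishart_logpdf(lam, hyper.nu0, w0)
        total += component_loglik(mu, hyper.sigma, hyper.kappa0 * lam)
    pi = state.weights.pi
    labels = state.hard_labels
    if np.any(pi[labels] <= 0):
        raise DomainError("a hard label falls on a zero-weight component")
    total += float(np.log(pi[labels]).sum())
    return float(total)


# ---------------------------------------------------------------------------
# variational fitting


def _init_responsibilities(Z: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    n = Z.shape[0]
    k = min(k, n)
    labels = KMeans(n_clusters=k, n_init=1, random_state=seed).fit_predict(Z)
    resp = np.full((n, k), 1e-6)
    resp[np.arange(n), labels] = 1.0
    return resp / resp.sum(axis=1, keepdims=True)


def _expected_log_sticks(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dig_sum = digamma(g1 + g2)
    return digamma(g1) - dig_sum, digamma(g2) - dig_sum


def _vb_run(Z, resp, alpha, hyper, max_iter, tol):
    """Coordinate-ascent VB from given responsibilities.

    Returns (resp, posterior dict, elbo_trace list). Monotone in ELBO.
    """
    n, d = Z.shape
    k = resp.shape[1]
    kappa0, nu0, sigma0 = hyper.kappa0, hyper.nu0, hyper.sigma
    w0_inv = nu0 * hyper.zeta  # inverse Wishart scale
    sign, logdet_w0 = np.linalg.slogdet(np.linalg.inv(w0_inv))
    log_b0 = (-0.5 * nu0 * logdet_w0 - 0.5 * nu0 * d * np.log(2.0)
              - 0.25 * d * (d - 1) * np.log(np.pi)
              - gammaln(0.5 * (nu0 + 1 - np.arange(1, d + 1))).sum())

    elbo_trace: list[float] = []
    prev_elbo = -np.inf

    for _ in range(max_iter):
        # ----- M-step: conjugate posterior updates from current resp -----
        nk = resp.sum(axis=0)  # (k,)
        tail = np.concatenate([np.cumsum(nk[::-1])[::-1][1:], [0.0]])
        g1 = 1.0 + nk
        g2 = alpha + tail

        safe_nk = np.maximum(nk, 1e-12)
        xbar = (resp.T @ Z) / safe_nk[:, None]            # (k, d)
        kappa = kappa0 + nk
        m = (kappa0 * sigma0 + nk[:, None] * xbar) / kappa[:, None]
        nu = nu0 + nk
        w_inv = np.empty((k, d, d))
        for j in range(k):
            diff = Z - xbar[j]
            s_j = (resp[:, j][:, None] * diff).T @ diff   # nk * S_k
            dx = (xbar[j] - sigma0)[:, None]
            w_inv[j] = w0_inv + s_j + (kappa0 * nk[j] / kappa[j]) * (dx @ dx.T)

        # ----- E-step: expected log weights + expected Gaussian densities -----
        e_log_delta, e_log_1m_delta = _expected_log_sticks(g1, g2)
        e_log_pi = e_log_delta + np.concatenate([[0.0], np.cumsum(e_log_1m_delta[:-1])])

        log_rho = np.empty((n, k))
        e_logdet = np.empty(k)
        chol_w = []
        for j in range(k):
            cw, low = cho_factor(w_inv[j], lower=True)
            chol_w.append((cw, low))
            logdet_winv = 2.0 * np.log(np.diag(cw)).sum()
            e_logdet[j] = (digamma(0.5 * (nu[j] + 1 - np.arange(1, d + 1))).sum()
                           + d * np.log(2.0) - logdet_winv)
            diff = Z - m[j]
            sol = cho_solve((cw, low), diff.T)            # W_j^{-1⁻¹}... = W_j diff
            quad = nu[j] * np.einsum("nd,dn->n", diff, sol)
            log_rho[:, j] = (e_log_pi[j] + 0.5 * e_logdet[j]
                             - 0.5 * d / kappa[j]
                             - 0.5 * quad
                             - 0.5 * d * np.log(2 * np.pi))
        lse = logsumexp(log_rho, axis=1)
        resp = np.exp(log_rho - lse[:, None])

        # ----- ELBO (after E-step, all terms at the current posterior) -----
        elbo = float(lse.sum())
        # stick KL: -KL(Beta(g1,g2) || Beta(1,alpha))
        kl_beta = (gammaln(g1 + g2) - gammaln(g1) - gammaln(g2)
                   - gammaln(1.0 + alpha) + gammaln(alpha)
                   + (g1 - 1.0) * digamma(g1) + (g2 - alpha) * digamma(g2)
                   + (1.0 + alpha - g1 - g2) * digamma(g1 + g2))
        elbo -= float(kl_beta.sum())
        # Normal-Wishart: E[ln p(mu,Lambda)] - E[ln q(mu,Lambda)]
        for j in range(k):
            cw, low = chol_w[j]
            w_j = cho_solve((cw, low), np.eye(d))
            dm = m[j] - sigma0
            e_ln_p = (0.5 * (d * np.log(kappa0 / (2 * np.pi)) + e_logdet[j]
                             - d * kappa0 / kappa[j]
                             - kappa0 * nu[j] * (dm @ w_j @ dm))
                      + log_b0 + 0.5 * (nu0 - d - 1) * e_logdet[j]
                      - 0.5 * nu[j] * np.trace(w0_inv @ w_j))
            logdet_wj = -2.0 * np.log(np.diag(cw)).sum()
            log_bj = (-0.5 * nu[j] * logdet_wj - 0.5 * nu[j] * d * np.log(2.0)
                      - 0.25 * d * (d - 1) * np.log(np.pi)
                      - gammaln(0.5 * (nu[j] + 1 - np.arange(1, d + 1))).sum())
            h_wishart = -log_bj - 0.5 * (nu[j] - d - 1) * e_logdet[j] + 0.5 * nu[j] * d
            e_ln_q = (0.5 * e_logdet[j] + 0.5 * d * np.log(kappa[j] / (2 * np.pi))
                      - 0.5 * d - h_wishart)
            elbo += e_ln_p - e_ln_q
        elbo_trace.append(elbo)
        if elbo - prev_elbo < tol and np.isfinite(prev_elbo):
            break
        prev_elbo = elbo

    posterior = {"g1": g1, "g2": g2, "kappa": kappa, "m": m, "nu": nu,
                 "w_inv": w_inv, "chol_w": chol_w, "nk": nk}
    return resp, posterior, elbo_trace


def _build_state(Z, resp, posterior, elbo_trace, alpha, hyper, precision_floor):
    d = Z.shape[1]
    g1, g2 = posterior["g1"], posterior["g2"]
    nu, m = posterior["nu"], posterior["m"]
    k = m.shape[0]
    delta_hat = np.clip(g1 / (g1 + g2), 1e-12, 1 - 1e-12)
    sticks = StickBreaking(delta=delta_hat, alpha=alpha)
    weights = stick_to_weights(sticks)
    floor_eye = precision_floor * np.eye(d)
    precisions = np.empty((k, d, d))
    for j in range(k):
        cw, low = posterior["chol_w"][j]
        w_j = cho_solve((cw, low), np.eye(d))
        lam = nu[j] * w_j
        precisions[j] = 0.5 * (lam + lam.T) + floor_eye
    components = ComponentParams(means=m, precisions=precisions)
    resp = resp / resp.sum(axis=1, keepdims=True)
    return DPMMState(
        sticks=sticks,
        weights=weights,
        components=components,
        responsibilities=resp,
        hard_labels=resp.argmax(axis=1),
        hyper=hyper,
        elbo_trace=np.asarray(elbo_trace),
        posterior={key: posterior[key] for key in ("g1", "g2", "kappa", "m", "nu", "w_inv")},
    )


def _merge_candidates(posterior, occupied_threshold: float = 0.5) -> list[tuple[int, int, float]]:
    """Pairs of occupied components ordered by mean Mahalanobis proximity."""
    nk = posterior["nk"]
    m = posterior["m"]
    nu = posterior["nu"]
    occ = np.flatnonzero(nk > occupied_threshold)
    pairs = []
    for a_idx in range(occ.size):
        for b_idx in range(a_idx + 1, occ.size):
            i, j = occ[a_idx], occ[b_idx]
            diff = m[i] - m[j]
            cw_i, low_i = posterior["chol_w"][i]
            cw_j, low_j = posterior["chol_w"][j]
            # Mahalanobis under each component's expected precision nu * W
            qi = nu[i] * diff @ cho_solve((cw_i, low_i), diff)
            qj = nu[j] * diff @ cho_solve((cw_j, low_j), diff)
            dist = float(np.sqrt(min(qi, qj)))
            pairs.append((int(i), int(j), dist))
    pairs.sort(key=lambda t: t[2])
    return pairs


def fit_S(
    Z: np.ndarray,
    alpha: float = 1e-10,
    hyper: NWHyper | None = None,
    K_max: int = 50,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    warm_start: DPMMState | None = None,
    precision_floor: float = 1e-6,
    merge_moves: bool = True,
    merge_distance: float = 4.0,
    max_merge_attempts: int = 20,
    min_mass: float = 2.0,
) -> DPMMState:
    """Fit the truncated DP Gaussian mixture to latent vectors by variational EM.

    E-step: responsibilities from expected log stick weights plus expected
    Gaussian log-densities. M-step: conjugate Beta and Normal–Wishart
    posterior updates. Runs until the ELBO improves by less than ``tol`` or
    ``max_iter`` is reached, then attempts merge moves: nearby component
    pairs are tentatively combined and re-optimized, and the merge is kept
    only if it improves the ELBO (escaping the split local optima that plain
    coordinate ascent cannot leave). The reported ELBO trace covers the main
    run plus the final ELBO of each accepted merge, and is non-decreasing.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValidationError("need a 2-D latent matrix with at least 2 rows")
    if not np.all(np.isfinite(Z)):
        raise ValidationError("latent matrix contains non-finite values")
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    n, d = Z.shape
    if hyper is None:
        hyper = default_hyper(Z)
    if hyper.sigma.size != d:
        raise ValidationError("hyperparameter dimension does not match Z")

    if warm_start is not None and warm_start.responsibilities.shape[0] == n:
        resp = warm_start.responsibilities.copy()
    else:
        resp = _init_responsibilities(Z, K_max, seed)

    resp, posterior, elbo_trace = _vb_run(Z, resp, alpha, hyper, max_iter, tol)

    def try_move(cand_resp, budget):
        nonlocal resp, posterior
        r2, p2, t2 = _vb_run(Z, cand_resp, alpha, hyper, budget, tol)
        if t2[-1] > elbo_trace[-1] + 1e-9:
            resp, posterior = r2, p2
            elbo_trace.append(t2[-1])
            return True
        return False

    if merge_moves:
        # reorder components by decreasing mass: the stick-breaking prior
        # favors heavy early sticks, and a fair ordering keeps true clusters
        # from being merged just to escape a high stick index
        order = np.argsort(-posterior["nk"], kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            try_move(resp[:, order], max_iter)

        attempts = 0
        improved = True
        while improved and attempts < max_merge_attempts:
            improved = False
            for i, j, dist in _merge_candidates(posterior):
                if dist > merge_distance or attempts >= max_merge_attempts:
                    break
                attempts += 1
                cand = resp.copy()
                cand[:, i] += cand[:, j]
                cand[:, j] = 1e-12
                cand /= cand.sum(axis=1, keepdims=True)
                if try_move(cand, max_iter):
                    improved = True
                    break

    # minimum-mass constraint: a component holding less than ``min_mass``
    # cells of responsibility is degenerate (an outlier capturing a free
    # trailing stick); drop its column and let the E-step reassign the cells
    while min_mass > 0 and resp.shape[1] > 1:
        nk = resp.sum(axis=0)
        tiny = np.flatnonzero((nk > 1e-9) & (nk < min_mass))
        if tiny.size == 0:
            break
        j = tiny[np.argmin(nk[tiny])]
        resp = np.delete(resp, j, axis=1)
        resp = np.maximum(resp, 1e-12)
        resp /= resp.sum(axis=1, keepdims=True)
        resp, posterior, t2 = _vb_run(Z, resp, alpha, hyper, max(50, max_iter // 4), tol)
        if t2[-1] > elbo_trace[-1]:
            elbo_trace.append(t2[-1])

    return _build_state(Z, resp, posterior, elbo_trace, alpha, hyper, precision_floor)


# ---------------------------------------------------------------------------
# mixture-density loss and responsibilities at point estimates


def _log_components(Z: np.ndarray, state: DPMMState) -> np.ndarray:
    """(N, K) matrix: ln pi_hat_k + ln N(z_n | mu_k, Lambda_k^{-1})."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    pi_hat = state.weights.normalized()
    means = state.components.means
    precisions = state.components.precisions
    n, d = Z.shape
    k = means.shape[0]
    out = np.empty((n, k))
    log_pi = np.log(np.maximum(pi_hat, _EPS))
    for j in range(k):
        chol = cholesky(precisions[j], lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        diff = Z - means[j]
        y = diff @ chol
        quad = np.einsum("nd,nd->n", y, y)
        out[:, j] = log_pi[j] + 0.5 * logdet - 0.5 * d * np.log(2 * np.pi) - 0.5 * quad
    return out


def loss_z(z: np.ndarray, state: DPMMState) -> float | np.ndarray:
    """Negative log mixture density of latent vector(s) under the fitted state.

    ``-ln sum_k pi_hat_k N(z | mu_k, Lambda_k^{-1})`` with posterior-mean
    parameters and normalized weights.
    """
    single = np.asarray(z).ndim == 1
    vals = -logsumexp(_log_components(z, state), axis=1)
    return float(vals[0]) if single else vals


def loss_z_grad(Z: np.ndarray, state: DPMMState) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mixture loss and its gradient with respect to Z."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    log_comp = _log_components(Z, state)
    lse = logsumexp(log_comp, axis=1)
    resp = np.exp(log_comp - lse[:, None])
    grad = np.zeros_like(Z)
    for j in range(state.components.means.shape[0]):
        diff = Z - state.components.means[j]
        grad += resp[:, j][:, None] * (diff @ state.components.precisions[j])
    return -lse, grad


def responsibilities(z: np.ndarray, state: DPMMState) -> np.ndarray:
    """Posterior component probabilities of latent vector(s), rows sum to 1."""
    single = np.asarray(z).ndim == 1
    log_comp = _log_components(z, state)
    r = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
    return r[0] if single else r


def effective_cluster_count(state: DPMMState) -> int:
    """Number of components that win the argmax for at least one cell."""
    return int(np.unique(state.hard_labels).size)
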