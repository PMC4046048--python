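"""Bayes C Gibbs sampler for whole-genome marker regression.

Model for the deregressed pseudo-phenotype of animal i:

    y_i = mu + u_i + sum_k z_ik a_k + e_i

with z_ik the alt-allele dosage (0/1/2), a_k a spike-and-slab marker
effect (zero with prior probability pi, else N(0, sigma2_a) with a common
slab variance), an optional polygenic value u_i with pedigree covariance
A sigma2_u, and e_i ~ N(0, sigma2_e / w_i) when per-record weights are in
use. Variances carry scaled inverse chi-square priors with nu degrees of
freedom and scale S2 = sigma2_hat (nu - 2) / nu.

Each sweep samples mu (flat prior), then for every marker the indicator
and effect jointly — the indicator from the marginal likelihood with the
effect integrated out, the effect from its Normal full conditional when
included — then the variances. Residuals are maintained incrementally;
`run_bayesc` can return the final state so that the incremental residual
can be checked against a from-scratch recomputation.

The per-marker inclusion probability reported is the fraction of retained
(post-burn-in, thinned) samples with a nonzero effect; the reported
effect is the average over all retained samples, counting zero whenever
the marker is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import HaplotypeSet, PosteriorSummary


@dataclass
class BayesCConfig:
    """Chain settings; defaults are the full-scale run constants.

    ``pi`` is the prior exclusion probability of a marker effect; ``nu``
    the inverse chi-square degrees of freedom shared by all variances.
    Prior point values for the variances default to a data-driven split
    of var(y) when left as None (see :func:`default_variance_priors`).
    """

    pi: float = 0.99
    nu: float = 4.2
    sigma2_a_prior: float | None = None
    sigma2_e_prior: float | None = None
    sigma2_u_prior: float | None = None
    n_iter: int = 180_000
    burn_in: int = 20_000
    thin: int = 50
    seed: int = 0
    polygenic_enabled: bool = False
    use_weights: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.pi < 1:
            raise ValueError("pi must be in [0, 1)")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.nu <= 2:
            raise ValueError("nu must exceed 2 for a finite prior scale")


@dataclass
class ModelState:
    """Mutable Gibbs state; residuals are kept consistent incrementally."""

    mu: float
    a: np.ndarray  # marker effects, 0 where excluded
    delta: np.ndarray  # inclusion indicators
    e: np.ndarray  # residuals y - mu - Z (a*delta) - u
    sigma2_a: float
    sigma2_e: float
    u: np.ndarray | None = None
    sigma2_u: float | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def recompute_residuals(self, y: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Residuals from scratch, for consistency checks."""
        e = y - self.mu - Z @ self.a
        if self.u is not None:
            e = e - self.u
        return e


def scale_param(sigma2_hat: float, nu: float) -> float:
    """Inverse chi-square scale S2 = sigma2_hat (nu - 2) / nu."""
    if nu <= 2:
        raise ValueError("nu must exceed 2")
    if sigma2_hat < 0:
        raise ValueError("variance point estimate must be >= 0")
    return sigma2_hat * (nu - 2.0) / nu


def default_variance_priors(y: np.ndarray, Z: np.ndarray, pi: float) -> tuple[float, float]:
    """Heuristic prior point values when none are supplied.

    Half of var(y) is treated as genetic and spread over the expected
    number of included markers weighted by their dosage variance; the
    other half is residual.
    """
    vy = float(np.var(y))
    sum_2pq = float(np.sum(np.var(Z, axis=0))) or 1.0
    sigma2_a = 0.5 * vy / max((1.0 - pi) * sum_2pq, 1e-12)
    sigma2_e = 0.5 * vy
    return sigma2_a, sigma2_e


def gibbs_update_marker(
    state: ModelState,
    k: int,
    Z: np.ndarray,
    pi: float,
    weights: np.ndarray | None = None,
) -> None:
    """Joint (delta_k, a_k) update for one marker, in place.

    The inclusion odds use the marginal likelihood with a_k integrated
    over its N(0, sigma2_a) slab; when included, a_k is drawn from its
    Normal full conditional and the residuals are adjusted.
    """
    z = Z[:, k]
    if weights is None:
        zz = float(z @ z)
        r = float(z @ state.e) + zz * state.a[k]
    else:
        zw = z * weights
        zz = float(zw @ z)
        r = float(zw @ state.e) + zz * state.a[k]
    _sample_marker(state, k, z, zz, r, pi)


def _sample_marker(
    state: ModelState, k: int, z: np.ndarray, zz: float, r: float, pi: float
) -> None:
    s2e = state.sigma2_e
    lam = 1.0 / state.sigma2_a
    prec = zz / s2e + lam
    mean = (r / s2e) / prec
    # log Bayes factor of inclusion vs exclusion (a_k integrated out)
    log_bf = 0.5 * (math.log(lam) - math.log(prec)) + 0.5 * mean * mean * prec
    log_odds = math.log1p(-pi) - math.log(pi) + log_bf
    p_incl = 1.0 / (1.0 + math.exp(-log_odds)) if log_odds < 35 else 1.0
    a_old = state.a[k]
    if state.rng.random() < p_incl:
        a_new = mean + state.rng.standard_normal() / math.sqrt(prec)
        state.delta[k] = 1
    else:
        a_new = 0.0
        state.delta[k] = 0
    if a_new != a_old:
        state.e -= z * (a_new - a_old)
        state.a[k] = a_new


def gibbs_update_variances(
    state: ModelState,
    nu: float,
    s2_a: float,
    s2_e: float,
    weights: np.ndarray | None = None,
    s2_u: float | None = None,
    ainv: np.ndarray | None = None,
) -> None:
    """Draw sigma2_a and sigma2_e (and sigma2_u) from scaled inv-chi2."""
    rng = state.rng
    m_in = int(state.delta.sum())
    ssa = float(state.a @ state.a)
    state.sigma2_a = (ssa + nu * s2_a) / rng.chisquare(nu + m_in)
    if weights is None:
        sse = float(state.e @ state.e)
    else:
        sse = float((state.e * weights) @ state.e)
    n = state.e.shape[0]
    state.sigma2_e = (sse + nu * s2_e) / rng.chisquare(nu + n)
    if state.u is not None:
        ssu = float(state.u @ ainv @ state.u)
        state.sigma2_u = (ssu + nu * s2_u) / rng.chisquare(nu + n)


def _update_mu(state: ModelState, weights: np.ndarray | None) -> None:
    if weights is None:
        n = state.e.shape[0]
        mean = float(state.e.mean())
        sd = math.sqrt(state.sigma2_e / n)
    else:
        sw = float(weights.sum())
        mean = float(weights @ state.e) / sw
        sd = math.sqrt(state.sigma2_e / sw)
    shift = mean + sd * state.rng.standard_normal()
    state.mu += shift
    state.e -= shift


def _update_polygenic(state: ModelState, ainv: np.ndarray, weights) -> None:
    # single-site Gibbs over animals; prior N(cond mean, sigma2_u / ainv_ii)
    s2e, s2u = state.sigma2_e, state.sigma2_u
    rng = state.rng
    u = state.u
    for i in range(u.shape[0]):
        wi = 1.0 if weights is None else weights[i]
        off = float(ainv[i] @ u) - ainv[i, i] * u[i]
        prec = wi / s2e + ainv[i, i] / s2u
        mean = (wi * (state.e[i] + u[i]) / s2e - off / s2u) / prec
        u_new = mean + rng.standard_normal() / math.sqrt(prec)
        state.e[i] -= u_new - u[i]
        u[i] = u_new


def pedigree_a_inverse(pedigree, animal_ids: list) -> np.ndarray:
    """Henderson's A-inverse (no inbreeding adjustment) for a sire/dam table."""
    index = {a: i for i, a in enumerate(animal_ids)}
    n = len(animal_ids)
    ainv = np.zeros((n, n))
    for _, row in pedigree.iterrows():
        if row["animal_id"] not in index:
            continue
        i = index[row["animal_id"]]
        s = index.get(row["sire_id"])
        d = index.get(row["dam_id"])
        known = (s is not None) + (d is not None)
        alpha = [1.0, 4.0 / 3.0, 2.0][known]
        ainv[i, i] += alpha
        for p in (s, d):
            if p is not None:
                ainv[i, p] -= alpha / 2.0
                ainv[p, i] -= alpha / 2.0
                ainv[p, p] += alpha / 4.0
        if known == 2:
            ainv[s, d] += alpha / 4.0
            ainv[d, s] += alpha / 4.0
    return ainv


def run_bayesc(
    y: np.ndarray,
    genotypes: HaplotypeSet | np.ndarray,
    config: BayesCConfig,
    weights: np.ndarray | None = None,
    pedigree=None,
    animal_ids: list | None = None,
    marker_ids: list | None = None,
    return_state: bool = False,
):
    """Run the Gibbs chain and summarise the retained samples.

    ``genotypes`` may be a phased :class:`HaplotypeSet` (dosages are
    formed internally) or a raw (n_animals, n_markers) dosage matrix.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    if isinstance(genotypes, HaplotypeSet):
        Z = genotypes.dosages().astype(float)
        if marker_ids is None:
            marker_ids = list(genotypes.panel.table["id"])
        if animal_ids is None:
            animal_ids = list(genotypes.animal_ids)
    else:
        Z = np.asarray(genotypes, dtype=float)
    n, K = Z.shape
    if y.shape[0] != n:
        raise ValueError("phenotype/genotype row mismatch")
    if marker_ids is None:
        marker_ids = [f"m{k}" for k in range(K)]
    Zc = np.ascontiguousarray(Z.T)  # marker-major rows for fast dot products
    w = None
    if config.use_weights and weights is not None:
        w = np.asarray(weights, dtype=float)
    s2a_hat, s2e_hat = default_variance_priors(y, Z, config.pi)
    if config.sigma2_a_prior is not None:
        s2a_hat = config.sigma2_a_prior
    if config.sigma2_e_prior is not None:
        s2e_hat = config.sigma2_e_prior
    s2_a = scale_param(s2a_hat, config.nu)
    s2_e = scale_param(s2e_hat, config.nu)

    rng = np.random.default_rng(config.seed)
    state = ModelState(
        mu=float(np.mean(y)),
        a=np.zeros(K),
        delta=np.zeros(K, dtype=np.int8),
        e=y - float(np.mean(y)),
        sigma2_a=s2a_hat,
        sigma2_e=s2e_hat,
        rng=rng,
    )
    ainv = s2_u = None
    if config.polygenic_enabled:
        if pedigree is not None and animal_ids is not None:
            ainv = pedigree_a_inverse(pedigree, animal_ids)
        else:
            ainv = np.eye(n)
        s2u_hat = (
            config.sigma2_u_prior
            if config.sigma2_u_prior is not None
            else 0.1 * float(np.var(y))
        )
        s2_u = scale_param(s2u_hat, config.nu)
        state.u = np.zeros(n)
        state.sigma2_u = s2u_hat

    if w is None:
        zz_all = np.einsum("kn,kn->k", Zc, Zc)
        Zw = None
    else:
        Zw = np.ascontiguousarray(Zc * w)
        zz_all = np.einsum("kn,kn->k", Zw, Zc)

    incl = np.zeros(K)
    a_sum = np.zeros(K)
    mu_sum = s2a_sum = s2e_sum = s2u_sum = 0.0
    n_ret = 0
    pi = config.pi
    for it in range(config.n_iter):
        _update_mu(state, w)
        for k in range(K):
            z = Zc[k]
            if w is None:
                r = float(z @ state.e) + zz_all[k] * state.a[k]
            else:
                r = float(Zw[k] @ state.e) + zz_all[k] * state.a[k]
            _sample_marker(state, k, z, zz_all[k], r, pi)
        if state.u is not None:
            _update_polygenic(state, ainv, w)
        gibbs_update_variances(state, config.nu, s2_a, s2_e, w, s2_u, ainv)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            incl += state.delta
            a_sum += state.a
            mu_sum += state.mu
            s2a_sum += state.sigma2_a
            s2e_sum += state.sigma2_e
            if state.sigma2_u is not None:
                s2u_sum += state.sigma2_u
            n_ret += 1

    summary = PosteriorSummary(
        marker_ids=list(marker_ids),
        p=incl / n_ret,
        a_hat=a_sum / n_ret,
        mu_mean=mu_sum / n_ret,
        sigma2_a_mean=s2a_sum / n_ret,
        sigma2_e_mean=s2e_sum / n_ret,
        sigma2_u_mean=(s2u_sum / n_ret) if config.polygenic_enabled else None,
        n_retained=n_ret,
    )
    if return_state:
        return summary, state, y, Z
    return summary
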