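"""Attachment-site length model and Western-blot fold-change ratios.

The length model is a gamma GLMM with a log link: mean
``μ = exp(Xβ + u_sample + u_image)`` with genotype as fixed effect (treatment
coding, wild type as reference) and nested zero-mean Gaussian random
intercepts for sample and image-within-sample. The marginal likelihood is
Laplace-approximated and maximized jointly over β, the gamma shape and the
two variance components. Prespecified comparisons (wild type vs each single
mutant, and double mutant vs the sum of the single-mutant effects) are
evaluated as Wald z-tests with model-based standard errors and Bonferroni
correction over the supplied set.

Because genotype is constant within a sample, the linear predictor is
constant within an image; observations therefore enter the likelihood only
through per-image sufficient statistics (count, Σy, Σ log y), and the
per-cluster Laplace mode is found by Newton steps on an arrow-structured
Hessian solved in closed form. This keeps a fit fast enough for simulation
studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


class InferenceError(ValueError):
    pass


@dataclass
class GlmmSpec:
    response: str = "length"
    genotype: str = "genotype"
    sample: str = "sample"
    image: str = "image"
    reference_level: str = "wt"


@dataclass
class GlmmFit:
    coef_names: list[str]
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    var_sample: float
    var_image: float
    shape: float
    loglik: float
    converged: bool
    spec: GlmmSpec = field(default_factory=GlmmSpec)


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_bonferroni: float


# ---------------------------------------------------------------------------
# sufficient statistics


def _prepare(data: pd.DataFrame, spec: GlmmSpec):
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("responses must be strictly positive")
    levels = [spec.reference_level] + sorted(
        set(data[spec.genotype].astype(str)) - {spec.reference_level})
    img_key = data[spec.sample].astype(str) + "\x00" + data[spec.image].astype(str)
    images = pd.DataFrame({
        "sample": data[spec.sample].astype(str),
        "genotype": data[spec.genotype].astype(str),
        "img": img_key,
        "y": y,
        "logy": np.log(y),
    }).groupby("img", sort=True).agg(
        sample=("sample", "first"), genotype=("genotype", "first"),
        n=("y", "size"), S=("y", "sum"), L=("logy", "sum"))
    # nesting check: every image id belongs to exactly one sample by keying
    sample_ids = sorted(images["sample"].unique())
    s_index = {s: i for i, s in enumerate(sample_ids)}
    n_clusters = len(sample_ids)
    m_max = int(images.groupby("sample").size().max())

    # padded (cluster, image-slot) arrays; pad slots have n=0
    N = np.zeros((n_clusters, m_max))
    S = np.zeros((n_clusters, m_max))
    L = np.zeros((n_clusters, m_max))
    Xeta = np.zeros((n_clusters, m_max, len(levels)))
    slot = {s: 0 for s in sample_ids}
    for _, row in images.iterrows():
        ci = s_index[row["sample"]]
        j = slot[row["sample"]]
        slot[row["sample"]] = j + 1
        N[ci, j] = row["n"]
        S[ci, j] = row["S"]
        L[ci, j] = row["L"]
        Xeta[ci, j, 0] = 1.0
        g = row["genotype"]
        if g != levels[0]:
            Xeta[ci, j, levels.index(g)] = 1.0
    coef_names = ["intercept"] + [f"genotype[{lv}]" for lv in levels[1:]]
    return coef_names, N, S, L, Xeta, sample_ids


def _laplace_loglik(params: np.ndarray, N: np.ndarray, S: np.ndarray,
                    L: np.ndarray, Xeta: np.ndarray) -> float:
    """Laplace-approximated marginal log-likelihood, vectorized over clusters."""
    p = Xeta.shape[2]
    beta = params[:p]
    alpha = math.exp(min(params[p], 30.0))
    sig_s2 = math.exp(2 * np.clip(params[p + 1], -10, 10))
    sig_i2 = math.exp(2 * np.clip(params[p + 2], -10, 10))

    eta0 = Xeta @ beta                      # (C, M) fixed part per image
    C, M = N.shape
    u = np.zeros(C)                         # sample intercepts
    v = np.zeros((C, M))                    # image intercepts

    for _ in range(50):
        eta = eta0 + u[:, None] + v
        Se = S * np.exp(-eta)
        g_img = -alpha * N + alpha * Se     # dll/dη per image
        r0 = g_img.sum(axis=1) - u / sig_s2
        rj = g_img - v / sig_i2
        h_img = -alpha * Se                 # d²ll/dη² per image
        a = h_img.sum(axis=1) - 1.0 / sig_s2
        d = h_img - 1.0 / sig_i2
        c = h_img
        # arrow solve H x = r (Schur complement on the sample entry)
        cd = c / d
        denom = a - (c * cd).sum(axis=1)
        x0 = (r0 - (cd * rj).sum(axis=1)) / denom
        xj = (rj - c * x0[:, None]) / d
        step = 1.0
        for _damp in range(6):
            u_new, v_new = u - step * x0, v - step * xj
            if np.all(np.abs(u_new) < 50) and np.all(np.abs(v_new) < 50):
                break
            step *= 0.5
        delta = max(np.abs(x0).max(initial=0), np.abs(xj).max(initial=0)) * step
        u, v = u_new, v_new
        if delta < 1e-10:
            break

    eta = eta0 + u[:, None] + v
    Se = S * np.exp(-eta)
    ll_obs = (N * (alpha * math.log(alpha) - special.gammaln(alpha))
              + (alpha - 1) * L - alpha * N * eta - alpha * Se).sum()
    n_img = (N > 0).sum()
    ll_prior = (-0.5 * (u**2).sum() / sig_s2 - 0.5 * C * math.log(2 * math.pi * sig_s2)
                - 0.5 * (v**2).sum() / sig_i2
                - 0.5 * (C * M) * math.log(2 * math.pi * sig_i2))
    # log|−H| via the arrow determinant: |−H| = Π(−d) · (−a + Σ c²/d)
    h_img = -alpha * Se
    a = h_img.sum(axis=1) - 1.0 / sig_s2
    d = h_img - 1.0 / sig_i2
    c = h_img
    logdet = (np.log(-d).sum(axis=1)
              + np.log(-(a - (c * c / d).sum(axis=1)))).sum()
    # padded image slots (n=0) contribute a parameter-free constant: their
    # prior normalization cancels against their log-determinant term
    dim = C * (1 + M)
    return float(ll_obs + ll_prior + 0.5 * dim * math.log(2 * math.pi)
                 - 0.5 * logdet)


def fit_gamma_glmm(data: pd.DataFrame, spec: GlmmSpec | None = None,
                   reml: bool = True) -> GlmmFit:
    """Laplace-approximated fit of the gamma/log GLMM with nested intercepts.

    With ``reml=True`` (default) the variance components are estimated under
    a Cox–Reid adjusted profile likelihood: the objective carries a
    ``−½ log|X'V⁻¹X|`` penalty (computed from the expected fixed-effect
    information, which is closed-form here because genotype is constant
    within a sample), removing the downward bias of plain ML variance
    estimates with few samples per genotype. ``reml=False`` gives plain ML.
    """
    spec = spec or GlmmSpec()
    coef_names, N, S, L, Xeta, sample_ids = _prepare(data, spec)
    p = Xeta.shape[2]

    # cluster genotype index (0 = reference) and per-image counts for the
    # Cox-Reid term: cluster-mean variance v_c = σs² + Σ_j(σi² + 1/(α n_j))/m²
    gidx = np.zeros(N.shape[0], dtype=int)
    dummies = Xeta[:, 0, 1:]
    hit = dummies.argmax(axis=1)
    gidx = np.where(dummies.max(axis=1) > 0, hit + 1, 0)

    def cox_reid(params: np.ndarray) -> float:
        alpha = math.exp(min(params[p], 30.0))
        sig_s2 = math.exp(2 * np.clip(params[p + 1], -10, 10))
        sig_i2 = math.exp(2 * np.clip(params[p + 2], -10, 10))
        m_c = (N > 0).sum(axis=1)
        with np.errstate(divide="ignore"):
            per_img = np.where(N > 0, sig_i2 + 1.0 / (alpha * np.maximum(N, 1)),
                               0.0)
        v_c = sig_s2 + per_img.sum(axis=1) / np.maximum(m_c, 1) ** 2
        w_c = 1.0 / v_c
        logdet = 0.0
        for g in range(p):
            logdet += math.log(w_c[gidx == g].sum())
        return -0.5 * logdet

    # starting values from a fixed-effects gamma GLM
    import statsmodels.api as sm

    y = data[spec.response].to_numpy(dtype=float)
    gmap = {name[len("genotype["):-1]: i
            for i, name in enumerate(coef_names) if name != "intercept"}
    Xobs = np.zeros((len(y), p))
    Xobs[:, 0] = 1.0
    for i, g in enumerate(data[spec.genotype].astype(str)):
        if g in gmap:
            Xobs[i, gmap[g]] = 1.0
    glm = sm.GLM(y, Xobs, family=sm.families.Gamma(sm.families.links.Log())).fit()
    alpha0 = 1.0 / max(glm.scale, 1e-6)
    x0 = np.concatenate([glm.params, [math.log(alpha0), math.log(0.1),
                                      math.log(0.1)]])

    def nll(params: np.ndarray) -> float:
        val = _laplace_loglik(params, N, S, L, Xeta)
        if reml:
            val += cox_reid(params)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"gtol": 1e-5, "eps": 1e-6,
                                     "maxiter": 200})
    converged = bool(res.success)
    if not converged:
        # polish with a derivative-free pass; accept if the optimum moved
        # by less than the loglik convergence tolerance
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-6, "fatol": 1e-8,
                                          "maxiter": 2000})
        if res2.fun <= res.fun:
            rel = abs(res.fun - res2.fun) / max(abs(res2.fun), 1.0)
            converged = bool(res2.success) or rel < 1e-8
            res = res2
    params = res.x

    # model-based covariance from the numerical Hessian of -loglik; variance
    # components pinned at their boundary leave flat directions, which are
    # conditioned out rather than inverted
    hess = _numeric_hessian(nll, params)
    keep = np.where(np.diag(hess) > 1e-8)[0]
    if not set(range(p)).issubset(keep):
        raise InferenceError("singular information matrix for fixed effects")
    sub = np.linalg.pinv(hess[np.ix_(keep, keep)])
    cov_all = np.zeros((len(params), len(params)))
    cov_all[np.ix_(keep, keep)] = sub
    cov_beta = cov_all[:p, :p]
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    if np.any(se == 0):
        raise InferenceError("degenerate standard errors")
    return GlmmFit(coef_names=coef_names, beta=params[:p], se_beta=se,
                   cov_beta=cov_beta,
                   var_sample=float(math.exp(2 * params[p + 1])),
                   var_image=float(math.exp(2 * params[p + 2])),
                   shape=float(math.exp(params[p])),
                   loglik=float(-res.fun), converged=converged, spec=spec)


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0) / eps**2
    return H


# ---------------------------------------------------------------------------
# contrasts


def default_contrasts(fit: GlmmFit) -> dict[str, np.ndarray]:
    """The three prespecified comparisons in treatment coding:
    wild type vs Filamin-closed, wild type vs Drak-KO, and the epistasis
    contrast β_double − β_closed − β_ko (double mutant vs additivity)."""
    idx = {name: i for i, name in enumerate(fit.coef_names)}
    p = len(fit.coef_names)

    def unit(name: str, w: float = 1.0) -> np.ndarray:
        c = np.zeros(p)
        c[idx[name]] = w
        return c

    closed, ko, dbl = ("genotype[filamin_closed]", "genotype[drak_ko]",
                       "genotype[double]")
    return {
        "wt_vs_filamin_closed": unit(closed),
        "wt_vs_drak_ko": unit(ko),
        "double_vs_additive": unit(dbl) - unit(closed) - unit(ko),
    }


def wald_contrasts(fit: GlmmFit,
                   contrasts: dict[str, np.ndarray] | None = None
                   ) -> list[ContrastResult]:
    """Two-sided Wald z-tests of c'β with Bonferroni over the supplied set."""
    if contrasts is None:
        contrasts = default_contrasts(fit)
    m = len(contrasts)
    out = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.shape != fit.beta.shape:
            raise ValueError(f"contrast {name!r} has wrong length")
        est = float(c @ fit.beta)
        var = float(c @ fit.cov_beta @ c)
        if var <= 0:
            raise InferenceError(f"non-positive variance for contrast {name!r}")
        se = math.sqrt(var)
        z = est / se
        p_raw = float(2 * stats.norm.sf(abs(z)))
        out.append(ContrastResult(name=name, estimate=est, se=se, z=z,
                                  p_raw=p_raw,
                                  p_bonferroni=min(1.0, m * p_raw)))
    return out


# ---------------------------------------------------------------------------
# Western-blot fold change


def fold_change_ratio(band_table: pd.DataFrame,
                      reference_genotype: str = "wt") -> pd.DataFrame:
    """Per-lane ratio of phospho and total fold changes.

    Each intensity is normalized to the mean of the reference-genotype lanes
    of the same blot channel; the reported value is
    ``(phospho fold change) / (total fold change)``.
    """
    required = {"lane", "phospho_intensity", "total_intensity", "genotype"}
    if not required.issubset(band_table.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    if (band_table["total_intensity"] <= 0).any() or \
       (band_table["phospho_intensity"] <= 0).any():
        raise ValueError("band intensities must be positive")
    ref = band_table[band_table["genotype"] == reference_genotype]
    if ref.empty:
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    out = band_table.copy()
    out["fc_phospho"] = out["phospho_intensity"] / ref["phospho_intensity"].mean()
    out["fc_total"] = out["total_intensity"] / ref["total_intensity"].mean()
    out["ratio"] = out["fc_phospho"] / out["fc_total"]
    return out
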