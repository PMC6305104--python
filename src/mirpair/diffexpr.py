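"""Paired carcinoma-vs-normal differential expression.

The model for one gene is a negative binomial GLMM with a log link,

    y_it ~ NB(mu_it, theta),   log mu_it = beta_0 + beta_t * [t = carcinoma]
                                           + u_i + log N_it,

where i indexes subjects, t the tissue, u_i ~ Normal(0, sigma_u^2) is a
per-subject random intercept, N_it is the sample's total count over all
protein-coding genes (the exposure offset) and theta the NB size parameter
(variance mu + mu^2/theta). The marginal likelihood integrates u_i out by
Gauss-Hermite quadrature and is maximized over (beta_0, beta_t, theta,
sigma_u); the test of beta_t = 0 is a likelihood-ratio test by default (a
Wald test is available). A fixed-effects fallback (one intercept per subject,
fitted with statsmodels' NB regression) is provided for very small data where
the variance component is weakly identified.

Fold changes are reported as the ratio of arithmetic mean RPMPCG expression
in carcinoma over normal tissue, not as exp(beta_t): that is the convention
the reported tables follow. Multiple testing is controlled per analysis
(overall, MSS, MSI) with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess3

from .containers import CARCINOMA, NORMAL, NormalizedSet, PairedExpressionSet
from .normalization import rpmpcg_normalize

_SQRT2 = np.sqrt(2.0)
_ETA_MAX = 40.0  # cap on the log mean; exp(40) dwarfs any realistic count


@lru_cache(maxsize=None)
def _gh_nodes(n_quad: int):
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    return z, np.log(w) - 0.5 * np.log(np.pi)


def _nb_logpmf(y, mu, theta):
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _paired_arrays(y: pd.Series, subject_of: pd.Series, tissue_of: pd.Series, offsets: pd.Series):
    """Reshape per-sample values into (n_subjects, 2) arrays, col 0 normal, col 1 carcinoma."""
    samples = list(y.index)
    sub = subject_of.loc[samples]
    tis = tissue_of.loc[samples]
    subjects = list(dict.fromkeys(sub))
    idx = {(sub.loc[s], tis.loc[s]): s for s in samples}
    cols = {}
    for j, t in enumerate((NORMAL, CARCINOMA)):
        try:
            cols[j] = [idx[(subj, t)] for subj in subjects]
        except KeyError as e:  # incomplete pair
            raise ValueError(f"incomplete pair: missing sample for {e.args[0]}") from None
    Y = np.column_stack([y.loc[cols[0]].to_numpy(float), y.loc[cols[1]].to_numpy(float)])
    OFF = np.column_stack([offsets.loc[cols[0]].to_numpy(float), offsets.loc[cols[1]].to_numpy(float)])
    return Y, OFF


def _marginal_nll(Y, OFF, z, logw, beta0, beta_t, log_theta, log_sigma):
    theta = np.exp(log_theta)
    sigma = np.exp(log_sigma)
    eta = beta0 + OFF
    eta = eta + np.array([0.0, beta_t])  # carcinoma column
    eta = eta[:, :, None] + _SQRT2 * sigma * z[None, None, :]
    mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
    lp = _nb_logpmf(Y[:, :, None], mu, theta).sum(axis=1)  # (n, K)
    return -float(logsumexp(lp + logw, axis=1).sum())


@dataclass
class DEFit:
    """Result of the per-gene paired NB fit."""

    beta_t: float
    se: float
    p_raw: float
    theta: float
    sigma_u: float
    loglik: float
    converged: bool
    flag: str = ""
    n_pairs: int = 0


def _start_values(Y, OFF):
    expo = np.exp(OFF - OFF.max())
    scale = np.exp(OFF.max())
    m_n = max(Y[:, 0].sum() / (expo[:, 0].sum() * scale), 1e-12)
    m_c = max(Y[:, 1].sum() / (expo[:, 1].sum() * scale), 1e-12)
    b0 = np.log(m_n)
    bt = np.log(m_c / m_n)
    mu = np.exp(np.clip(np.column_stack([b0 + OFF[:, 0], b0 + bt + OFF[:, 1]]), -_ETA_MAX, _ETA_MAX))
    phi = ((Y - mu) ** 2 - mu).sum() / max((mu**2).sum(), 1e-12)
    theta0 = 1.0 / min(max(phi, 1e-3), 100.0)
    return b0, bt, np.log(theta0), np.log(0.3)


def _optimize(fun, x0, bounds):
    """L-BFGS-B with a Nelder-Mead polish when the line search degenerates.

    Near-flat likelihoods (e.g. the Poisson limit, where theta runs to its
    bound) can make quasi-Newton line searches report failure at what is in
    fact the optimum; the simplex restart resolves those cases.
    """
    res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        polish = minimize(fun, res.x, method="Nelder-Mead", bounds=bounds,
                          options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
        if polish.fun <= res.fun:
            res = polish
    return res


def fit_paired_nb(
    y: pd.Series,
    subject_of: pd.Series,
    tissue_of: pd.Series,
    offsets: pd.Series,
    method: str = "random",
    test: str = "lrt",
    n_quad: int = 25,
) -> DEFit:
    """Fit the paired NB model for one gene and test the tumor effect.

    Parameters
    ----------
    y
        Raw counts indexed by sample ID.
    subject_of, tissue_of
        Sample-to-subject and sample-to-tissue maps covering ``y``'s index.
    offsets
        Log exposure per sample (log of the protein-coding total).
    method
        ``"random"`` (Gauss-Hermite ML over a Normal random intercept) or
        ``"fixed"`` (per-subject fixed intercepts via statsmodels NB
        regression).
    test
        ``"lrt"`` or ``"wald"`` for the p-value of beta_t = 0.
    """
    if test not in ("lrt", "wald"):
        raise ValueError("test must be 'lrt' or 'wald'")
    Y, OFF = _paired_arrays(y, subject_of, tissue_of, offsets)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if not Y.any():
        return DEFit(0.0, np.nan, 1.0, np.nan, np.nan, 0.0, False, flag="all_zero", n_pairs=n)
    if method == "fixed":
        return _fit_fixed(Y, OFF, test)
    if method != "random":
        raise ValueError("method must be 'random' or 'fixed'")

    z, logw = _gh_nodes(n_quad)
    b0, bt, lt, ls = _start_values(Y, OFF)
    bounds_full = [(-50, 20), (-20, 20), (-7, 12), (-7, 2.5)]

    def nll_full(p):
        return _marginal_nll(Y, OFF, z, logw, p[0], p[1], p[2], p[3])

    def nll_null(p):
        return _marginal_nll(Y, OFF, z, logw, p[0], 0.0, p[1], p[2])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full = _optimize(nll_full, [b0, bt, lt, ls], bounds_full)
        null = _optimize(nll_null, [b0, lt, ls], [bounds_full[0]] + bounds_full[2:])

    beta_t = float(full.x[1])
    ll_full, ll_null = -full.fun, -null.fun
    flag = "" if (full.success and null.success) else "non_converged"

    se = np.nan
    if test == "wald" or flag == "":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess3(full.x, nll_full)
                cov = np.linalg.inv(H)
                se = float(np.sqrt(max(cov[1, 1], 0.0)))
        except (np.linalg.LinAlgError, ValueError):
            se = np.nan

    if flag:
        p_raw = np.nan
    elif test == "lrt":
        lr = max(0.0, 2.0 * (ll_full - ll_null))
        p_raw = float(chi2.sf(lr, df=1))
    else:
        if not np.isfinite(se) or se == 0:
            p_raw, flag = np.nan, "non_converged"
        else:
            p_raw = float(2.0 * norm.sf(abs(beta_t) / se))

    return DEFit(
        beta_t=beta_t,
        se=se,
        p_raw=p_raw,
        theta=float(np.exp(full.x[2])),
        sigma_u=float(np.exp(full.x[3])),
        loglik=ll_full,
        converged=flag == "",
        flag=flag,
        n_pairs=n,
    )


def _fit_fixed(Y, OFF, test: str) -> DEFit:
    """Per-subject fixed-intercept NB regression (small-data fallback)."""
    import statsmodels.api as sm

    n = Y.shape[0]
    y = Y.ravel()  # subject-major: [normal_i, carcinoma_i]
    off = OFF.ravel()
    tumor = np.tile([0.0, 1.0], n)
    dummies = np.repeat(np.eye(n), 2, axis=0)
    X_full = np.column_stack([dummies, tumor])
    X_null = dummies
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.NegativeBinomial(y, X_full, offset=off).fit(disp=0, maxiter=500)
        nullm = sm.NegativeBinomial(y, X_null, offset=off).fit(disp=0, maxiter=500)
    beta_t = float(full.params[n])
    se = float(full.bse[n])
    converged = bool(full.mle_retvals.get("converged", True) and nullm.mle_retvals.get("converged", True))
    if not converged:
        return DEFit(beta_t, se, np.nan, np.nan, 0.0, float(full.llf), False, flag="non_converged", n_pairs=n)
    if test == "lrt":
        lr = max(0.0, 2.0 * (full.llf - nullm.llf))
        p_raw = float(chi2.sf(lr, df=1))
    else:
        p_raw = float(2.0 * norm.sf(abs(beta_t) / se))
    theta = float(1.0 / full.params[-1]) if full.params[-1] > 0 else np.nan
    return DEFit(beta_t, se, p_raw, theta, 0.0, float(full.llf), True, n_pairs=n)


# -- summaries over normalized values ---------------------------------------


def fold_change(normalized: NormalizedSet, gene: str):
    """Arithmetic-mean expression per tissue and their ratio (carcinoma/normal).

    Returns ``(mean_carcinoma, mean_normal, fc)``; ``fc`` is NaN when the
    normal-tissue mean is zero.
    """
    if gene not in normalized.feature_ids:
        raise KeyError(f"gene {gene!r} not in the normalized set")
    mc = float(normalized.tissue_values(CARCINOMA).loc[gene].mean())
    mn = float(normalized.tissue_values(NORMAL).loc[gene].mean())
    fc = mc / mn if mn > 0 else np.nan
    return mc, mn, fc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fc_gate(records: pd.DataFrame, low: float = 0.67, high: float = 1.50, fdr: float = 0.05) -> list[str]:
    """Genes with adjusted p <= ``fdr`` and fold change > ``high`` or < ``low``.

    The FC inequalities are strict (a gene printed at exactly 1.50 is not
    admitted); the FDR threshold is inclusive. ``records`` needs columns
    ``gene``, ``fc`` and ``p_adj``.
    """
    mask = (records["p_adj"] <= fdr) & ((records["fc"] > high) | (records["fc"] < low))
    return records.loc[mask.fillna(False), "gene"].tolist()


def stratum_unique(overall_pass, stratum_pass) -> set[str]:
    """Genes gated in a stratum (MSS or MSI) but not in the overall analysis."""
    return set(stratum_pass) - set(overall_pass)


class PairedNBDE(BaseEstimator):
    """Paired NB differential expression over a gene panel.

    ``fit`` takes the raw count :class:`PairedExpressionSet`; offsets, RPMPCG
    means and fold changes are derived internally. Fitted attributes:

    results_ : DataFrame
        One row per analyzed gene: mean_carcinoma, mean_normal, fc, beta_t,
        p_raw, p_adj, passes_fc_gate, flag, stratum.
    passed_genes_ : list of str
        Genes admitted by the FC/FDR gate.
    """

    def __init__(
        self,
        genes=None,
        method: str = "random",
        test: str = "lrt",
        fc_low: float = 0.67,
        fc_high: float = 1.50,
        alpha: float = 0.05,
        n_quad: int = 25,
        stratum: str = "overall",
    ):
        self.genes = genes
        self.method = method
        self.test = test
        self.fc_low = fc_low
        self.fc_high = fc_high
        self.alpha = alpha
        self.n_quad = n_quad
        self.stratum = stratum

    def fit(self, counts: PairedExpressionSet, protein_coding_ids=None):
        pc = list(protein_coding_ids) if protein_coding_ids is not None else list(counts.feature_ids)
        totals = counts.values.loc[pc].sum(axis=0).astype(float)
        zero = totals.index[totals <= 0]
        if len(zero):
            raise ValueError(f"zero protein-coding total in sample(s) {list(zero)[:5]}")
        offsets = np.log(totals)
        normalized = rpmpcg_normalize(counts, pc)
        genes = list(self.genes) if self.genes is not None else list(counts.feature_ids)

        rows = []
        for g in genes:
            fit = fit_paired_nb(
                counts.values.loc[g],
                counts.subject_of,
                counts.tissue_of,
                offsets,
                method=self.method,
                test=self.test,
                n_quad=self.n_quad,
            )
            mc, mn, fc = fold_change(normalized, g)
            rows.append(
                {
                    "gene": g,
                    "mean_carcinoma": mc,
                    "mean_normal": mn,
                    "fc": fc,
                    "beta_t": fit.beta_t,
                    "p_raw": fit.p_raw,
                    "flag": fit.flag,
                    "stratum": self.stratum,
                }
            )
        res = pd.DataFrame(rows)
        ok = res["p_raw"].notna()
        if (~ok).any():
            bad = res.loc[~ok, "gene"].tolist()
            warnings.warn(
                f"{len(bad)} gene(s) excluded from the FDR family (non-convergent or all-zero): {bad[:5]}",
                stacklevel=2,
            )
        res["p_adj"] = np.nan
        res.loc[ok, "p_adj"] = bh_adjust(res.loc[ok, "p_raw"].to_numpy())
        gated = set(fc_gate(res, self.fc_low, self.fc_high, self.alpha))
        res["passes_fc_gate"] = res["gene"].isin(gated)
        self.results_ = res
        self.normalized_ = normalized
        self.offsets_ = offsets
        self.passed_genes_ = [g for g in res["gene"] if g in gated]
        return self
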