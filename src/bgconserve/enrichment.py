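"""Genus-level enrichment of BGC counts.

Per BGC class, counts per genome are modelled as negative binomial with a
genus-only log-linear mean, ``log mu_i = b0 + b_genus(i)``, the reference
genus absorbed into the intercept.  The NB dispersion is estimated by
maximum likelihood (statsmodels NB2).  Reported per genus: the fitted mean
count per genome on a log10 scale, a 95% Wald interval on the linear
predictor (transformed to log10), and the Wald p-value of the genus
contrast against the reference.  When the ML dispersion indicates
Poisson-like data (theta above 1e6), the model falls back to a Poisson GLM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("bgconserve")

#: dispersion above which the NB is considered Poisson-like
POISSON_THETA = 1e6


@dataclass
class EnrichmentResult:
    class_name: str
    reference_genus: str
    per_genus: pd.DataFrame  # genus, n, log10_mean, ci_low, ci_high, p_value
    dispersion: float  # theta = 1 / alpha
    converged: bool
    model: str = "negative_binomial"


def select_top_genera(table, k: int = 7) -> list[str]:
    """The ``k`` genera with the most genomes; ties broken lexicographically."""
    if table.metadata is None or "genus" not in table.metadata.columns:
        raise ValueError("metadata with a 'genus' column required")
    counts = table.metadata["genus"].value_counts()
    order = sorted(counts.index, key=lambda g: (-counts[g], g))
    if len(order) < k:
        warnings.warn(f"only {len(order)} genera present; returning all", stacklevel=2)
        return order
    return order[:k]


def nb_enrichment(
    table,
    class_name: str,
    reference_genus: str,
    min_group_size: int = 5,
) -> EnrichmentResult:
    """Fit the per-class genus model and report per-genus enrichment.

    Genera with fewer than ``min_group_size`` genomes are pooled into
    ``"other"`` and excluded from the report (the pool still informs the
    dispersion estimate).
    """
    if class_name not in table.class_names:
        raise ValueError(f"unknown class {class_name!r}")
    if table.metadata is None or "genus" not in table.metadata.columns:
        raise ValueError("metadata with a 'genus' column required")
    y = table.counts[class_name].to_numpy(dtype=float)
    genus = table.metadata["genus"].astype(str).to_numpy()

    sizes = pd.Series(genus).value_counts()
    small = set(sizes.index[sizes < min_group_size])
    if reference_genus in small or reference_genus not in sizes.index:
        raise ValueError(
            f"reference genus {reference_genus!r} absent or below "
            f"min_group_size={min_group_size}"
        )
    genus = np.array([g if g not in small else "other" for g in genus])
    if y.sum() == 0:
        raise ValueError(f"class {class_name!r} has zero counts everywhere")

    levels = [reference_genus] + sorted(set(genus) - {reference_genus})
    codes = pd.Categorical(genus, categories=levels).codes
    X = np.zeros((len(y), len(levels)))
    X[:, 0] = 1.0
    for j in range(1, len(levels)):
        X[codes == j, j] = 1.0

    beta, cov, theta, converged, model_name = _fit_nb(y, X)

    z = stats.norm.ppf(0.975)
    ln10 = np.log(10.0)
    rows = []
    for j, g in enumerate(levels):
        if g == "other":
            continue
        a = np.zeros(len(levels))
        a[0] = 1.0
        if j > 0:
            a[j] = 1.0
        eta = float(a @ beta)
        se = float(np.sqrt(a @ cov[: len(levels), : len(levels)] @ a))
        if j == 0:
            p = 1.0
        else:
            bj, sj = beta[j], np.sqrt(cov[j, j])
            p = float(2 * stats.norm.sf(abs(bj / sj))) if sj > 0 else float("nan")
        rows.append(
            {
                "genus": g,
                "n": int((codes == j).sum()),
                "log10_mean": eta / ln10,
                "ci_low": (eta - z * se) / ln10,
                "ci_high": (eta + z * se) / ln10,
                "p_value": p,
            }
        )
    return EnrichmentResult(
        class_name=class_name,
        reference_genus=reference_genus,
        per_genus=pd.DataFrame(rows),
        dispersion=theta,
        converged=converged,
        model=model_name,
    )


def _fit_nb(y: np.ndarray, X: np.ndarray):
    """NB2 ML fit with Poisson fallback for vanishing overdispersion.

    Returns ``(beta, cov_beta, theta, converged, model_name)`` where cov
    covers the linear coefficients only.
    """
    p = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomial(y, X, loglike_method="nb2")
            fit = nb.fit(disp=0, maxiter=200, method="bfgs")
        alpha = float(fit.params[-1])
        converged = bool(fit.mle_retvals.get("converged", False))
        if alpha > 1e-8 and np.isfinite(fit.bse[:p]).all():
            theta = 1.0 / alpha
            if theta <= POISSON_THETA:
                return (
                    np.asarray(fit.params[:p]),
                    np.asarray(fit.cov_params())[:p, :p],
                    theta,
                    converged,
                    "negative_binomial",
                )
    except Exception as exc:  # singular Hessian, separation, ...
        logger.warning("NB fit failed (%s); falling back to Poisson", exc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return (
        np.asarray(glm.params),
        np.asarray(glm.cov_params()),
        float("inf"),
        True,
        "poisson",
    )
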