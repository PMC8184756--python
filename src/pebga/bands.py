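"""Which frequency bands carry prediction-error information?

Per recording site, trial-wise band-power features (gamma and beta averaged
over 0.25-1 s; theta/alpha averaged over the early 0-0.5 s and late 0.5-1 s
windows) are used to predict the PE regressor in a family of linear models:
the gamma-only model plus gamma combined with every non-empty subset of
{beta, early theta/alpha, late theta/alpha} — eight models. Model evidence
is approximated as -BIC/2 under a Gaussian likelihood, and site-wise
evidences feed a random-effects Bayesian model selection (variational
Dirichlet update) yielding expected frequencies (Ef) and exceedance
probabilities (Xp).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .preprocessing import EpochedPower

WINDOW_HIGH = (0.25, 1.0)
WINDOW_EARLY = (0.0, 0.5)
WINDOW_LATE = (0.5, 1.0)

FEATURES = ("gamma", "beta", "ta_early", "ta_late")

#: gamma-only first, then gamma plus every non-empty low-frequency subset
MODEL_SPACE: list[tuple[str, ...]] = [("gamma",)] + [
    ("gamma",) + combo
    for r in (1, 2, 3)
    for combo in itertools.combinations(("beta", "ta_early", "ta_late"), r)
]


def band_feature_table(
    gamma: EpochedPower, beta: EpochedPower, theta_alpha: EpochedPower
) -> pd.DataFrame:
    """Window-averaged, z-scored band-power features for one site.

    The three epoch sets must share the trial grid. Raises if a feature is
    constant across trials (zero variance carries no information).
    """
    if not (gamma.n_trials == beta.n_trials == theta_alpha.n_trials):
        raise ValueError("band epochs must share the trial set")
    cols = {
        "gamma": gamma.window_mean(WINDOW_HIGH),
        "beta": beta.window_mean(WINDOW_HIGH),
        "ta_early": theta_alpha.window_mean(WINDOW_EARLY),
        "ta_late": theta_alpha.window_mean(WINDOW_LATE),
    }
    out = {}
    for name, v in cols.items():
        sd = v.std(ddof=0)
        if sd == 0.0:
            raise ValueError(f"band feature {name!r} has zero variance")
        out[name] = (v - v.mean()) / sd
    return pd.DataFrame(out)


def band_glm_evidence(
    features: pd.DataFrame, pe: np.ndarray, model: tuple[str, ...]
) -> float:
    """Log evidence (BIC approximation) of one band-combination GLM at one site.

    OLS of the z-scored PE on the model's feature subset plus intercept;
    log evidence = -BIC/2 with BIC = n ln(RSS/n) + k ln(n), k counting the
    fitted coefficients.
    """
    X = np.column_stack([np.ones(len(features))] + [features[f].to_numpy() for f in model])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(f"collinear feature subset {model}")
    pe = np.asarray(pe, dtype=float)
    beta_hat, *_ = np.linalg.lstsq(X, pe, rcond=None)
    rss = float(((pe - X @ beta_hat) ** 2).sum())
    n, k = X.shape
    bic = n * np.log(rss / n) + k * np.log(n)
    return -bic / 2.0


def model_evidence_table(
    features_by_site: list[pd.DataFrame], pe_by_site: list[np.ndarray]
) -> np.ndarray:
    """Sites x models log-evidence matrix over the fixed model space."""
    rows = []
    for feats, pe in zip(features_by_site, pe_by_site):
        rows.append([band_glm_evidence(feats, pe, m) for m in MODEL_SPACE])
    return np.asarray(rows)


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection posterior."""

    expected_frequency: np.ndarray  # Ef, sums to 1
    exceedance_probability: np.ndarray  # Xp, sums to 1
    dirichlet_alpha: np.ndarray
    model_names: list[str]

    def best_model(self) -> str:
        return self.model_names[int(np.argmax(self.exceedance_probability))]


def rfx_bms(
    log_evidence: np.ndarray,
    alpha0: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_samples: int = 100_000,
    rng: np.random.Generator | int = 0,
    model_names: list[str] | None = None,
) -> BMSResult:
    """Random-effects BMS over a sites x models log-evidence matrix.

    Variational fixed point for the Dirichlet posterior over model
    frequencies: each site's model assignment posterior is
    ``u_nk ∝ exp(ln E_nk + ψ(α_k) − ψ(Σα))``, and ``α = α0 + Σ_n u_n``.
    Ef is the Dirichlet mean; Xp — the probability that each model is the
    most frequent in the population — is estimated by seeded Monte-Carlo
    sampling of the posterior Dirichlet.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need a (>=2 sites) x (>=2 models) evidence matrix")
    if not np.isfinite(L).all():
        raise ValueError("log evidences must be finite")
    rng = np.random.default_rng(rng)
    n, K = L.shape
    alpha = np.full(K, alpha0)
    for _ in range(max_iter):
        ln_u = L + digamma(alpha) - digamma(alpha.sum())
        ln_u -= ln_u.max(axis=1, keepdims=True)
        u = np.exp(ln_u)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    ef = alpha / alpha.sum()
    draws = rng.dirichlet(alpha, size=n_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples
    names = model_names if model_names is not None else ["+".join(m) for m in MODEL_SPACE[:K]]
    return BMSResult(
        expected_frequency=ef, exceedance_probability=xp, dirichlet_alpha=alpha,
        model_names=names,
    )
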