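"""Trial-wise regression of band power and its inference machinery.

Per time point, normalized power is regressed across trials on prediction
error (or on outcome + expectation jointly). Site-level significance is
assessed with Benjamini-Hochberg FDR over the 0-1.5 s window (97 time
points at 64 Hz) with a 100-ms minimum-duration rule; parcel-level
screening uses a fixed-effect t-test on 0.25-1 s window-averaged betas,
Bonferroni-corrected across parcels; timecourse inference within an ROI
uses cluster-based permutation of the trial/regressor pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import ENVELOPE_RATE, EpochedPower

WINDOW_FDR = (0.0, 1.5)
WINDOW_EFFECT = (0.25, 1.0)
WINDOW_PRE_OUTCOME = (-1.2, -0.2)
MIN_DURATION = 0.100  # s; >= 7 consecutive samples at 64 Hz


@dataclass
class RegressionTimecourse:
    """OLS estimates per time point for one site and one regressor set."""

    betas: np.ndarray  # (n_regressors, n_times)
    t: np.ndarray
    p: np.ndarray
    times: np.ndarray
    n_trials: int
    regressor_names: list[str]

    def regressor(self, name: str) -> int:
        return self.regressor_names.index(name)


def pointwise_regression(
    epochs: EpochedPower,
    regressors: np.ndarray | dict[str, np.ndarray],
    covariates: dict[str, np.ndarray] | None = None,
    trial_mask: np.ndarray | None = None,
) -> RegressionTimecourse:
    """OLS of power on regressor(s), independently at every time point.

    ``regressors`` is a vector (single regressor) or an ordered name->vector
    mapping; covariates are appended to the design but reported too. An
    intercept is always included. Artifact-masked trials are excluded via
    ``epochs.artifact_mask`` and, optionally, an extra ``trial_mask``.
    """
    if isinstance(regressors, np.ndarray):
        regressors = {"x": regressors}
    names = list(regressors)
    cols = [np.asarray(regressors[n], dtype=float) for n in names]
    if covariates:
        for n, v in covariates.items():
            names.append(n)
            cols.append(np.asarray(v, dtype=float))

    keep = epochs.good_trials()
    if trial_mask is not None:
        keep = keep & trial_mask
    Y = epochs.data[keep]
    X = np.column_stack([np.ones(keep.sum())] + [c[keep] for c in cols])
    n, k = X.shape
    if n <= k:
        raise ValueError(f"too few trials ({n}) for {k - 1} regressors")
    for j, nm in enumerate(names):
        if X[:, j + 1].std() == 0.0:
            raise ValueError(f"regressor {nm!r} has zero variance")

    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # (k, n_times)
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = B / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return RegressionTimecourse(
        betas=B[1:], t=tval[1:], p=np.clip(pval[1:], np.finfo(float).tiny, 1.0),
        times=epochs.times, n_trials=n, regressor_names=names,
    )


def _prune_short_runs(mask: np.ndarray, min_samples: int) -> np.ndarray:
    """Zero out True-runs shorter than min_samples."""
    out = mask.copy()
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_samples:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


@dataclass
class SiteStats:
    """FDR-corrected site-level significance and window-averaged effect size."""

    site_id: str
    significant_mask: np.ndarray  # over the full time grid
    any_significant: bool
    window_beta: float
    n_comparisons: int


def site_fdr_significance(
    tc: RegressionTimecourse,
    site_id: str = "",
    regressor: int = 0,
    window: tuple[float, float] = WINDOW_FDR,
    q: float = 0.05,
    min_duration: float = MIN_DURATION,
    effect_window: tuple[float, float] = WINDOW_EFFECT,
    rate: float = ENVELOPE_RATE,
) -> SiteStats:
    """Benjamini-Hochberg over the in-window p-values, with a minimum-duration
    rule discarding significant runs shorter than 100 ms (7 samples at 64 Hz)."""
    in_win = (tc.times >= window[0]) & (tc.times <= window[1])
    pvals = tc.p[regressor, in_win]
    rej, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    min_samples = int(np.ceil(min_duration * rate)) + 1  # > 100 ms at 64 Hz -> 7 samples
    rej = _prune_short_runs(rej, min_samples)
    mask = np.zeros(len(tc.times), dtype=bool)
    mask[np.where(in_win)[0]] = rej
    eff = (tc.times >= effect_window[0]) & (tc.times <= effect_window[1])
    return SiteStats(
        site_id=site_id, significant_mask=mask, any_significant=bool(rej.any()),
        window_beta=float(tc.betas[regressor, eff].mean()), n_comparisons=int(in_win.sum()),
    )


@dataclass
class ParcelStats:
    parcel: str
    n_sites: int
    mean_beta: float
    t: float
    p_uncorrected: float
    p_bonferroni: float
    proportion_significant: float
    selected: bool


def parcel_fixed_effect(
    site_stats: list[SiteStats],
    parcel_map: dict[str, str],
    n_parcels: int | None = None,
    alpha: float = 0.05,
    prop_threshold: float = 0.20,
) -> list[ParcelStats]:
    """Fixed-effect screening: one-sample t across a parcel's pooled sites on
    window-averaged betas, Bonferroni across parcels; a parcel is selected iff
    corrected-significant AND its proportion of individually (FDR) significant
    sites is strictly greater than ``prop_threshold``."""
    groups: dict[str, list[SiteStats]] = {}
    for s in site_stats:
        parcel = parcel_map.get(s.site_id)
        if parcel is None:
            continue
        groups.setdefault(parcel, []).append(s)
    tested = {p: g for p, g in groups.items() if len(g) >= 2}
    for p, g in groups.items():
        if len(g) < 2:
            warnings.warn(f"parcel {p} has a single site; excluded from screening")
    n_tests = n_parcels if n_parcels is not None else len(tested)
    out = []
    for parcel, g in tested.items():
        betas = np.array([s.window_beta for s in g])
        t, p = stats.ttest_1samp(betas, 0.0)
        p_b = min(1.0, float(p) * n_tests)
        prop = float(np.mean([s.any_significant for s in g]))
        out.append(
            ParcelStats(
                parcel=parcel, n_sites=len(g), mean_beta=float(betas.mean()),
                t=float(t), p_uncorrected=float(p), p_bonferroni=p_b,
                proportion_significant=prop,
                selected=bool(p_b < alpha and prop > prop_threshold),
            )
        )
    return out


@dataclass
class Cluster:
    start_time: float
    end_time: float
    mass: float  # summed group t over the cluster
    p_corrected: float

    @property
    def sign(self) -> int:
        return 1 if self.mass > 0 else -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    group_t: np.ndarray
    times: np.ndarray
    threshold: float
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < alpha]


def _site_betas_matrix(Y_by_site: list[np.ndarray], x_by_site: list[np.ndarray]) -> np.ndarray:
    """Per-site single-regressor OLS betas per time point.

    With the regressor z-scored per site, beta(t) = x . Y(t) / n exactly
    (intercept absorbed by the zero mean of x).
    """
    betas = []
    for Y, x in zip(Y_by_site, x_by_site):
        xz = (x - x.mean()) / x.std(ddof=0)
        betas.append(xz @ Y / len(xz))
    return np.asarray(betas)  # (n_sites, n_times)


def _clusters_from_t(tvals: np.ndarray, tcrit: float) -> list[tuple[int, int, float]]:
    """Contiguous same-sign runs of |t| strictly above threshold; (start, stop, mass)."""
    sig = np.abs(tvals) > tcrit
    out = []
    i, n = 0, len(tvals)
    while i < n:
        if sig[i]:
            s = np.sign(tvals[i])
            j = i
            while j < n and sig[j] and np.sign(tvals[j]) == s:
                j += 1
            out.append((i, j, float(tvals[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def _group_t(betas: np.ndarray) -> np.ndarray:
    """One-sample t across sites, per time point."""
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def cluster_permutation(
    Y_by_site: list[np.ndarray],
    x_by_site: list[np.ndarray],
    times: np.ndarray,
    n_perm: int = 60_000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> ClusterResult:
    """Cluster-based permutation test of a group PE effect over time.

    Observed statistic: one-sample t across sites of per-site regression
    betas at each time point. Clusters are contiguous same-sign runs with
    two-sided pointwise p < ``cluster_alpha``; cluster mass is the summed t.
    The null shuffles the trial/regressor pairing independently per site
    (trials are not aligned across patients) and records the maximal
    absolute cluster mass per iteration; corrected p is the (1+r)/(1+n) rank
    estimate, two-sided via the shared max-|mass| null.
    """
    if len(Y_by_site) < 2:
        raise ValueError("cluster permutation needs at least 2 sites")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value floor of {1 / (1 + n_perm):.3g}")
    rng = np.random.default_rng(rng)
    n_sites = len(Y_by_site)
    dof = n_sites - 1
    tcrit = stats.t.ppf(1.0 - cluster_alpha / 2.0, dof)

    obs_betas = _site_betas_matrix(Y_by_site, x_by_site)
    obs_t = _group_t(obs_betas)
    obs_clusters = _clusters_from_t(obs_t, tcrit)

    # permutation null, chunked to bound memory: per chunk accumulate the
    # across-site first and second moments of permuted betas
    n_times = obs_betas.shape[1]
    null_max = np.zeros(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(n_times, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        s1 = np.zeros((m, n_times))
        s2 = np.zeros((m, n_times))
        for Y, x in zip(Y_by_site, x_by_site):
            xz = (x - x.mean()) / x.std(ddof=0)
            P = np.empty((m, len(xz)))
            for i in range(m):
                P[i] = rng.permutation(xz)
            b = P @ Y / len(xz)
            s1 += b
            s2 += b * b
        mean = s1 / n_sites
        var = (s2 - n_sites * mean**2) / (n_sites - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_t = mean / np.sqrt(var / n_sites)
        for i in range(m):
            cl = _clusters_from_t(perm_t[i], tcrit)
            if cl:
                null_max[done + i] = max(abs(mm) for *_, mm in cl)
        done += m

    clusters = []
    for a, b, mass in obs_clusters:
        p_c = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(start_time=float(times[a]), end_time=float(times[b - 1]),
                                mass=mass, p_corrected=float(p_c)))
    return ClusterResult(clusters=clusters, group_t=obs_t, times=times,
                         threshold=float(tcrit), n_permutations=n_perm)


def condition_contrast_timecourse(
    Y_by_site: list[np.ndarray],
    rpe_by_site: list[np.ndarray],
    ppe_by_site: list[np.ndarray],
    reward_mask_by_site: list[np.ndarray],
    times: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, ClusterResult]:
    """RPE-vs-PPE contrast of regression estimates, cluster-tested across sites.

    For each site, beta_RPE(t) is fitted on reward trials and beta_PPE(t) on
    punishment trials; the contrast beta_RPE - beta_PPE is tested across
    sites with the same permutation scheme, shuffling the trial/regressor
    pairing within each condition. Returns (beta_RPE, beta_PPE) site x time
    arrays and the contrast ClusterResult.
    """
    rng = np.random.default_rng(rng)
    n_sites = len(Y_by_site)
    if n_sites < 2:
        raise ValueError("contrast needs at least 2 sites")
    for m in reward_mask_by_site:
        if m.sum() < 10 or (~m).sum() < 10:
            raise ValueError("each condition needs at least 10 trials per site")

    def betas_for(perm: bool) -> tuple[np.ndarray, np.ndarray]:
        br, bp = [], []
        for Y, xr, xp, m in zip(Y_by_site, rpe_by_site, ppe_by_site, reward_mask_by_site):
            xr_c, xp_c = xr[m], xp[~m]
            if perm:
                xr_c = rng.permutation(xr_c)
                xp_c = rng.permutation(xp_c)
            xr_z = (xr_c - xr_c.mean()) / xr_c.std(ddof=0)
            xp_z = (xp_c - xp_c.mean()) / xp_c.std(ddof=0)
            br.append(xr_z @ Y[m] / len(xr_z))
            bp.append(xp_z @ Y[~m] / len(xp_z))
        return np.asarray(br), np.asarray(bp)

    beta_r, beta_p = betas_for(perm=False)
    dof = n_sites - 1
    tcrit = stats.t.ppf(1.0 - cluster_alpha / 2.0, dof)
    obs_t = _group_t(beta_r - beta_p)
    obs_clusters = _clusters_from_t(obs_t, tcrit)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        br, bp = betas_for(perm=True)
        cl = _clusters_from_t(_group_t(br - bp), tcrit)
        if cl:
            null_max[i] = max(abs(m) for *_, m in cl)
    clusters = [
        Cluster(start_time=float(times[a]), end_time=float(times[b - 1]), mass=mass,
                p_corrected=float((1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)))
        for a, b, mass in obs_clusters
    ]
    res = ClusterResult(clusters=clusters, group_t=obs_t, times=times,
                        threshold=float(tcrit), n_permutations=n_perm)
    return beta_r, beta_p, res


def outcome_contrast_by_phase(
    Y_by_site: list[np.ndarray],
    outcome_nonzero_by_site: list[np.ndarray],
    trial_phase_by_site: list[np.ndarray],  # True = late
    times: np.ndarray,
    window: tuple[float, float] = WINDOW_EFFECT,
) -> dict:
    """Model-free outcome contrast (non-zero vs zero) in early vs late trials.

    Window-averaged BGA difference per site and phase, a one-sample t per
    phase across sites, and a paired t on the early-late difference (the
    phase interaction). In the reinforcement-learning account this contrast
    should be stationary across learning.
    """
    win = (times >= window[0]) & (times <= window[1])
    early, late = [], []
    for Y, nz, ph in zip(Y_by_site, outcome_nonzero_by_site, trial_phase_by_site):
        w = Y[:, win].mean(axis=1)
        for dest, m_ph in ((early, ~ph), (late, ph)):
            sel_nz = m_ph & nz
            sel_z = m_ph & ~nz
            if sel_nz.sum() == 0 or sel_z.sum() == 0:
                raise ValueError("a phase lacks zero or non-zero outcomes")
            dest.append(w[sel_nz].mean() - w[sel_z].mean())
    early, late = np.asarray(early), np.asarray(late)
    t_e, p_e = stats.ttest_1samp(early, 0.0)
    t_l, p_l = stats.ttest_1samp(late, 0.0)
    d = early - late
    if np.allclose(d, 0.0):
        t_i, p_i = 0.0, 1.0
    else:
        t_i, p_i = stats.ttest_rel(early, late)
    return {
        "early_contrast_mean": float(early.mean()), "early_t": float(t_e), "early_p": float(p_e),
        "late_contrast_mean": float(late.mean()), "late_t": float(t_l), "late_p": float(p_l),
        "interaction_t": float(t_i), "interaction_p": float(p_i),
    }
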