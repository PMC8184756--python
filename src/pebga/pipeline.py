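"""End-to-end orchestration: behavior -> envelopes -> epochs -> statistics.

The pipeline mirrors the analysis sequence of the study it emulates:
Q-learning (QLr) behavioral fits and model comparison, broadband-gamma
extraction, trial-wise PE regression with site-level FDR and parcel-level
fixed-effect screening, the reward-vs-punishment PE contrast, the
outcome/expectation decomposition, and frequency-band model comparison.
Everything is deterministic given the root seed (per-patient child streams).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from .bands import MODEL_SPACE, band_feature_table, model_evidence_table, rfx_bms
from .glm import (
    WINDOW_EFFECT,
    condition_contrast_timecourse,
    parcel_fixed_effect,
    pointwise_regression,
    site_fdr_significance,
)
from .preprocessing import (
    BETA,
    GAMMA,
    THETA_ALPHA,
    EpochedPower,
    epoch_and_baseline,
    session_envelope,
)
from .synth import (
    NoiseConfig,
    PUNISHMENT_PARCELS,
    REWARD_PARCELS,
    default_site_table,
    generate_session_recording,
)
from .task import REWARD, TaskConfig


@dataclass
class RunConfig:
    """Cohort sizes, statistical settings and seeds for one pipeline run."""

    n_patients: int = 6
    n_sites: int = 8
    sfreq: float = 512.0
    task: TaskConfig = field(default_factory=lambda: TaskConfig(n_sessions=2))
    agent: bh.AgentParameters = field(default_factory=lambda: bh.TABLE1_QLR)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_starts: int = 10
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    fdr_q: float = 0.05
    prop_threshold: float = 0.20
    bms_max_sites: int = 16
    seed: int = 0

    def manifest(self) -> dict:
        d = asdict(self)
        d.update(
            epoch_window_s=[-3.0, 1.5],
            envelope_rate_hz=64.0,
            baseline="outcome-centered-6s",
            fdr_window_s=[0.0, 1.5],
            effect_window_s=list(WINDOW_EFFECT),
            min_duration_s=0.100,
            gamma_band_hz=[50, 150],
            model_space=["+".join(m) for m in MODEL_SPACE],
        )
        return d


@dataclass
class PatientData:
    """Per-patient intermediate products used by the group stages."""

    patient_id: str
    performance: dict
    fit_ql: bh.ModelFit
    fit_qlr: bh.ModelFit
    regressors: pd.DataFrame
    epochs_by_site: dict[str, EpochedPower]
    epochs_beta: dict[str, EpochedPower]
    epochs_ta: dict[str, EpochedPower]
    site_parcel: dict[str, str]


def _concat_epochs(parts: list[EpochedPower]) -> EpochedPower:
    return EpochedPower(
        data=np.vstack([p.data for p in parts]),
        times=parts[0].times,
        trial_index=np.concatenate(
            [p.trial_index + i * 10_000 for i, p in enumerate(parts)]
        ),
        baseline_mode=parts[0].baseline_mode,
    )


def process_patient(
    patient_id: str,
    config: RunConfig,
    rng: np.random.Generator,
    with_low_bands: bool = True,
) -> PatientData:
    """Simulate and preprocess one synthetic patient end to end."""
    sessions = bh.simulate_patient(config.agent, config.task, rng)
    fit_ql = bh.fit_patient(sessions, "QL", n_starts=config.n_starts, rng=rng)
    fit_qlr = bh.fit_patient(sessions, "QLr", n_starts=config.n_starts, rng=rng)
    reg = bh.derive_regressors(fit_qlr, sessions)
    specs = default_site_table(config.n_sites)

    bands = {"gamma": GAMMA}
    if with_low_bands:
        bands.update(beta=BETA, theta_alpha=THETA_ALPHA)
    acc: dict[str, dict[str, list[EpochedPower]]] = {b: {} for b in bands}
    kept_rows = []
    for s_idx, sess in enumerate(sessions):
        r = reg[reg["session"] == s_idx].reset_index(drop=True)
        rec, ev = generate_session_recording(
            specs, sess, r, rng, sfreq=config.sfreq, noise=config.noise
        )
        for b_name, b_spec in bands.items():
            envs, names = session_envelope(rec.data, rec.ch_names, rec.sfreq, b_spec)
            for env, name in zip(envs, names):
                ep = epoch_and_baseline(env, ev)
                acc[b_name].setdefault(name, []).append(ep)
        first_site = next(iter(acc["gamma"]))
        kept_rows.append(r.iloc[acc["gamma"][first_site][-1].trial_index])
    reg_kept = pd.concat(kept_rows, ignore_index=True)

    return PatientData(
        patient_id=patient_id,
        performance=bh.performance_summary(sessions),
        fit_ql=fit_ql,
        fit_qlr=fit_qlr,
        regressors=reg_kept,
        epochs_by_site={k: _concat_epochs(v) for k, v in acc["gamma"].items()},
        epochs_beta={k: _concat_epochs(v) for k, v in acc.get("beta", {}).items()},
        epochs_ta={k: _concat_epochs(v) for k, v in acc.get("theta_alpha", {}).items()},
        site_parcel={s.site_id: s.parcel for s in specs},
    )


def run_pipeline(config: RunConfig, out_dir: Path | str | None = None) -> dict:
    """Run the full synthetic analysis and return the report dictionary.

    With ``config.n_perm == 0`` the cluster stages emit descriptive
    timecourses only (no corrected p-values).
    """
    root = np.random.SeedSequence(config.seed)
    patient_seeds = root.spawn(config.n_patients)
    patients = [
        process_patient(
            f"sub-{i + 1:02d}", config, np.random.default_rng(s),
            with_low_bands=i * config.n_sites < config.bms_max_sites,
        )
        for i, s in enumerate(patient_seeds)
    ]

    report: dict = {"config": config.manifest()}

    # ---- behavior ----------------------------------------------------------
    comp = bh.compare_models([p.fit_ql for p in patients], [p.fit_qlr for p in patients])
    report["behavior"] = {
        "correct_rate": {
            cond: float(np.mean([p.performance["correct_rate"][cond] for p in patients]))
            for cond in ("reward", "punishment")
        },
        "delta_bic": comp,
        "alpha_mean": float(np.mean([p.fit_qlr.params.alpha for p in patients])),
        "beta_mean": float(np.mean([p.fit_qlr.params.beta for p in patients])),
        "theta_mean": float(np.mean([p.fit_qlr.params.theta for p in patients])),
    }

    # ---- site-level regression + FDR --------------------------------------
    site_stats = []
    tc_by_site = {}
    parcel_map = {}
    for p in patients:
        pe = p.regressors["pe_all_z"].to_numpy()
        for site, ep in p.epochs_by_site.items():
            uid = f"{p.patient_id}:{site}"
            tc = pointwise_regression(ep, pe)
            tc_by_site[uid] = tc
            site_stats.append(site_fdr_significance(tc, site_id=uid, q=config.fdr_q))
            parcel_map[uid] = p.site_parcel[site]

    parcels = parcel_fixed_effect(
        site_stats, parcel_map, alpha=0.05, prop_threshold=config.prop_threshold
    )
    report["parcels"] = [asdict(p) for p in parcels]
    selected = {p.parcel for p in parcels if p.selected}

    # ---- RPE vs PPE contrast per parcel ------------------------------------
    contrast = {}
    times = next(iter(tc_by_site.values())).times
    win = (times >= WINDOW_EFFECT[0]) & (times <= WINDOW_EFFECT[1])
    for parcel in sorted({*parcel_map.values()}):
        Y, xr, xp, msk = [], [], [], []
        for p in patients:
            rew = (p.regressors["condition"] == REWARD).to_numpy()
            for site, ep in p.epochs_by_site.items():
                if p.site_parcel[site] != parcel:
                    continue
                Y.append(ep.data)
                xr.append(p.regressors["pe_cond_z"].to_numpy())
                xp.append(p.regressors["pe_cond_z"].to_numpy())
                msk.append(rew)
        if len(Y) < 2:
            continue
        n_perm = max(config.n_perm, 0)
        if n_perm:
            br, bp, cres = condition_contrast_timecourse(
                Y, xr, xp, msk, times, n_perm=n_perm,
                cluster_alpha=config.cluster_alpha, rng=np.random.default_rng(config.seed),
            )
            sig = [
                {"start": c.start_time, "end": c.end_time, "mass": c.mass, "p_c": c.p_corrected}
                for c in cres.significant()
            ]
        else:
            br, bp, _ = condition_contrast_timecourse(
                Y, xr, xp, msk, times, n_perm=1, rng=0
            )
            sig = None
        d = (br - bp)[:, win].mean(axis=1)
        from scipy import stats as _st

        t, pv = _st.ttest_1samp(d, 0.0)
        contrast[parcel] = {
            "n_sites": len(Y),
            "mean_rpe_minus_ppe": float(d.mean()),
            "t": float(t),
            "p": float(pv),
            "dominance": "reward" if d.mean() > 0 else "punishment",
            "clusters": sig,
        }
    report["rpe_vs_ppe"] = contrast
    report["dissociation"] = {
        "reward_dominant": sorted(
            p for p, c in contrast.items()
            if c["dominance"] == "reward" and c["p"] < 0.05 and p in selected
        ),
        "punishment_dominant": sorted(
            p for p, c in contrast.items()
            if c["dominance"] == "punishment" and c["p"] < 0.05 and p in selected
        ),
        "expected_reward": list(REWARD_PARCELS),
        "expected_punishment": list(PUNISHMENT_PARCELS),
    }

    # ---- outcome / expectation decomposition -------------------------------
    decomp = {}
    for parcel in sorted({*parcel_map.values()}):
        rows = {"reward": {"R": [], "Q": []}, "punishment": {"R": [], "Q": []}}
        for p in patients:
            cond = p.regressors["condition"].to_numpy()
            for site, ep in p.epochs_by_site.items():
                if p.site_parcel[site] != parcel:
                    continue
                for cname in rows:
                    m = cond == cname
                    tc = pointwise_regression(
                        ep,
                        {
                            "R": p.regressors["outcome_z"].to_numpy(),
                            "Q": p.regressors["expectation_z"].to_numpy(),
                        },
                        trial_mask=m,
                    )
                    rows[cname]["R"].append(float(tc.betas[0, win].mean()))
                    rows[cname]["Q"].append(float(tc.betas[1, win].mean()))
        if not rows["reward"]["R"]:
            continue
        decomp[parcel] = {
            c: {k: {"mean": float(np.mean(v)), "n": len(v)} for k, v in comps.items()}
            for c, comps in rows.items()
        }
    report["decomposition"] = decomp

    # ---- frequency-band model comparison -----------------------------------
    feats, pes = [], []
    for p in patients:
        pe = p.regressors["pe_all_z"].to_numpy()
        for site in p.epochs_by_site:
            if not p.epochs_beta or len(feats) >= config.bms_max_sites:
                continue
            feats.append(
                band_feature_table(
                    p.epochs_by_site[site], p.epochs_beta[site], p.epochs_ta[site]
                )
            )
            pes.append(pe)
    if len(feats) >= 2:
        L = model_evidence_table(feats, pes)
        bms = rfx_bms(L, rng=np.random.default_rng(config.seed))
        report["band_comparison"] = {
            "model_names": bms.model_names,
            "expected_frequency": bms.expected_frequency.tolist(),
            "exceedance_probability": bms.exceedance_probability.tolist(),
            "best_model": bms.best_model(),
            "n_sites": len(feats),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        pd.DataFrame(report["parcels"]).to_csv(out_dir / "parcels.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
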