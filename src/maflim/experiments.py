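"""Study-scale validation experiments over the synthetic pipeline.

These drivers define the reference conditions under which the pipeline's
claims are checked: noiseless deconvolution-oracle grids, universal-
semicircle membership of monoexponential phasors, and the cohort-level
recovery experiments (a strongly separated cohort that the classifier must
solve, and a zero-effect cohort whose permutation null must sit at chance).
They are shared by the analysis scripts, the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .classification import CVResult, lopo_cv, sweep_n_sfs
from .core import AcquisitionConfig
from .features import extract_cohort_features
from .phasor import frequency_deconvolve, harmonic_frequencies
from .preprocess import concat_irf, pad_and_concatenate
from .simulate import (
    DecayParams,
    RegionDecayParams,
    SceneSpec,
    cohort_spec_like_study,
    default_irf,
    default_scene,
    generate_cohort,
    generate_lesion_image,
    strong_effect,
)
from .timedomain import BIEXP_POOL, IrfKernel, fit_decay

#: Inter-patient spread used in the recovery experiments ("low" relative to
#: the strong class effect).
LOW_INTER_PATIENT_SD: dict[str, float] = {
    "tau_fast": 0.02,
    "tau_slow": 0.05,
    "alpha_fast": 0.01,
    "intensity_frac": 0.05,
}

RECOVERY_ALPHAS = (0.3, 0.5, 0.7, 0.9)
RECOVERY_TAU_FAST = (0.3, 0.7, 1.2, 1.6, 2.0)
RECOVERY_TAU_SLOW = (2.5, 4.0, 5.5, 7.0, 8.0)


def biexp_recovery_grid(
    alphas=RECOVERY_ALPHAS,
    tau_fasts=RECOVERY_TAU_FAST,
    tau_slows=RECOVERY_TAU_SLOW,
    channel: int = 452,
) -> pd.DataFrame:
    """Noiseless parameter-recovery grid for the reconvolution fitter.

    Returns one row per (alpha_fast, tau_fast, tau_slow) with the relative
    errors of the recovered parameters (100 fits on the default grid).
    """
    config = AcquisitionConfig(rows=1, cols=1)
    irf = default_irf(config)
    kernel = IrfKernel.from_instrument(irf, channel)
    t = config.time_ns
    rows = []
    for a in alphas:
        for tf in tau_fasts:
            for ts in tau_slows:
                p = DecayParams(a, tf, ts, 500.0)
                y = 500.0 * kernel.model(np.array([a, 1 - a]), np.array([tf, ts]))
                fit = fit_decay(y, kernel, n_components=2)
                rows.append(
                    {
                        "alpha_fast": a,
                        "tau_fast": tf,
                        "tau_slow": ts,
                        "err_alpha": abs(fit.alpha_fast - a) / a,
                        "err_tau_fast": abs(fit.tau_fast - tf) / tf,
                        "err_tau_slow": abs(fit.tau_slow - ts) / ts,
                    }
                )
    return pd.DataFrame(rows)


def semicircle_check(
    taus=(0.5, 1.0, 2.0, 3.0),
    rows: int = 4,
    cols: int = 4,
) -> pd.DataFrame:
    """Universal-semicircle membership of monoexponential phasors.

    For each lifetime, a channel-identical monoexponential image is rendered,
    deconvolved in the frequency domain, and the worst deviation of
    (G - 1/2)^2 + S^2 from 1/4 over the nine harmonics is reported, together
    with the worst relative disagreement between the phasor-derived lifetime
    S/(w G) and the time-domain reconvolution fit.
    """
    config = AcquisitionConfig(rows=rows, cols=cols)
    irf = default_irf(config)
    u = concat_irf(irf, config.n_samples_per_channel)
    w = 2 * np.pi * harmonic_frequencies(config) * 1e-9  # rad/ns
    out = []
    for tau in taus:
        params = RegionDecayParams(
            {ch: DecayParams(1.0, tau, tau, 500.0) for ch in (390, 452, 500)}
        )
        scene = SceneSpec(region1_params=params, region2_params=params,
                          noise_model=None, offset=0.0, seed=0)
        img = generate_lesion_image(scene, config, irf)
        y = pad_and_concatenate(img).data[0, 0]
        P = frequency_deconvolve(y, u)
        G, S = P.real, P.imag
        dev = np.abs((G - 0.5) ** 2 + S**2 - 0.25).max()
        tau_phasor = S / (w * G)
        kernel = IrfKernel.from_instrument(irf, 452)
        fit = fit_decay(img.channels[452][0, 0], kernel, n_components=1)
        tau_fit = fit.taus[0]
        out.append(
            {
                "tau_ns": tau,
                "max_semicircle_deviation": dev,
                "max_lifetime_rel_err": np.abs(tau_phasor / tau_fit - 1).max(),
            }
        )
    return pd.DataFrame(out)


def strong_effect_recovery(
    rows: int = 32,
    cols: int = 32,
    seed: int = 11,
    snr_db: float = 35.0,
    pools: tuple[str, ...] = ("biexponential",),
) -> tuple[pd.DataFrame, dict[str, CVResult]]:
    """Cohort recovery under a large class effect and low noise.

    Renders the 30-patient / 60-lesion study-layout cohort with the strong
    malignant parameter shifts, extracts the requested pools, and runs the
    feature-count sweep with LOPO-CV per pool.  Returns the feature table and
    the chosen CV result per pool.
    """
    config = AcquisitionConfig(rows=rows, cols=cols)
    irf = default_irf(config)
    spec = cohort_spec_like_study(
        effect=strong_effect(), inter_patient_sd=LOW_INTER_PATIENT_SD, seed=seed
    )
    scene = default_scene(seed=seed, snr_db=snr_db)
    lesions = generate_cohort(spec, scene, config, irf)
    feats = extract_cohort_features(lesions, irf, config, pools=pools,
                                    cluster_seed=seed)
    results = {}
    from .features import POOLS

    for pool_name in pools:
        _, cv, _ = sweep_n_sfs(feats, list(POOLS[pool_name]))
        results[pool_name] = cv
    return feats, results


def null_cohort_features(
    rows: int = 32,
    cols: int = 32,
    seed: int = 5,
    snr_db: float = 25.0,
) -> pd.DataFrame:
    """Feature table of a zero-effect cohort (labels carry no information)."""
    config = AcquisitionConfig(rows=rows, cols=cols)
    irf = default_irf(config)
    spec = cohort_spec_like_study(effect={}, seed=seed)
    scene = default_scene(seed=seed, snr_db=snr_db)
    lesions = generate_cohort(spec, scene, config, irf)
    return extract_cohort_features(lesions, irf, config,
                                   pools=("biexponential",), cluster_seed=seed)


def null_permutation_accuracies(
    feats: pd.DataFrame,
    n_permutations: int = 20,
    n_sfs: int = 5,
    seed: int = 42,
) -> np.ndarray:
    """LOPO-CV accuracies under patient-level label permutations.

    Patient diagnoses are reshuffled across patients (keeping the 17/13
    patient split), the biexponential-pool CV is rerun per permutation, and
    the accuracies are returned.  With no class effect these must sit at
    chance level.
    """
    rng = np.random.default_rng(seed)
    patients = feats["patient_id"].unique()
    labels = feats.groupby("patient_id")["label"].first().loc[patients].to_numpy()
    accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        df = feats.copy()
        df["label"] = df["patient_id"].map(dict(zip(patients, perm)))
        cv = lopo_cv(df, list(BIEXP_POOL), n_sfs=n_sfs)
        accs.append(cv.metrics["accuracy"])
    return np.asarray(accs)
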