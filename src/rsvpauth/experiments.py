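"""End-to-end simulation experiments exercising the whole pipeline.

Every function here drives the public package API on synthetic recordings
and returns plain numbers; they back the acceptance checks and the
``scripts/acceptance.py`` report.  Problem sizes are scaled to desk scale
(documented in ``docs/methods.md``): the GA oracle and recovery studies run
on 10-block sessions (100 registration trials → 50 pair-averaged trials per
subject role) with a 20-generation cap; the design-arithmetic, null
calibration and method-comparison runs use the full 20-block protocol.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from sklearn.covariance import LedoitWolf

from . import evaluate, ga, hdca, preprocess, simulate

#: Channel subset used for the small exhaustive-search montage.
SMALL_MONTAGE = ("Cz", "P3", "Pz", "P4", "Oz", "Fz")

#: GA run length used by the simulation studies (cap scaled down from the
#: API default of 50; the stall rule usually stops runs earlier anyway).
STUDY_GA = dict(pop_size=100, max_generations=20, stall_generations=8)


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def session_epochs(
    config: simulate.SimConfig,
    templates: list | None = None,
    user_familiarity: float = 1.0,
    nonblind_familiarity: float = 0.3,
    include: tuple[str, ...] = ("user", "blind", "nonblind"),
) -> preprocess.EpochSet:
    """Simulate one account's session and return classification-ready epochs.

    Generates the user and imposter recordings (independent noise, shared
    stimulus timing), runs the full preprocessing chain on each, crops to
    the 0..1000 ms classification window and concatenates.
    ``user_familiarity`` < 1 attenuates the user's self response, modelling
    cross-session drift.
    """
    ss = np.random.SeedSequence(config.seed)
    r_time, r_user, r_blind, r_non = (np.random.default_rng(s) for s in ss.spawn(4))
    timeline = simulate._make_timeline(config, r_time)
    recs = {
        "user": lambda: simulate.generate_recording(
            config, templates, "self", user_familiarity, timeline, r_user),
        "blind": lambda: simulate.generate_recording(
            config, templates, "nonself", 0.0, timeline, r_blind),
        "nonblind": lambda: simulate.generate_recording(
            config, templates, "nonself", nonblind_familiarity, timeline, r_non),
    }
    parts = [preprocess.preprocess_pipeline(recs[name]()).crop(0.0, 1000.0)
             for name in include]
    return preprocess.concatenate(parts)


def design_arithmetic(seed: int = 0) -> dict:
    """Structural counts of the default protocol, measured off a real run.

    Simulates a full default registration session, preprocesses it, and
    reads the quantities off the resulting arrays: target events per
    session, samples per classification epoch, pair-averaged trial count,
    subject-level datasets in the study design, and the 2-trial login
    duration.
    """
    config = simulate.SimConfig(seed=seed)
    rec = simulate.generate_recording(config)
    ep = preprocess.preprocess_pipeline(rec, pair_average=False).crop(0.0, 1000.0)
    paired = preprocess.average_adjacent_pairs(ep)
    protocol = evaluate.AuthProtocol()
    return {
        "registration_trials": len(rec.events),
        "epoch_samples": ep.n_times,
        "epoch_fs": ep.fs,
        "paired_trials": paired.n_trials,
        "subject_datasets": protocol.n_datasets,
        "login_seconds": protocol.login_seconds(config.trial_duration_ms),
    }


def filter_contract(fs: float = 2400.0, passband_hz: float = 40.0,
                    stopband_hz: float = 49.0) -> dict:
    """Frequency-response audit of the designed low-pass (single pass).

    Returns the worst-case passband ripple (dB below unity over 0..passband)
    and the minimum stopband attenuation (dB over stopband..100 Hz).
    """
    sos = preprocess.design_lowpass(fs, passband_hz, stopband_hz)
    freqs = np.concatenate([np.linspace(0.0, passband_hz, 200),
                            np.linspace(stopband_hz, 100.0, 200)])
    _, h = sp_signal.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
    pass_db = gain_db[:200]
    stop_db = gain_db[200:]
    return {
        "passband_ripple_db": float(-pass_db.min()),
        "stopband_attenuation_db": float(-stop_db.max()),
    }


def fld_closed_form_cosine(seed: int = 0, n_instances: int = 20,
                           n_trials: int = 80, n_channels: int = 8) -> float:
    """Worst-case cosine between fitted FLD weights and the closed form.

    Independent oracle: the shrunk within-class covariance is re-estimated
    with :class:`sklearn.covariance.LedoitWolf` and the direction solved
    directly as (S_w + λ target)⁻¹ (μ₁ − μ₀).
    """
    rng = np.random.default_rng(seed)
    worst = 1.0
    for _ in range(n_instances):
        labels = rng.integers(0, 2, size=n_trials)
        while np.unique(labels).size < 2 or min((labels == 0).sum(), (labels == 1).sum()) < 2:
            labels = rng.integers(0, 2, size=n_trials)
        A = rng.standard_normal((n_channels, n_channels))
        X = rng.standard_normal((n_trials, n_channels)) @ A
        X[labels == 1] += rng.standard_normal(n_channels)
        w = hdca.fld_weights(X, labels)

        centered = X.copy()
        centered[labels == 0] -= X[labels == 0].mean(axis=0)
        centered[labels == 1] -= X[labels == 1].mean(axis=0)
        lw = LedoitWolf(assume_centered=True).fit(centered)
        diff = X[labels == 1].mean(axis=0) - X[labels == 0].mean(axis=0)
        w_ref = np.linalg.solve(lw.covariance_, diff)
        w_ref /= np.linalg.norm(w_ref)
        worst = min(worst, float(abs(w @ w_ref)))
    return worst


def _small_montage_templates():
    """Two informative channels (P3, Pz) on the 6-channel montage."""
    topo = simulate._topo(SMALL_MONTAGE, P3=0.9, Pz=1.0)
    return [
        simulate.ERPTemplate("P3a", latency=320.0, width=45.0,
                             amplitude_self=6.0, amplitude_nonself=2.0,
                             topography=topo),
        simulate.ERPTemplate("P3b", latency=450.0, width=70.0,
                             amplitude_self=7.0, amplitude_nonself=2.5,
                             topography=topo),
    ]


def small_montage_dataset(seed: int, n_blocks: int = 10) -> preprocess.EpochSet:
    config = simulate.SimConfig(n_channels=6, channel_names=SMALL_MONTAGE,
                                n_blocks=n_blocks, seed=seed)
    return session_epochs(config, _small_montage_templates(),
                          include=("user", "blind"))


def ga_exhaustive_agreement(seed: int = 0, n_seeds: int = 10) -> dict:
    """GA optimum vs brute force over all 63 masks of a 6-channel problem.

    One shared dataset; ``n_seeds`` independent GA runs, each compared
    against an exhaustive search using that run's frozen fold assignment.
    Returns the fraction of runs whose best fitness equals the global
    optimum exactly.
    """
    epochs = small_montage_dataset(_derive_seed(seed, 101))
    hits = 0
    for k in range(n_seeds):
        cfg = ga.GAConfig(seed=_derive_seed(seed, 200 + k), **STUDY_GA)
        best, history = ga.run_ga(epochs, config=cfg)
        oracle = ga.exhaustive_best(epochs, cv_folds=cfg.cv_folds,
                                    fold_seed=history["fold_seed"])
        if best.fitness == oracle.fitness:
            hits += 1
    return {"agreement_rate": hits / n_seeds, "n_seeds": n_seeds}


def recovery_dataset(seed: int, n_blocks: int = 20) -> preprocess.EpochSet:
    """16-channel dataset whose class signal lives only at P3/Pz/P4, 300–500 ms."""
    config = simulate.SimConfig(n_blocks=n_blocks, seed=seed)
    return session_epochs(config, simulate.parietal_effect_templates(),
                          include=("user", "blind"))


def channel_recovery(seed: int = 0, n_runs: int = 10) -> dict:
    """Does GA-HDCA localise a known spatial/temporal effect?

    Per run: fresh dataset with the parietal 300–500 ms effect, one GA run;
    success when the selected mask contains all of P3, Pz, P4.  Also checks,
    per run, that the full-montage HDCA temporal weights |v_k| peak in the
    300–500 ms windows (0-based windows 3–4 of the 100 ms tiling).
    """
    informative = [simulate.CHANNELS_16.index(ch) for ch in ("P3", "Pz", "P4")]
    mask_hits = 0
    vk_hits = 0
    for k in range(n_runs):
        epochs = recovery_dataset(_derive_seed(seed, 300 + k))
        cfg = ga.GAConfig(seed=_derive_seed(seed, 400 + k), **STUDY_GA)
        best, _ = ga.run_ga(epochs, config=cfg)
        if all(best.mask[i] for i in informative):
            mask_hits += 1
        model = hdca.train(epochs)
        if int(np.argmax(np.abs(model.temporal_weights))) in (3, 4):
            vk_hits += 1
    return {"mask_recovery_rate": mask_hits / n_runs,
            "vk_peak_rate": vk_hits / n_runs, "n_runs": n_runs}


def null_cv_accuracy(seed: int = 0, n_blocks: int = 20) -> dict:
    """Calibration on effect-free data: CV accuracy should sit near chance.

    Balanced design (user vs one imposter, identical response amplitudes) so
    chance is exactly 50%; with the protocol's 1:2 imbalance a trivial
    majority vote would already sit at 66%.
    """
    config = simulate.SimConfig(n_blocks=n_blocks, seed=_derive_seed(seed, 500))
    epochs = session_epochs(config, simulate.null_templates(),
                            include=("user", "blind"))
    metrics = evaluate.crossval(epochs, seed=_derive_seed(seed, 501))
    half_width = 100 * 1.96 * np.sqrt(0.25 / metrics.n_test)
    return {"acc_pct": metrics.acc, "n_test": metrics.n_test,
            "band_halfwidth_pct": float(half_width)}


def method_comparison(seed: int = 0, n_blocks: int = 20,
                      drift_levels: tuple[float, ...] = (1.0, 0.6, 0.2)) -> dict:
    """HDCA vs GA-HDCA: in-session CV and cross-session permanence.

    Session 1 trains both models (full montage vs GA-selected mask) on the
    user + two imposters; permanence applies them, without refitting, to
    session-2 data in which the user's self response is attenuated toward
    the non-self response by each drift level (1.0 = no drift).
    """
    s1_config = simulate.SimConfig(n_blocks=n_blocks, seed=_derive_seed(seed, 600))
    epochs1 = session_epochs(s1_config)

    cv_seed = _derive_seed(seed, 601)
    m_hdca, folds_hdca = evaluate.crossval(epochs1, seed=cv_seed,
                                           return_fold_details=True)
    best, _ = ga.run_ga(epochs1, config=ga.GAConfig(seed=_derive_seed(seed, 602),
                                                    **STUDY_GA))
    m_ga, folds_ga = evaluate.crossval(epochs1, seed=cv_seed,
                                       channel_mask=best.mask,
                                       return_fold_details=True)

    model_full = hdca.train(epochs1)
    model_ga = hdca.train(epochs1, channel_mask=best.mask)
    permanence = {"hdca": [], "ga_hdca": []}
    for level in drift_levels:
        s2_config = simulate.SimConfig(n_blocks=n_blocks,
                                       seed=_derive_seed(seed, 700))
        epochs2 = session_epochs(s2_config, user_familiarity=level)
        permanence["hdca"].append(evaluate.permanence_test(model_full, epochs2).acc)
        permanence["ga_hdca"].append(evaluate.permanence_test(model_ga, epochs2).acc)

    return {
        "hdca": m_hdca.as_dict(),
        "ga_hdca": m_ga.as_dict(),
        "fold_acc_hdca": folds_hdca,
        "fold_acc_ga": folds_ga,
        "mask": [int(b) for b in best.mask],
        "n_selected": best.n_selected,
        "drift_levels": list(drift_levels),
        "permanence_acc": permanence,
    }
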