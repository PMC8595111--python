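"""Desk-scale simulation studies: parameter recovery, permutation nulls and
type-I error calibration for the classification and ERP statistics paths.

These functions are the package's reproducible in-silico experiments; they
drive the same public pipeline operations as the CLI stages, at session
sizes chosen to keep a full study in the minutes range on one CPU (the
methods note documents the scales).
"""

from __future__ import annotations

import numpy as np

from . import classification as clf
from . import erp
from . import preprocessing as pre
from . import synthetic as syn
from .types import DEVIANT, STANDARD


def session_difference_trials(cohort: syn.CohortSpec, animal: int,
                              effect: syn.TreatmentEffect,
                              antialias: pre.FilterSpec | None = None,
                              fs_hz: float = 3000.0,
                              templates=None) -> clf.DifferenceTrialSet:
    """Classification-path preparation of one simulated session: epoch-level
    rendering at the frontocentral channel, baseline correction, 400 µV
    artifact rejection, 32 Hz anti-alias + 64 Hz downsampling, difference
    trials."""
    epochs = syn.simulate_epochs(cohort, animal, effect, fs_hz=fs_hz,
                                 templates=templates)
    epochs = pre.baseline_correct(epochs)
    epochs = pre.reject_artifacts(epochs)
    down = pre.resample(epochs, 64.0, antialias=antialias)
    return clf.make_difference_trials(down, channel=epochs.channels[0])


def cohort_trialsets(cohort: syn.CohortSpec,
                     effects: list[syn.TreatmentEffect],
                     fs_hz: float = 3000.0, templates=None
                     ) -> dict[tuple[int, str], clf.DifferenceTrialSet]:
    antialias = pre.design_antialias_ls(fs_hz)
    return {(animal, eff.label):
            session_difference_trials(cohort, animal, eff, antialias,
                                      fs_hz=fs_hz, templates=templates)
            for animal in range(cohort.n_animals) for eff in effects}


def suppression_effect(fraction: float, label: str | None = None
                       ) -> syn.TreatmentEffect:
    """Treatment suppressing the N1 and P3 amplitudes by ``fraction``."""
    g = 1.0 - fraction
    return syn.TreatmentEffect(label or f"suppress{int(fraction * 100)}",
                               gain={"N1": g, "P3": g})


def recovery_accuracy(seed: int, n_animals: int = 8,
                      suppression: float = 0.5,
                      n_standard: int = 174, n_deviant: int = 26,
                      shuffle_training_labels: bool = False) -> float:
    """Mean session accuracy of leave-one-animal-out SWLDA on a synthetic
    cohort: sham vs an N1/P3 suppression treatment.

    With ``shuffle_training_labels`` the training sessions' treatment labels
    are permuted (animal-wise), giving the chance-level null.
    """
    cohort = syn.CohortSpec(n_animals=n_animals, seed=seed,
                            n_standard=n_standard, n_deviant=n_deviant)
    eff = suppression_effect(suppression)
    sham = syn.default_treatments()["sham"]
    trialsets = cohort_trialsets(cohort, [sham, eff])
    if shuffle_training_labels:
        rng = np.random.default_rng(seed + 1)
        for animal in range(n_animals):
            if rng.random() < 0.5:
                a = trialsets[(animal, "sham")]
                b = trialsets[(animal, eff.label)]
                a.treatment, b.treatment = b.treatment, a.treatment
                trialsets[(animal, "sham")] = b
                trialsets[(animal, eff.label)] = a
    preds = clf.loo_session_classification(trialsets, "sham", eff.label,
                                           seed=seed)
    correct = sum(p.predicted == p.actual for p in preds)
    return correct / len(preds)


def null_classification_accuracy(seed: int, n_animals: int = 4,
                                 n_standard: int = 52, n_deviant: int = 8
                                 ) -> float:
    """Session accuracy when the two 'treatments' are both the identity
    (standard ≡ deviant response statistics differ, but the two conditions
    do not): chance level."""
    cohort = syn.CohortSpec(n_animals=n_animals, seed=seed,
                            n_standard=n_standard, n_deviant=n_deviant)
    null_b = syn.TreatmentEffect("condition_b")  # identity, like sham
    sham = syn.default_treatments()["sham"]
    trialsets = cohort_trialsets(cohort, [sham, null_b])
    preds = clf.loo_session_classification(trialsets, "sham", "condition_b",
                                           seed=seed)
    return sum(p.predicted == p.actual for p in preds) / len(preds)


def erp_difference_pvalue(seed: int, component: str = "N1",
                          null: bool = True, n_animals: int = 10,
                          n_standard: int = 12, n_deviant: int = 6,
                          fs_hz: float = 750.0) -> float:
    """One-sample t p-value of the per-animal difference-curve amplitude.

    Under ``null`` the deviant evokes the standard template, so the
    difference curve is pure noise. Amplitudes are measured in the fixed
    10 ms window at the canonical template latency (measuring at a peak
    picked on the same data would bias the null).
    """
    cohort = syn.CohortSpec(n_animals=n_animals, seed=seed,
                            n_standard=n_standard, n_deviant=n_deviant,
                            artifact_rate=0.0)
    templates = syn.default_templates()
    if null:
        templates = {STANDARD: templates[STANDARD],
                     DEVIANT: syn.ERPTemplate(DEVIANT,
                                              templates[STANDARD].components)}
    sham = syn.default_treatments()["sham"]
    latency = templates[STANDARD].component(component).peak_latency_ms
    amps = []
    for animal in range(n_animals):
        epochs = syn.simulate_epochs(cohort, animal, sham, fs_hz=fs_hz,
                                     templates=templates)
        epochs = pre.baseline_correct(epochs)
        dev = erp.average_erp(epochs, DEVIANT)
        std = erp.average_erp(epochs, STANDARD)
        diff = erp.difference_curve(dev, std)
        m = erp.component_amplitude(diff.waveforms[0], diff.time_ms,
                                    component, latency)
        amps.append(m.amplitude_uV)
    return erp.one_sample_t(amps).p_uncorrected


def multichannel_difference_pvalues(seed: int,
                                    components: tuple[str, ...] = ("N1",
                                                                   "P3"),
                                    n_animals: int = 10,
                                    n_standard: int = 72, n_deviant: int = 24,
                                    fs_hz: float = 750.0,
                                    channels=syn.CHANNELS
                                    ) -> dict[str, np.ndarray]:
    """Per-channel one-sample t p-values of the difference-curve amplitude
    under the default (deviant > standard) templates, with peak latencies
    taken from each channel's grand-average difference curve."""
    cohort = syn.CohortSpec(n_animals=n_animals, seed=seed,
                            n_standard=n_standard, n_deviant=n_deviant,
                            artifact_rate=0.0)
    sham = syn.default_treatments()["sham"]
    pvals: dict[str, list] = {c: [] for c in components}
    for channel in channels:
        diffs = []
        for animal in range(n_animals):
            epochs = syn.simulate_epochs(cohort, animal, sham, fs_hz=fs_hz,
                                         channel=channel)
            epochs = pre.baseline_correct(epochs)
            diff = erp.difference_curve(erp.average_erp(epochs, DEVIANT),
                                        erp.average_erp(epochs, STANDARD))
            diffs.append(diff)
        grand = np.mean([d.waveforms[0] for d in diffs], axis=0)
        for component in components:
            lat = erp.find_component_peak(grand, diffs[0].time_ms, component)
            amps = [erp.component_amplitude(d.waveforms[0], d.time_ms,
                                            component, lat).amplitude_uV
                    for d in diffs]
            pvals[component].append(erp.one_sample_t(amps).p_uncorrected)
    return {c: np.asarray(v) for c, v in pvals.items()}
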