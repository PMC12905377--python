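"""Synthetic calcium-trace cohorts.

Generates labeled ΔF/F₀ trace matrices with the statistical structure of
ex-vivo GCaMP recordings from gonadal LHR-expressing cells: spontaneous
basal dynamics (slow oscillation + drift + noise) in every cell, and a
ligand-evoked response (delayed saturating rise, plateau through the bath
application, exponential washout decay) in a responder subset.

Default per-group parameters are calibrated so that cohort mean-trace
peaks and first-minute inactive fractions reproduce the study's printed
group summaries: male Het/Hom mean-trace peaks 0.40 / 0.23; female
Het / Hom / chaperone-treated peaks 0.28 / 0.055 / 0.32; and a delayed
treated response with ≈37% of treated cells vs ≈16.5% of Het cells
inactive (< 0.1 ΔF/F₀) during the first minute of ligand application.
"""

from __future__ import annotations

import numpy as np

from .data import GROUPS, CohortConfig, GroupParams, TimeGrid, TraceMatrix

#: Printed target peaks of the group mean traces, by cohort sex.
PEAK_TARGETS: dict[str, dict[str, float]] = {
    "male": {"HET": 0.40, "HOM": 0.23},
    "female": {"HET": 0.28, "HOM": 0.055, "HOM_TREATED": 0.32},
}

#: Printed first-LH-minute inactive fractions (female cohort).
INACTIVE_TARGETS = {"HET": 0.165, "HOM_TREATED": 0.37}

# Cell/animal counts mirror the study's pooled recordings.
_DEFAULT_COUNTS = {
    "male": {"HET": (278, 3), "HOM": (175, 3)},
    "female": {"HET": (401, 5), "HOM": (203, 5), "HOM_TREATED": (391, 3)},
}


def _default_group_params(sex: str) -> dict[str, GroupParams]:
    # Basal dynamics differ by genotype (distinct oscillation bands), which is
    # what makes basal-only classification possible; treated cells get
    # control-like basal dynamics and a delayed, slower response.
    # Male genotype bands overlap (basal is informative but weaker than the
    # response); female bands are disjoint, and the treated group shares the
    # control band — the basal signature that carries the rescue phenotype.
    male_het_basal = dict(basal_osc_amp=0.045, basal_osc_freq_range=(0.02, 0.10),
                          drift_amp=0.02, noise_sd=0.02)
    male_hom_basal = dict(basal_osc_amp=0.034, basal_osc_freq_range=(0.06, 0.16),
                          drift_amp=0.016, noise_sd=0.02)
    het_basal = dict(basal_osc_amp=0.05, basal_osc_freq_range=(0.02, 0.07),
                     drift_amp=0.02, noise_sd=0.02)
    hom_basal = dict(basal_osc_amp=0.03, basal_osc_freq_range=(0.09, 0.16),
                     drift_amp=0.016, noise_sd=0.02)
    treated_basal = dict(basal_osc_amp=0.05, basal_osc_freq_range=(0.03, 0.08),
                         drift_amp=0.02, noise_sd=0.02)
    if sex == "male":
        return {
            "HET": GroupParams(
                responder_fraction=0.85, peak_amp_mean=0.452, peak_amp_sd=0.14,
                latency_mean=8.0, latency_sd=4.0, rise_tau=10.0, decay_tau=60.0,
                **male_het_basal),
            "HOM": GroupParams(
                responder_fraction=0.70, peak_amp_mean=0.305, peak_amp_sd=0.14,
                latency_mean=20.0, latency_sd=8.0, rise_tau=30.0, decay_tau=18.0,
                **male_hom_basal),
        }
    if sex == "female":
        return {
            "HET": GroupParams(
                responder_fraction=0.825, peak_amp_mean=0.335, peak_amp_sd=0.12,
                latency_mean=15.0, latency_sd=25.0, rise_tau=12.0, decay_tau=40.0,
                **het_basal),
            "HOM": GroupParams(
                responder_fraction=0.15, peak_amp_mean=0.36, peak_amp_sd=0.15,
                latency_mean=15.0, latency_sd=8.0, rise_tau=20.0, decay_tau=40.0,
                **hom_basal),
            "HOM_TREATED": GroupParams(
                responder_fraction=0.90, peak_amp_mean=0.37, peak_amp_sd=0.13,
                latency_mean=49.0, latency_sd=24.0, rise_tau=25.0, decay_tau=45.0,
                **treated_basal),
        }
    raise ValueError(f"unknown sex tag {sex!r}; expected 'male' or 'female'")


def make_default_config(sex: str, seed: int = 0) -> CohortConfig:
    """Default cohort recipe for one sex.

    The male cohort has HET and HOM groups only; the female cohort adds the
    chaperone-treated HOM group with delayed response kinetics.
    """
    params = _default_group_params(sex)
    counts = _DEFAULT_COUNTS[sex]
    groups = {g: (params[g], *counts[g]) for g in params}
    return CohortConfig(grid=TimeGrid(), groups=groups, seed=seed, sex=sex)


def _response_component(grid: TimeGrid, amp: float, latency: float,
                        rise_tau: float, decay_tau: float) -> np.ndarray:
    """Ligand-evoked component: saturating rise from onset, plateau through
    the application window, exponential decay after washout begins."""
    t = grid.times
    lh_start_t = grid.lh_start / grid.rate
    lh_end_t = grid.lh_end / grid.rate
    onset = lh_start_t + max(latency, 0.0)
    r = np.zeros(grid.n_frames)
    if amp <= 0 or onset >= lh_end_t:
        return r
    rising = (t >= onset) & (t < lh_end_t)
    if rise_tau > 0:
        r[rising] = amp * (1.0 - np.exp(-(t[rising] - onset) / rise_tau))
        level_at_end = amp * (1.0 - np.exp(-(lh_end_t - onset) / rise_tau))
    else:
        r[rising] = amp
        level_at_end = amp
    washing = t >= lh_end_t
    if decay_tau > 0:
        r[washing] = level_at_end * np.exp(-(t[washing] - lh_end_t) / decay_tau)
    return r


def _basal_component(grid: TimeGrid, params: GroupParams,
                     rng: np.random.Generator) -> np.ndarray:
    t = grid.times
    lo, hi = params.basal_osc_freq_range
    freq = rng.uniform(lo, hi)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    osc = params.basal_osc_amp * np.sin(2.0 * np.pi * freq * t + phase)
    # Random-walk drift scaled so its typical excursion is ~drift_amp.
    steps = rng.normal(0.0, 1.0, grid.n_frames)
    walk = np.cumsum(steps)
    walk -= walk[0]
    drift = params.drift_amp * walk / np.sqrt(grid.n_frames)
    noise = rng.normal(0.0, params.noise_sd, grid.n_frames)
    return osc + drift + noise


def generate_cohort(config: CohortConfig) -> TraceMatrix:
    """Generate a labeled cohort; bit-identical for identical (config, seed).

    Cells are generated group by group in canonical label order, and animal
    ids are assigned round-robin within each group.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    rows, labels, animals = [], [], []
    for label in [g for g in GROUPS if g in config.groups]:
        params, n_cells, n_animals = config.groups[label]
        for i in range(n_cells):
            trace = _basal_component(grid, params, rng)
            is_responder = rng.random() < params.responder_fraction
            amp = max(0.0, rng.normal(params.peak_amp_mean, params.peak_amp_sd))
            latency = max(0.0, rng.normal(params.latency_mean, params.latency_sd))
            if is_responder:
                trace = trace + _response_component(
                    grid, amp, latency, params.rise_tau, params.decay_tau)
            rows.append(trace)
            labels.append(label)
            animals.append(f"{label}_a{i % n_animals + 1}")
    return TraceMatrix(
        values=np.array(rows),
        labels=np.array(labels),
        animal_id=np.array(animals),
        grid=grid,
        sex=config.sex,
    )


def make_paired_config(difference: str, n_cells: int = 120, n_animals: int = 3,
                       seed: int = 0) -> CohortConfig:
    """Two-group cohort whose groups differ in exactly one trace component.

    ``difference`` selects the contrast:

    - ``"response"``: identical basal dynamics; ligand-response kinetics
      differ (latency and rise time), so all class signal lies in the
      application window.
    - ``"basal"``: identical responses; spontaneous dynamics differ
      (oscillation band and amplitude), so all class signal is pre-ligand.
    - ``"none"``: identical parameters throughout — the null cohort on which
      any classifier should sit at chance.

    Used by the saliency-localization and chance-level analyses.
    """
    shared_basal = dict(basal_osc_amp=0.04, basal_osc_freq_range=(0.02, 0.08),
                        drift_amp=0.02, noise_sd=0.02)
    shared_resp = dict(responder_fraction=0.8, peak_amp_mean=0.4, peak_amp_sd=0.1,
                       latency_mean=8.0, latency_sd=4.0, rise_tau=10.0,
                       decay_tau=60.0)
    if difference == "response":
        a = GroupParams(responder_fraction=0.9, peak_amp_mean=0.4, peak_amp_sd=0.1,
                        latency_mean=8.0, latency_sd=4.0, rise_tau=10.0,
                        decay_tau=40.0, **shared_basal)
        b = GroupParams(responder_fraction=0.9, peak_amp_mean=0.4, peak_amp_sd=0.1,
                        latency_mean=35.0, latency_sd=10.0, rise_tau=30.0,
                        decay_tau=40.0, **shared_basal)
    elif difference == "basal":
        a = GroupParams(**shared_resp, basal_osc_amp=0.06,
                        basal_osc_freq_range=(0.02, 0.05), drift_amp=0.02,
                        noise_sd=0.015)
        b = GroupParams(**shared_resp, basal_osc_amp=0.02,
                        basal_osc_freq_range=(0.10, 0.16), drift_amp=0.02,
                        noise_sd=0.015)
    elif difference == "none":
        a = b = GroupParams(**shared_resp, **shared_basal)
    else:
        raise ValueError(f"unknown difference {difference!r}")
    return CohortConfig(grid=TimeGrid(),
                        groups={"HET": (a, n_cells, n_animals),
                                "HOM": (b, n_cells, n_animals)},
                        seed=seed, sex="female")
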