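"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (spectral metrics, event detection,
classification, group statistics, differential-expression filtering, bench
assays) is exercised against cohorts produced here, so recovery can always be
judged against the inserted truth.  The LFP generator emulates the statistical
structure of kainate-evoked hippocampal slice recordings: a gamma-band
sinusoid whose amplitude rises with agonist concentration and then collapses,
riding on band-limited Gaussian noise, contaminated by brief epileptiform
"spikes" and longer interictal discharges (IIDs) at genotype-dependent Poisson
rates.  No attempt is made at biophysical realism; the targets are the
assumptions the detectors and statistics make.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "KA_LADDER",
    "LfpTrace",
    "GroundTruth",
    "EventSpec",
    "DoseResponseParams",
    "DEFAULT_DOSE_PARAMS",
    "DEFAULT_SLICES_PER_MOUSE",
    "simulate_trace",
    "simulate_cohort",
    "simulate_event_counts",
    "simulate_de_study",
    "simulate_bench_tables",
    "dose_response_amplitude",
    "spike_waveform",
    "iid_waveform",
]

#: Kainate concentration ladder (nM): baseline plus the stepped applications.
KA_LADDER: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0, 200.0, 400.0, 600.0, 800.0, 1000.0)

#: 16 slices from 6 mice per genotype.
DEFAULT_SLICES_PER_MOUSE: tuple[int, ...] = (3, 3, 3, 3, 2, 2)


@dataclass
class LfpTrace:
    """One slice x concentration local-field-potential recording."""

    samples: np.ndarray
    sampling_rate: float = 5000.0
    slice_id: str = "slice0"
    mouse_id: str = "mouse0"
    genotype: str = "WT"
    ka_nm: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def metadata(self) -> dict:
        return {
            "slice_id": self.slice_id,
            "mouse_id": self.mouse_id,
            "genotype": self.genotype,
            "ka_nm": self.ka_nm,
            "sampling_rate": self.sampling_rate,
        }


@dataclass
class GroundTruth:
    """Inserted-event bookkeeping for one simulated trace."""

    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    iid_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma_freq: float = 0.0
    gamma_amp: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.iid_times = np.asarray(self.iid_times, dtype=float)

    @property
    def n_events(self) -> int:
        return len(self.spike_times) + len(self.iid_times)


@dataclass
class EventSpec:
    """Where and how large transient events are.

    Either explicit ``times`` (seconds) or a Poisson ``rate_per_min`` may be
    given.  ``amplitude`` is the peak absolute amplitude in trace units;
    ``width_ms`` the characteristic waveform width.
    """

    times: Sequence[float] | None = None
    rate_per_min: float = 0.0
    amplitude: float = 8.0
    width_ms: float = 8.0

    def resolve_times(self, duration_s: float, rng: np.random.Generator,
                      min_separation_s: float, occupied: list[float]) -> np.ndarray:
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            if np.any((times < 0) | (times >= duration_s)):
                raise ValueError("event time outside trace")
            occupied.extend(times.tolist())
            return np.sort(times)
        n = rng.poisson(self.rate_per_min * duration_s / 60.0)
        picked: list[float] = []
        # rejection sampling keeps ground truth unambiguous (no overlap)
        margin = min_separation_s
        for _ in range(50 * max(n, 1)):
            if len(picked) == n:
                break
            t = rng.uniform(margin, duration_s - margin)
            if all(abs(t - u) >= min_separation_s for u in occupied):
                picked.append(t)
                occupied.append(t)
        return np.sort(np.asarray(picked))


@dataclass
class DoseResponseParams:
    """Per-genotype dose-response and event-rate preset.

    Gamma amplitude follows ``amp_scale * c/(c+half_sat_nm) * exp(-c/collapse_nm)``,
    a saturating rise multiplied by an exponential collapse, peaking near
    400-600 nM with the defaults.  Event rates are per minute of recording and
    apply at every non-zero agonist concentration (no spontaneous activity at
    baseline).
    """

    amp_scale: float = 20.0
    half_sat_nm: float = 150.0
    collapse_nm: float = 700.0
    spike_rate_per_min: float = 8.0
    iid_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("amp_scale", "half_sat_nm", "collapse_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_rate_per_min < 0 or self.iid_rate_per_min < 0:
            raise ValueError("event rates must be non-negative")


DEFAULT_DOSE_PARAMS: Mapping[str, DoseResponseParams] = {
    "WT": DoseResponseParams(spike_rate_per_min=8.0, iid_rate_per_min=0.0),
    "KO": DoseResponseParams(spike_rate_per_min=20.0, iid_rate_per_min=0.5),
}


def dose_response_amplitude(ka_nm: float, params: DoseResponseParams) -> float:
    """Gamma amplitude at concentration ``ka_nm`` under ``params``."""
    c = float(ka_nm)
    if c <= 0:
        return 0.0
    return params.amp_scale * c / (c + params.half_sat_nm) * np.exp(-c / params.collapse_nm)


def spike_waveform(sampling_rate: float, amplitude: float, width_ms: float = 8.0) -> np.ndarray:
    """Biphasic difference-of-Gaussians transient, peak |amplitude| as given.

    The trailing lobe is 0.6x the leading one so the absolute peak — the
    sample ground truth records as the event time — is unambiguous.
    """
    sigma = width_ms / 1000.0 / 2.5
    half = 4.0 * sigma
    t = np.arange(-half, half, 1.0 / sampling_rate)
    w = np.exp(-((t + sigma) / sigma) ** 2) - 0.6 * np.exp(-((t - sigma) / sigma) ** 2)
    return amplitude * w / np.max(np.abs(w))


def iid_waveform(sampling_rate: float, amplitude: float, width_ms: float = 80.0) -> np.ndarray:
    """Sharp transient followed by a slow wave; total width ~ ``width_ms``.

    The slow component is 0.65x the sharp peak, so with a 12 SD peak the
    above-5-SD envelope spans well over 40 ms — the duration criterion the
    detector uses to separate discharges from spikes.
    """
    sigma_fast = 0.005
    sigma_slow = width_ms / 1000.0 * 0.3125  # 25 ms at the 80 ms default
    delay = width_ms / 1000.0 * 0.375
    t = np.arange(-4 * sigma_fast, delay + 4 * sigma_slow, 1.0 / sampling_rate)
    w = np.exp(-((t / sigma_fast) ** 2)) + 0.65 * np.exp(-(((t - delay) / sigma_slow) ** 2))
    return amplitude * w / np.max(np.abs(w))


def _band_limited_noise(n: int, sampling_rate: float, sd: float,
                        rng: np.random.Generator,
                        band: tuple[float, float] = (1.0, 300.0)) -> np.ndarray:
    """White Gaussian noise band-limited to ``band`` and rescaled to ``sd``."""
    if sd == 0:
        return np.zeros(n)
    pad = int(round(sampling_rate))  # 1 s padding absorbs filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    nyq = sampling_rate / 2.0
    sos = _signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    shaped = _signal.sosfiltfilt(sos, white)[pad:pad + n]
    return shaped * (sd / shaped.std())


def _insert(samples: np.ndarray, waveform: np.ndarray, center_s: float,
            sampling_rate: float) -> None:
    center = int(round(center_s * sampling_rate))
    start = center - np.argmax(np.abs(waveform))
    if start < 0 or start + len(waveform) > len(samples):
        raise ValueError("event waveform extends outside trace")
    samples[start:start + len(waveform)] += waveform


def simulate_trace(duration_s: float = 60.0,
                   sampling_rate: float = 5000.0,
                   gamma_freq: float = 0.0,
                   gamma_amp: float = 0.0,
                   noise_sd: float = 0.0,
                   spike_spec: EventSpec | None = None,
                   iid_spec: EventSpec | None = None,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   **metadata) -> tuple[LfpTrace, GroundTruth]:
    """Simulate one recording: noise + gamma sinusoid + inserted transients.

    Deterministic given ``seed`` (or an explicit ``rng``).  Traces shorter
    than 60 s are rejected because the analysis pipeline operates on the final
    minute of each recording.
    """
    if duration_s < 60.0:
        raise ValueError(
            f"trace duration {duration_s} s is below the 60 s final-minute "
            "requirement; short traces are rejected, not truncated")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    samples = _band_limited_noise(n, sampling_rate, noise_sd, rng)
    if gamma_amp != 0.0:
        samples = samples + gamma_amp * np.sin(2 * np.pi * gamma_freq * t)
    else:
        samples = np.asarray(samples, dtype=float)

    occupied: list[float] = []
    min_sep = 0.4  # refractory window between inserted events (s)
    spike_times = np.empty(0)
    iid_times = np.empty(0)
    # IIDs placed first: they are rarer and wider
    if iid_spec is not None:
        iid_times = iid_spec.resolve_times(duration_s, rng, min_sep, occupied)
        wf = iid_waveform(sampling_rate, iid_spec.amplitude, iid_spec.width_ms)
        for ts in iid_times:
            _insert(samples, wf, ts, sampling_rate)
    if spike_spec is not None:
        spike_times = spike_spec.resolve_times(duration_s, rng, min_sep, occupied)
        wf = spike_waveform(sampling_rate, spike_spec.amplitude, spike_spec.width_ms)
        for ts in spike_times:
            _insert(samples, wf, ts, sampling_rate)

    trace = LfpTrace(samples=samples, sampling_rate=sampling_rate, **metadata)
    truth = GroundTruth(spike_times=spike_times, iid_times=iid_times,
                        gamma_freq=gamma_freq, gamma_amp=gamma_amp, noise_sd=noise_sd)
    return trace, truth


def _slice_layout(n_mice_per_genotype: int,
                  slices_per_mouse: int | Sequence[int]) -> list[int]:
    if isinstance(slices_per_mouse, int):
        layout = [slices_per_mouse] * n_mice_per_genotype
    else:
        layout = list(slices_per_mouse)
        if len(layout) != n_mice_per_genotype:
            raise ValueError("slices_per_mouse length must equal n_mice_per_genotype")
    if n_mice_per_genotype <= 0 or any(s <= 0 for s in layout):
        raise ValueError("mouse and slice counts must be positive")
    return layout


def simulate_cohort(n_mice_per_genotype: int = 6,
                    slices_per_mouse: int | Sequence[int] = DEFAULT_SLICES_PER_MOUSE,
                    ka_ladder: Sequence[float] = KA_LADDER,
                    dose_params: Mapping[str, DoseResponseParams] = DEFAULT_DOSE_PARAMS,
                    duration_s: float = 60.0,
                    sampling_rate: float = 5000.0,
                    noise_sd: float = 1.0,
                    gamma_freq: float = 40.0,
                    spike_z: float = 8.0,
                    iid_z: float = 14.0,
                    seed: int | None = None) -> list[tuple[LfpTrace, GroundTruth]]:
    """Simulate a two-genotype slice cohort: one trace per slice x concentration.

    Event amplitudes are ``spike_z`` / ``iid_z`` multiples of the total
    background SD, sqrt(noise_sd^2 + gamma_amp^2/2), because the detection
    threshold is defined on the measured final-minute SD which includes the
    oscillation.  Only the analysed final minute of each application step is
    simulated.
    """
    layout = _slice_layout(n_mice_per_genotype, slices_per_mouse)
    rng = np.random.default_rng(seed)
    out: list[tuple[LfpTrace, GroundTruth]] = []
    for genotype in dose_params:
        params = dose_params[genotype]
        slice_idx = 0
        for mouse in range(n_mice_per_genotype):
            mouse_id = f"{genotype}_m{mouse}"
            for _ in range(layout[mouse]):
                slice_id = f"{genotype}_s{slice_idx}"
                slice_idx += 1
                for ka in ka_ladder:
                    amp = dose_response_amplitude(ka, params)
                    background_sd = np.sqrt(noise_sd ** 2 + amp ** 2 / 2.0)
                    active = ka > 0
                    spike_spec = EventSpec(rate_per_min=params.spike_rate_per_min if active else 0.0,
                                           amplitude=spike_z * background_sd)
                    iid_spec = EventSpec(rate_per_min=params.iid_rate_per_min if active else 0.0,
                                         amplitude=iid_z * background_sd, width_ms=80.0)
                    out.append(simulate_trace(
                        duration_s=duration_s, sampling_rate=sampling_rate,
                        gamma_freq=gamma_freq, gamma_amp=amp, noise_sd=noise_sd,
                        spike_spec=spike_spec, iid_spec=iid_spec, rng=rng,
                        slice_id=slice_id, mouse_id=mouse_id,
                        genotype=genotype, ka_nm=float(ka)))
    return out


def simulate_event_counts(n_mice_per_genotype: int = 6,
                          slices_per_mouse: int | Sequence[int] = DEFAULT_SLICES_PER_MOUSE,
                          ka_ladder: Sequence[float] = KA_LADDER,
                          dose_params: Mapping[str, DoseResponseParams] = DEFAULT_DOSE_PARAMS,
                          duration_s: float = 60.0,
                          seed: int | None = None) -> pd.DataFrame:
    """Count-level cohort: Poisson spike/IID counts without waveform synthesis.

    Draws per-slice, per-concentration event counts from the same rates that
    drive :func:`simulate_cohort`.  Used for statistics calibration, where the
    ANOVA consumes rates and full trace synthesis would add nothing.
    """
    layout = _slice_layout(n_mice_per_genotype, slices_per_mouse)
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in dose_params:
        params = dose_params[genotype]
        slice_idx = 0
        for mouse in range(n_mice_per_genotype):
            for _ in range(layout[mouse]):
                slice_id = f"{genotype}_s{slice_idx}"
                slice_idx += 1
                for ka in ka_ladder:
                    active = ka > 0
                    minutes = duration_s / 60.0
                    spikes = rng.poisson(params.spike_rate_per_min * minutes) if active else 0
                    iids = rng.poisson(params.iid_rate_per_min * minutes) if active else 0
                    rows.append({
                        "slice_id": slice_id, "mouse_id": f"{genotype}_m{mouse}",
                        "genotype": genotype, "ka_nm": float(ka),
                        "spike_count": int(spikes), "iid_count": int(iids),
                        "spike_rate": spikes / minutes, "iid_rate": iids / minutes,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression study generator
# ---------------------------------------------------------------------------

def simulate_de_study(n_genes: int = 12000,
                      n_shared_up: int = 40,
                      n_tissue_specific: int = 60,
                      lfc_mean: float = 1.5,
                      lfc_sd: float = 0.3,
                      null_p_uniform: bool = True,
                      target_set_size: int = 400,
                      frac_targets_in_shared: float = 0.15,
                      lfc_se: float = 0.15,
                      null_lfc_sd: float = 0.05,
                      seed: int | None = None):
    """Two-tissue differential-expression tables with known truth labels.

    Returns ``(table_hippocampus, table_neocortex, target_sets, truth_labels)``.
    Truth labels partition the gene universe into ``shared_up``,
    ``hippocampus_only``, ``neocortex_only`` and ``null``.  Shared genes are
    upregulated in both tissues; tissue-specific genes are perturbed (random
    sign) in one tissue only.  Observed per-tissue statistics: logFC = true
    logFC + N(0, lfc_se); p from the two-sided normal tail of logFC/lfc_se
    (so null p-values are uniform); nulls may instead draw p ~ U(0,1) directly
    when ``null_p_uniform``.
    """
    if not 0.0 <= frac_targets_in_shared <= 1.0:
        raise ValueError("frac_targets_in_shared must lie in [0, 1]")
    if n_shared_up + 2 * n_tissue_specific > n_genes:
        raise ValueError("too many DE genes for the gene universe")
    if target_set_size > n_genes:
        raise ValueError("target_set_size exceeds gene universe")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene{i:05d}" for i in range(n_genes)])
    labels = np.full(n_genes, "null", dtype=object)
    labels[:n_shared_up] = "shared_up"
    labels[n_shared_up:n_shared_up + n_tissue_specific] = "hippocampus_only"
    labels[n_shared_up + n_tissue_specific:
           n_shared_up + 2 * n_tissue_specific] = "neocortex_only"

    def one_tissue(tissue_label: str) -> pd.DataFrame:
        true_lfc = np.zeros(n_genes)
        shared = labels == "shared_up"
        true_lfc[shared] = rng.normal(lfc_mean, lfc_sd, shared.sum())
        spec = labels == tissue_label
        signs = rng.choice([-1.0, 1.0], spec.sum())
        true_lfc[spec] = signs * rng.normal(lfc_mean, lfc_sd, spec.sum())
        obs_lfc = true_lfc + rng.normal(0.0, lfc_se, n_genes)
        null_mask = ~(shared | spec)
        obs_lfc[null_mask] = rng.normal(0.0, null_lfc_sd, null_mask.sum())
        from scipy.stats import norm
        p = 2.0 * norm.sf(np.abs(obs_lfc) / lfc_se)
        if null_p_uniform:
            p[null_mask] = rng.uniform(0.0, 1.0, null_mask.sum())
        return pd.DataFrame({"gene": genes, "logFC": obs_lfc, "pvalue": np.clip(p, 0.0, 1.0)})

    hippocampus = one_tissue("hippocampus_only")
    neocortex = one_tissue("neocortex_only")

    n_in_shared = int(round(frac_targets_in_shared * n_shared_up))
    shared_genes = genes[:n_shared_up]
    in_shared = rng.choice(shared_genes, n_in_shared, replace=False)
    non_shared_pool = genes[n_shared_up:]
    n_outside = target_set_size - n_in_shared
    outside = rng.choice(non_shared_pool, n_outside, replace=False)
    union = np.concatenate([in_shared, outside])
    rng.shuffle(union)
    half = len(union) // 2
    # both arms share a few members, mirroring real target-prediction overlap
    targets_5p = set(union[:half]) | set(in_shared)
    targets_3p = set(union[half:])
    target_sets = {"miR-324-5p_targets": targets_5p, "miR-324-3p_targets": targets_3p}
    truth = pd.Series(labels, index=genes, name="truth_label")
    return hippocampus, neocortex, target_sets, truth


# ---------------------------------------------------------------------------
# Bench assay table generators
# ---------------------------------------------------------------------------

def simulate_bench_tables(n_samples_per_genotype: int = 6,
                          goi_fold_change: float = 2.0,
                          ct_noise_sd: float = 0.15,
                          luciferase_repression: float = 0.5,
                          blot_effect: float = 1.5,
                          seed: int | None = None):
    """qPCR Ct, dual-luciferase plate and blot band-intensity tables.

    Returns ``(ct_table, luciferase_table, blot_table)``.  The gene of
    interest is elevated ``goi_fold_change``-fold in KO samples (one fewer
    amplification cycle per doubling); the 5p-mimic luciferase wells are
    scaled by ``luciferase_repression``; KO blot target bands are scaled by
    ``blot_effect``.
    """
    if goi_fold_change <= 0:
        raise ValueError("fold change must be positive")
    rng = np.random.default_rng(seed)

    ct_rows = []
    baseline_delta = 5.0  # GOI amplifies 5 cycles after the normaliser in WT
    for genotype in ("WT", "KO"):
        shift = -np.log2(goi_fold_change) if genotype == "KO" else 0.0
        for i in range(n_samples_per_genotype):
            ct_norm = 20.0 + rng.normal(0.0, ct_noise_sd)
            ct_goi = ct_norm + baseline_delta + shift + rng.normal(0.0, ct_noise_sd)
            ct_rows.append({"sample_id": f"{genotype}_{i}", "genotype": genotype,
                            "gene": "Suox", "ct_goi": ct_goi, "ct_norm": ct_norm})
    ct_table = pd.DataFrame(ct_rows)

    luc_rows = []
    base_ratio = 0.8
    for construct in ("Suox-3UTR", "Cd300lf-3UTR"):
        for mimic in ("miCon", "miR-324-5p", "miR-324-3p"):
            factor = luciferase_repression if mimic == "miR-324-5p" else 1.0
            for well in range(6):
                renilla = rng.normal(1e5, 5e3)
                firefly = renilla * base_ratio * factor * np.exp(rng.normal(0.0, 0.03))
                luc_rows.append({"well_id": f"{construct}_{mimic}_{well}",
                                 "construct": construct, "mimic": mimic,
                                 "firefly": firefly, "renilla": renilla})
    luciferase_table = pd.DataFrame(luc_rows)

    blot_rows = []
    for genotype in ("WT", "KO"):
        factor = blot_effect if genotype == "KO" else 1.0
        for i in range(n_samples_per_genotype):
            gapdh = rng.normal(1.0, 0.05)
            target = gapdh * factor * np.exp(rng.normal(0.0, 0.05))
            blot_rows.append({"lane_id": f"{genotype}_{i}", "genotype": genotype,
                              "target_intensity": target, "gapdh_intensity": gapdh})
    blot_table = pd.DataFrame(blot_rows)
    return ct_table, luciferase_table, blot_table
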