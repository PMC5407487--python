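"""Synthetic snapshot cohorts with known clock phases.

Emulates the statistical structure the ordering method assumes: each sample
is a static snapshot of a periodic traveling wave of expression sweeping the
posterior -> anterior axis (a clock-gene band, Lfng(i)-like), optionally on
top of a static rostro-caudal gradient (Dll1/Notch1-like), with additive
Gaussian noise.  Every sample carries a known ground-truth phase, so
ordering recovery can be scored exactly.

Two signal shapes are provided.  ``sinusoid`` produces rows that are exact
sampled cosines under uniform-grid phases, for which the periodicity
objective has a closed-form zero — the clean test case.  ``band`` (the
default) is a Gaussian bump whose center tracks the phase across one cycle,
the biologically faithful stress case mimicking the sweeping expression
band.  The simulator emits profiles, not pixel images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .profiles import IntensityMatrix, SpatialProfile, build_matrix

__all__ = ["WaveModel", "SyntheticCohort", "wave_profile", "simulate_cohort", "paired_cohort"]


@dataclass
class WaveModel:
    """Generative parameters of a synthetic traveling-wave cohort.

    amplitude : peak oscillatory signal (arbitrary units).
    band_width : std. dev. of the Gaussian band as a fraction of the axis
        (band mode); 0.1 spans roughly one fifth of the PSM at half maximum.
    wave_number : spatial periods across [0, 1] (sinusoid mode).
    gradient_slope : static linear rostro-caudal component (signal units per
        unit axis); models a steady anteriorly increasing baseline.
    baseline : constant offset.
    noise_fraction : additive Gaussian noise std. as a fraction of amplitude.
    n_bins : number of axial bins per profile.
    """

    mode: str = "band"
    amplitude: float = 1.0
    band_width: float = 0.1
    wave_number: float = 1.0
    gradient_slope: float = 0.0
    baseline: float = 0.0
    noise_fraction: float = 0.1
    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("sinusoid", "band"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")
        if self.mode == "band" and not self.band_width > 0:
            raise ValueError("band_width must be positive in band mode")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class SyntheticCohort:
    """M synthetic snapshot profiles with their ground-truth phases.

    ``true_phases[j]`` is the clock phase of the j-th presented profile;
    ``true_order`` is the argsort of the phases, i.e. the permutation a
    perfect ordering method should recover (up to rotation/reflection).
    """

    profiles: list[SpatialProfile]
    true_phases: np.ndarray
    true_order: np.ndarray
    model: WaveModel
    seed: int

    def __post_init__(self) -> None:
        self.true_phases = np.asarray(self.true_phases, dtype=float)
        self.true_order = np.asarray(self.true_order, dtype=int)
        if len(self.profiles) != self.true_phases.size:
            raise ValueError("one phase per profile required")
        if not np.array_equal(self.true_order, np.argsort(self.true_phases, kind="stable")):
            raise ValueError("true_order must be the argsort of true_phases")

    @property
    def n_samples(self) -> int:
        return len(self.profiles)

    def to_matrix(self) -> IntensityMatrix:
        """Assemble the cohort into an intensity matrix on its own bin grid."""
        return build_matrix(self.profiles, self.model.n_bins)


def wave_profile(x, phase: float, model: WaveModel):
    """Noise-free signal at position(s) ``x`` for a snapshot at ``phase``.

    sinusoid: baseline + slope*x + amplitude*(1 + cos(2 pi wave_number x - phase))/2
    band:     baseline + slope*x + amplitude * exp(-(x - c)^2 / (2 band_width^2)),
              with band center c = phase / 2pi sweeping posterior -> anterior
              over one cycle.  Clipped at zero.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("positions must lie in [0, 1]")
    base = model.baseline + model.gradient_slope * x
    if model.mode == "sinusoid":
        signal = model.amplitude * (1 + np.cos(2 * np.pi * model.wave_number * x - phase)) / 2
    else:
        center = phase / (2 * np.pi)
        signal = model.amplitude * np.exp(-((x - center) ** 2) / (2 * model.band_width**2))
    return np.clip(base + signal, 0.0, None)


def _draw_phases(m: int, scheme: str, rng: np.random.Generator) -> np.ndarray:
    if scheme == "uniform-grid":
        return 2 * np.pi * np.arange(m) / m
    if scheme == "uniform-random":
        return rng.uniform(0.0, 2 * np.pi, size=m)
    raise ValueError(f"unknown phase scheme {scheme!r}")


def _make_profiles(model, phases, sample_ids, channel, noise_rng):
    x = (np.arange(model.n_bins) + 0.5) / model.n_bins
    profiles = []
    for sid, phase in zip(sample_ids, phases):
        clean = wave_profile(x, phase, model)
        noisy = clean + noise_rng.normal(0.0, model.noise_fraction * model.amplitude, model.n_bins)
        profiles.append(
            SpatialProfile(
                sample_id=sid,
                channel=channel,
                positions=x,
                intensities=np.clip(noisy, 0.0, None),
                normalized=False,
                metadata={"true_phase": float(phase)},
            )
        )
    return profiles


def simulate_cohort(
    model: WaveModel,
    n_samples: int,
    phase_scheme: str = "uniform-grid",
    seed: int = 0,
    shuffle: bool = False,
    channel: str = "Lfng_i",
) -> SyntheticCohort:
    """Draw a cohort of M snapshots at known phases.

    ``uniform-grid`` phases are 2 pi m / M (the cohort evenly tiles one
    cycle); ``uniform-random`` draws i.i.d. phases.  With ``shuffle`` the
    profiles are presented in a seeded random order — the situation the
    ordering method faces — while ``true_order`` still records the phase
    sort.  Fully reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    root = np.random.SeedSequence(seed)
    phase_rng, noise_rng, shuffle_rng = (np.random.default_rng(s) for s in root.spawn(3))
    phases = _draw_phases(n_samples, phase_scheme, phase_rng)
    ids = [f"s{j:03d}" for j in range(n_samples)]
    profiles = _make_profiles(model, phases, ids, channel, noise_rng)
    if shuffle:
        presentation = shuffle_rng.permutation(n_samples)
        profiles = [profiles[j] for j in presentation]
        phases = phases[presentation]
    return SyntheticCohort(
        profiles=profiles,
        true_phases=phases,
        true_order=np.argsort(phases, kind="stable"),
        model=model,
        seed=seed,
    )


def paired_cohort(
    reference_model: WaveModel,
    partner_model: WaveModel,
    phase_offset: float,
    n_samples: int,
    seed: int = 0,
    phase_scheme: str = "uniform-grid",
    shuffle: bool = False,
    reference_channel: str = "Lfng_i",
    partner_channel: str = "Dll1",
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two cohorts sharing samples, phases offset by a constant.

    Emulates contralateral explant pairs: one half reports the clock gene
    (reference), the other the protein of interest (partner) whose phase
    lags or leads by ``phase_offset``.  Both cohorts share sample_ids and
    presentation order; their noise streams are independent, so identical
    models with zero offset give identical signal but different noise.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    root = np.random.SeedSequence(seed)
    phase_rng, ref_noise, partner_noise, shuffle_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    phases = _draw_phases(n_samples, phase_scheme, phase_rng)
    partner_phases = np.mod(phases + phase_offset, 2 * np.pi)
    ids = [f"s{j:03d}" for j in range(n_samples)]
    ref_profiles = _make_profiles(reference_model, phases, ids, reference_channel, ref_noise)
    partner_profiles = _make_profiles(
        partner_model, partner_phases, ids, partner_channel, partner_noise
    )
    if shuffle:
        presentation = shuffle_rng.permutation(n_samples)
        ref_profiles = [ref_profiles[j] for j in presentation]
        partner_profiles = [partner_profiles[j] for j in presentation]
        phases = phases[presentation]
        partner_phases = partner_phases[presentation]
    reference = SyntheticCohort(
        profiles=ref_profiles,
        true_phases=phases,
        true_order=np.argsort(phases, kind="stable"),
        model=reference_model,
        seed=seed,
    )
    partner = SyntheticCohort(
        profiles=partner_profiles,
        true_phases=partner_phases,
        true_order=np.argsort(partner_phases, kind="stable"),
        model=partner_model,
        seed=seed,
    )
    return reference, partner
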