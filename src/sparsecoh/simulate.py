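"""Synthetic multichannel EEG with analytically known pairwise coherence.

Sessions are linear mixtures of band-limited latent sources plus sensor
noise:

    c(t) = sum_s loadings[c, s] * b_s(t) + noise_sd * eps_c(t)

where each ``b_s`` is zero-phase brick-wall band-passed white Gaussian
noise with a flat one-sided in-band spectral density (so coherence is flat
within a band and has a closed form), and ``eps_c`` is independent white
Gaussian noise. Because the model is linear and spectrally flat per band,
the in-band cross-spectral matrix — and hence every pairwise
magnitude-squared coherence — is known exactly, which is what makes the
generator usable as a ground-truth oracle for the estimation pipeline.

Cohorts emulate a two-arm (active / sham), two-timepoint (pre / post)
resting-EEG study on the 8-electrode dry cap. Group effects are planted as
latent "coupling" sources whose electrode loadings are solved from the
bipolar incidence matrix so the source is exposed on exactly the two
target bipolar sites; active-post sessions shift the coupling strength
(delta-band increase on a midline central-occipital connection, decrease
on a right frontal-central connection), all other cells share the null
generator. Synthetic percent-change symptom scores are linearly coupled to
each active participant's post-treatment right-frontal coherence (lower
coherence <-> greater improvement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import (
    DEFAULT_BIPOLAR_PAIRS,
    STUDY_ELECTRODES,
    BipolarMontage,
    RawSession,
)
from .spectral import BAND_BY_NAME, BandDefinition


class SimulationSpecError(ValueError):
    """Invalid simulation specification."""


@dataclass(frozen=True)
class SourceSpec:
    """A band-limited latent source.

    ``power`` is the one-sided in-band spectral density in µV²/Hz; outside
    [band_low, band_high] the source has no power.
    """

    band_low: float
    band_high: float
    power: float

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high <= 50:
            raise SimulationSpecError(
                f"band edges must satisfy 0 < low < high <= 50, got "
                f"[{self.band_low}, {self.band_high}]"
            )
        if self.power <= 0:
            raise SimulationSpecError("source power must be positive")


@dataclass
class MixingModel:
    """Linear electrode-space mixing of latent sources plus sensor noise."""

    loadings: np.ndarray  # n_channels x n_sources, dimensionless
    noise_sd: float = 4.0  # µV per sample
    fs: float = 500.0
    duration: float = 408.0  # 6.8 min of usable eyes-closed data
    channel_names: tuple[str, ...] = STUDY_ELECTRODES

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        if not np.all(np.isfinite(self.loadings)):
            raise SimulationSpecError("loadings must be finite")
        if self.noise_sd <= 0:
            raise SimulationSpecError("noise_sd must be positive")
        if self.fs <= 0 or self.duration <= 0:
            raise SimulationSpecError("fs and duration must be positive")
        if len(self.channel_names) != self.loadings.shape[0]:
            raise SimulationSpecError(
                "channel_names length must match loadings rows"
            )

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]

    @property
    def noise_density(self) -> float:
        """One-sided white-noise spectral density, µV²/Hz."""
        return 2.0 * self.noise_sd**2 / self.fs


def band_limited_noise(
    n_samples: int,
    fs: float,
    band_low: float,
    band_high: float,
    power: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-phase brick-wall band-passed white noise with flat in-band density.

    White Gaussian noise is masked in the rFFT domain to [band_low,
    band_high] (band edges inclusive) and scaled so the one-sided in-band
    density equals ``power`` µV²/Hz exactly in expectation.
    """
    w = rng.standard_normal(n_samples)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(f < band_low) | (f > band_high)] = 0.0
    # unit-variance white noise has one-sided density 2/fs
    return np.fft.irfft(spec, n_samples) * np.sqrt(power * fs / 2.0)


def simulate_session(
    model: MixingModel,
    sources: Sequence[SourceSpec],
    seed,
    arm: str = "active",
    timepoint: str = "pre",
    participant_id: str = "p0",
    symptoms: dict | None = None,
) -> RawSession:
    """Simulate one referential-space EEG session; deterministic given seed."""
    if len(sources) == 0:
        raise SimulationSpecError("at least one source is required")
    if model.loadings.shape[1] != len(sources):
        raise SimulationSpecError(
            f"loadings have {model.loadings.shape[1]} source columns but "
            f"{len(sources)} sources given"
        )
    rng = np.random.default_rng(seed)
    n = int(round(model.fs * model.duration))
    b = np.empty((len(sources), n))
    for s, spec in enumerate(sources):
        b[s] = band_limited_noise(
            n, model.fs, spec.band_low, spec.band_high, spec.power, rng
        )
    samples = model.loadings @ b
    samples += model.noise_sd * rng.standard_normal((model.n_channels, n))
    return RawSession(
        samples=samples,
        fs=model.fs,
        electrode_names=model.channel_names,
        arm=arm,
        timepoint=timepoint,
        participant_id=participant_id,
        symptoms=dict(symptoms or {}),
    )


def expected_coherence(
    a1: float, a2: float, source_power: float, noise_density: float
) -> float:
    """Closed-form magnitude-squared coherence for one shared source.

    Two channels with loadings ``a1``, ``a2`` on a common band-limited
    source of in-band density ``P`` plus independent noise of density
    ``N`` have in-band coherence

        C = (a1 * a2 * P)**2 / ((a1**2 P + N) * (a2**2 P + N))

    With equal loadings this is the (SNR / (1 + SNR))**2 family. Used as
    the analytic ground truth for the Welch estimator.
    """
    if noise_density <= 0:
        raise SimulationSpecError("noise_density must be positive")
    num = (a1 * a2 * source_power) ** 2
    den = (a1**2 * source_power + noise_density) * (
        a2**2 * source_power + noise_density
    )
    return float(num / den)


# ---------------------------------------------------------------------------
# analytic cross-spectra for arbitrary mixings (the general oracle)
# ---------------------------------------------------------------------------

def analytic_csd_matrix(
    model: MixingModel,
    sources: Sequence[SourceSpec],
    f: float,
    incidence: np.ndarray | None = None,
) -> np.ndarray:
    """Exact cross-spectral density matrix of the mixing model at frequency f.

    In channel space: S(f) = sum_s P_s(f) m_s m_s^T + N I. If a bipolar
    incidence matrix B is given, returns the site-space matrix B S B^T.
    """
    L = model.loadings
    S = np.zeros((model.n_channels, model.n_channels))
    for s, spec in enumerate(sources):
        if spec.band_low <= f <= spec.band_high:
            S += spec.power * np.outer(L[:, s], L[:, s])
    S += model.noise_density * np.eye(model.n_channels)
    if incidence is not None:
        S = incidence @ S @ incidence.T
    return S


def analytic_band_coherence(
    model: MixingModel,
    sources: Sequence[SourceSpec],
    band: BandDefinition,
    site_i: int,
    site_j: int,
    incidence: np.ndarray | None = None,
    n_eval: int = 5,
) -> float:
    """Model-implied band-average coherence between two (site) channels.

    Evaluates the exact coherence on an interior frequency grid of the
    band and averages; for sources aligned to the band edges the value is
    flat, so the grid density is immaterial.
    """
    fgrid = np.linspace(band.low, band.high, n_eval + 2)[1:-1]
    vals = []
    for f in fgrid:
        S = analytic_csd_matrix(model, sources, f, incidence)
        denom = S[site_i, site_i] * S[site_j, site_j]
        vals.append(abs(S[site_i, site_j]) ** 2 / denom if denom > 0 else np.nan)
    return float(np.nanmean(vals))


def coupling_loadings(
    montage: BipolarMontage,
    electrode_names: Sequence[str],
    site_pair: tuple[str, str],
) -> np.ndarray:
    """Electrode loadings exposing a source on exactly two bipolar sites.

    Solves B v = u (B the montage's signed incidence matrix, u the
    indicator of the two target sites) with the minimum-norm solution, so
    the latent source enters both target site traces with coefficient 1
    and every other site with coefficient 0. Feasible whenever u is
    orthogonal to the cycle space of the montage graph; infeasibility is
    reported as a spec error.
    """
    sites = montage.site_names
    for s in site_pair:
        if s not in sites:
            raise SimulationSpecError(
                f"effect connection site {s!r} not in montage "
                f"(sites: {', '.join(sites)})"
            )
    B = montage.incidence(electrode_names)
    u = np.zeros(len(sites))
    u[sites.index(site_pair[0])] = 1.0
    u[sites.index(site_pair[1])] = 1.0
    v, *_ = np.linalg.lstsq(B, u, rcond=None)
    if not np.allclose(B @ v, u, atol=1e-10):
        raise SimulationSpecError(
            f"connection {site_pair} cannot be planted exactly on this "
            "montage (target pattern lies outside the incidence range)"
        )
    return v


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectConnection:
    """A planted group effect on one bipolar-site pair in one band."""

    sites: tuple[str, str]
    band: str = "delta"
    direction: str = "increase"  # or "decrease"

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise SimulationSpecError(
                f"direction must be increase/decrease, got {self.direction!r}"
            )
        if self.band not in BAND_BY_NAME:
            raise SimulationSpecError(f"unknown band {self.band!r}")


#: delta-band effects mirroring the treatment signature: midline
#: central-occipital coherence up, right frontal-central coherence down
DEFAULT_EFFECTS: tuple[EffectConnection, ...] = (
    EffectConnection(("Fz-Cz", "Pz-Oz"), "delta", "increase"),
    EffectConnection(("FP2-Fz", "Cz-Pz"), "delta", "decrease"),
)

#: per-electrode background rhythm densities, µV²/Hz (free parameters of
#: the generator; delta-dominant eyes-closed-like spectrum)
DEFAULT_BAND_POWER = {"delta": 12.0, "theta": 8.0, "alpha": 10.0, "beta": 3.0}


@dataclass
class CohortSpec:
    """Study-shaped synthetic cohort: two arms, two timepoints.

    The planted coherence shifts apply only to (arm=active,
    timepoint=post) sessions; every other cell shares the null generator.
    ``effect_magnitude`` is the loading delta applied to the coupling
    sources (not a coherence delta; the implied coherence shift is
    available through :func:`analytic_band_coherence`).
    """

    n_active: int = 19
    n_sham: int = 16
    timepoints: tuple[str, ...] = ("pre", "post")
    effect_connections: tuple[EffectConnection, ...] = DEFAULT_EFFECTS
    effect_magnitude: float = 0.6
    seed: int = 0
    # generator conditions
    duration: float = 408.0
    fs: float = 500.0
    noise_sd: float = 4.0
    band_power: dict = field(default_factory=lambda: dict(DEFAULT_BAND_POWER))
    baseline_coupling: float = 1.2
    coupling_jitter_sd: float = 0.15
    background_jitter_sd: float = 0.10
    montage: BipolarMontage = field(
        default_factory=lambda: BipolarMontage(DEFAULT_BIPOLAR_PAIRS)
    )
    electrode_names: tuple[str, ...] = STUDY_ELECTRODES
    # symptom coupling (percent-change scale, positive = improvement)
    symptom_rho: dict = field(
        default_factory=lambda: {"ids_sr": -0.68, "pcl5": -0.54}
    )
    symptom_scale: dict = field(
        default_factory=lambda: {
            "active_mean": 35.0, "sham_mean": 10.0, "sd": 20.0,
        }
    )

    def __post_init__(self) -> None:
        if self.n_active < 2 or self.n_sham < 2:
            raise SimulationSpecError("need at least 2 participants per arm")
        if self.effect_magnitude < 0:
            raise SimulationSpecError("effect_magnitude must be >= 0")
        for eff in self.effect_connections:
            for s in eff.sites:
                if s not in self.montage.site_names:
                    raise SimulationSpecError(
                        f"effect connection site {s!r} not in montage"
                    )


def _cohort_sources(spec: CohortSpec) -> tuple[list[SourceSpec], np.ndarray, list[np.ndarray]]:
    """Background + coupling source specs, base loadings, coupling vectors.

    Returns (sources, background_loadings, coupling_vectors) where the
    coupling columns are appended after the background columns in the
    order of ``spec.effect_connections``.
    """
    n_elec = len(spec.electrode_names)
    sources: list[SourceSpec] = []
    cols: list[np.ndarray] = []
    for e in range(n_elec):
        for band_name, power in spec.band_power.items():
            band = BAND_BY_NAME[band_name]
            sources.append(SourceSpec(band.low, band.high, power))
            col = np.zeros(n_elec)
            col[e] = 1.0
            cols.append(col)
    background = np.column_stack(cols)

    couplings: list[np.ndarray] = []
    for eff in spec.effect_connections:
        band = BAND_BY_NAME[eff.band]
        power = spec.band_power.get(eff.band, 10.0)
        sources.append(SourceSpec(band.low, band.high, power))
        couplings.append(
            coupling_loadings(spec.montage, spec.electrode_names, eff.sites)
        )
    return sources, background, couplings


def _session_loadings(
    background: np.ndarray,
    couplings: list[np.ndarray],
    bg_jitter: np.ndarray,
    coupling_strengths: np.ndarray,
) -> np.ndarray:
    return np.hstack(
        [background * bg_jitter[np.newaxis, :]]
        + [(g * v)[:, np.newaxis] for g, v in zip(coupling_strengths, couplings)]
    )


def simulate_cohort(spec: CohortSpec) -> list[RawSession]:
    """Generate the labeled cohort; deterministic given ``spec.seed``.

    Participant-level loading jitter gives between-subject variability;
    active-post coupling strengths are shifted by ``effect_magnitude`` in
    each effect's direction. Symptom percent-change scores are attached to
    every session of a participant: active-arm scores are linearly coupled
    (correlation ``symptom_rho``) to the participant's model-implied
    post-treatment coherence on the first *decrease* connection (the right
    frontal-central one by default); sham scores are uncoupled noise.
    """
    sources, background, couplings = _cohort_sources(spec)
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_active + spec.n_sham
    part_seeds = ss.spawn(n_total + 1)
    score_rng = np.random.default_rng(part_seeds[-1])

    arms = ["active"] * spec.n_active + ["sham"] * spec.n_sham
    pids = [f"A{i + 1:02d}" for i in range(spec.n_active)] + [
        f"S{i + 1:02d}" for i in range(spec.n_sham)
    ]

    deltas = np.array(
        [
            spec.effect_magnitude
            if eff.direction == "increase"
            else -spec.effect_magnitude
            for eff in spec.effect_connections
        ]
    )

    # first pass: draw per-participant jitters and coupling strengths
    per_part: list[dict] = []
    for k in range(n_total):
        prng = np.random.default_rng(part_seeds[k])
        bg_jitter = 1.0 + spec.background_jitter_sd * prng.standard_normal(
            background.shape[1]
        )
        eta = spec.coupling_jitter_sd * prng.standard_normal(len(couplings))
        g_null = spec.baseline_coupling * (1.0 + eta)
        shifted = spec.baseline_coupling + deltas
        g_post_active = np.maximum(shifted * (1.0 + eta), 0.0)
        session_seed_pool = prng.integers(0, 2**31 - 1, size=len(spec.timepoints))
        per_part.append(
            dict(
                bg_jitter=bg_jitter,
                g_null=np.maximum(g_null, 0.0),
                g_post_active=g_post_active,
                session_seeds=session_seed_pool,
            )
        )

    # model-implied post-treatment coherence on the symptom-linked connection
    decrease_idx = next(
        (
            i
            for i, eff in enumerate(spec.effect_connections)
            if eff.direction == "decrease"
        ),
        0 if spec.effect_connections else None,
    )
    B = spec.montage.incidence(spec.electrode_names)
    true_coh = np.full(n_total, np.nan)
    if decrease_idx is not None:
        eff = spec.effect_connections[decrease_idx]
        band = BAND_BY_NAME[eff.band]
        i_site = spec.montage.site_names.index(eff.sites[0])
        j_site = spec.montage.site_names.index(eff.sites[1])
        for k in range(n_total):
            g = (
                per_part[k]["g_post_active"]
                if arms[k] == "active"
                else per_part[k]["g_null"]
            )
            loadings = _session_loadings(
                background, couplings, per_part[k]["bg_jitter"], g
            )
            model = MixingModel(
                loadings=loadings,
                noise_sd=spec.noise_sd,
                fs=spec.fs,
                duration=spec.duration,
                channel_names=tuple(spec.electrode_names),
            )
            true_coh[k] = analytic_band_coherence(
                model, sources, band, i_site, j_site, incidence=B
            )

    # symptom scores: coupled for active, noise for sham
    symptoms_by_part: list[dict] = [dict() for _ in range(n_total)]
    active_idx = np.arange(spec.n_active)
    scale = spec.symptom_scale
    if decrease_idx is not None and spec.n_active >= 3:
        z = true_coh[active_idx]
        z = (z - z.mean()) / (z.std(ddof=1) if z.std(ddof=1) > 0 else 1.0)
    else:
        z = np.zeros(len(active_idx))
    for name, rho in spec.symptom_rho.items():
        eps = score_rng.standard_normal(n_total)
        for k in range(n_total):
            if arms[k] == "active":
                zk = rho * z[k] + np.sqrt(max(0.0, 1 - rho**2)) * eps[k]
                val = scale["active_mean"] + scale["sd"] * zk
            else:
                val = scale["sham_mean"] + scale["sd"] * eps[k]
            symptoms_by_part[k][f"{name}_pct_change"] = float(val)

    # second pass: simulate sessions
    sessions: list[RawSession] = []
    for k in range(n_total):
        for t, tp in enumerate(spec.timepoints):
            is_effect_cell = arms[k] == "active" and tp == "post"
            g = (
                per_part[k]["g_post_active"]
                if is_effect_cell
                else per_part[k]["g_null"]
            )
            loadings = _session_loadings(
                background, couplings, per_part[k]["bg_jitter"], g
            )
            model = MixingModel(
                loadings=loadings,
                noise_sd=spec.noise_sd,
                fs=spec.fs,
                duration=spec.duration,
                channel_names=tuple(spec.electrode_names),
            )
            sessions.append(
                simulate_session(
                    model,
                    sources,
                    seed=int(per_part[k]["session_seeds"][t]),
                    arm=arms[k],
                    timepoint=tp,
                    participant_id=pids[k],
                    symptoms=symptoms_by_part[k],
                )
            )
    return sessions


def null_cohort_spec(**overrides) -> CohortSpec:
    """A cohort spec with no planted effect (all cells exchangeable)."""
    overrides.setdefault("effect_magnitude", 0.0)
    return CohortSpec(**overrides)
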