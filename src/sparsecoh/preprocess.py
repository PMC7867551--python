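"""Raw-to-epochs preprocessing for the sparse 8-electrode montage.

The pipeline mirrors standard practice for dry-electrode resting EEG:
referential recordings are re-referenced into nearest-neighbor bipolar
derivations (amplitude subtraction), segmented into non-overlapping 2-s
epochs, screened with deterministic amplitude/drift criteria, and checked
against the minimum-usable-data inclusion rule (>120 s, i.e. sixty 2-s
epochs, with all sites present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

#: electrode set of the 8-channel dry cap, in acquisition order
STUDY_ELECTRODES: tuple[str, ...] = (
    "FP1", "FP2", "FPz", "F3", "Fz", "Cz", "Pz", "Oz",
)

#: default nearest-neighbor bipolar derivations on the 10-20 layout
DEFAULT_BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "F3"),
    ("FP2", "Fz"),
    ("FPz", "Fz"),
    ("F3", "Fz"),
    ("Fz", "Cz"),
    ("Cz", "Pz"),
    ("Pz", "Oz"),
    ("FP1", "FPz"),
)

DEFAULT_EPOCH_LENGTH_S = 2.0
MIN_USABLE_EPOCHS = 60  # sixty 2-s epochs == the >120 s usable-data rule
DEFAULT_AMP_THRESHOLD_UV = 100.0
DEFAULT_DRIFT_THRESHOLD_UV = 100.0


class MontageError(ValueError):
    """A montage references electrodes absent from the recording."""


class PreprocessError(ValueError):
    """Invalid preprocessing input (bad durations, thresholds, ...)."""


@dataclass
class RawSession:
    """One labeled multichannel EEG recording in referential space.

    Parameters
    ----------
    samples : ndarray, shape (n_electrodes, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz (500 for the study device).
    electrode_names : sequence of str
        Channel order of ``samples``.
    arm : {"active", "sham"}
    timepoint : {"pre", "post"}
    participant_id : str
    symptoms : dict
        Optional percent-change scores (positive = improvement), keyed
        ``ids_sr_pct_change`` / ``pcl5_pct_change``.
    """

    samples: np.ndarray
    fs: float
    electrode_names: Sequence[str]
    arm: str = "active"
    timepoint: str = "pre"
    participant_id: str = "p0"
    symptoms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise PreprocessError("samples must be 2-D (electrodes x time)")
        if self.samples.shape[0] != len(self.electrode_names):
            raise PreprocessError(
                f"{self.samples.shape[0]} rows but "
                f"{len(self.electrode_names)} electrode names"
            )
        if not np.all(np.isfinite(self.samples)):
            raise PreprocessError("samples contain non-finite values")
        if self.fs <= 0:
            raise PreprocessError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class BipolarMontage:
    """Ordered list of (anode, cathode) electrode pairs.

    Each derived site is named ``"<anode>-<cathode>"``; the site trace is
    the sample-wise amplitude difference anode − cathode.
    """

    pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(f"{a}-{c}" for a, c in self.pairs)

    @property
    def n_sites(self) -> int:
        return len(self.pairs)

    def incidence(self, electrode_names: Sequence[str]) -> np.ndarray:
        """Signed incidence matrix B (sites x electrodes): site = B @ electrodes."""
        names = list(electrode_names)
        missing = sorted(
            {e for pair in self.pairs for e in pair if e not in names}
        )
        if missing:
            raise MontageError(
                "montage references electrodes not in the recording: "
                + ", ".join(missing)
            )
        B = np.zeros((len(self.pairs), len(names)))
        for k, (anode, cathode) in enumerate(self.pairs):
            B[k, names.index(anode)] = 1.0
            B[k, names.index(cathode)] = -1.0
        return B

    @classmethod
    def from_file(cls, path) -> "BipolarMontage":
        """Read a two-column whitespace/comma-delimited electrode-pair file."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise MontageError(f"bad montage line: {line!r}")
                pairs.append((parts[0], parts[1]))
        if not pairs:
            raise MontageError("montage file lists no pairs")
        return cls(pairs=tuple(pairs))


@dataclass
class BipolarRecording:
    """Continuous 8-site recording after bipolar derivation."""

    samples: np.ndarray  # sites x time, µV
    fs: float
    site_names: tuple[str, ...]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs of a bipolar recording.

    ``kept_epoch_indices`` tracks each epoch's position in the original
    segmentation so artifact rejection retains provenance.
    """

    epochs: np.ndarray  # epoch x site x sample, µV
    fs: float
    epoch_length: float
    site_names: tuple[str, ...]
    kept_epoch_indices: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.kept_epoch_indices = np.asarray(self.kept_epoch_indices, dtype=int)
        if self.epochs.ndim != 3:
            raise PreprocessError("epochs must be 3-D (epoch x site x sample)")
        if len(self.kept_epoch_indices) != self.epochs.shape[0]:
            raise PreprocessError("kept_epoch_indices length mismatch")
        if np.any(np.diff(self.kept_epoch_indices) <= 0):
            raise PreprocessError("kept_epoch_indices must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.epochs.shape[1]


@dataclass(frozen=True)
class InclusionDecision:
    passed: bool
    reason: str | None = None  # "insufficient-data" | "missing-channel"
    n_epochs: int = 0

    def __bool__(self) -> bool:
        return self.passed


def to_bipolar(
    session: RawSession, montage: BipolarMontage | None = None
) -> BipolarRecording:
    """Re-reference a referential session into bipolar derivations.

    Each site trace is the sample-wise amplitude subtraction
    anode − cathode; site order follows the montage order.
    """
    montage = montage or BipolarMontage()
    B = montage.incidence(session.electrode_names)
    return BipolarRecording(
        samples=B @ session.samples,
        fs=session.fs,
        site_names=montage.site_names,
    )


def bandpass_acquisition(
    session: RawSession, low: float = 0.5, high: float = 50.0, order: int = 4
) -> RawSession:
    """Optional zero-phase 0.5-50 Hz band-pass replicating the recorder filter.

    The study amplifier applies this at acquisition time; simulated or
    unfiltered inputs can be passed through here for parity.
    """
    sos = signal.butter(order, [low, high], btype="bandpass", fs=session.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, session.samples, axis=1)
    return RawSession(
        samples=filtered,
        fs=session.fs,
        electrode_names=session.electrode_names,
        arm=session.arm,
        timepoint=session.timepoint,
        participant_id=session.participant_id,
        symptoms=dict(session.symptoms),
    )


def segment_epochs(
    recording: BipolarRecording, epoch_length: float = DEFAULT_EPOCH_LENGTH_S
) -> EpochSet:
    """Cut a continuous recording into non-overlapping fixed-length epochs.

    Trailing samples that do not fill a whole epoch are discarded; a
    recording shorter than one epoch yields an empty EpochSet.
    """
    if epoch_length <= 0:
        raise PreprocessError("epoch_length must be positive")
    n_per = int(round(recording.fs * epoch_length))
    n_epochs = recording.samples.shape[1] // n_per
    sites = recording.samples.shape[0]
    trimmed = recording.samples[:, : n_epochs * n_per]
    epochs = trimmed.reshape(sites, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        fs=recording.fs,
        epoch_length=epoch_length,
        site_names=recording.site_names,
        kept_epoch_indices=np.arange(n_epochs),
    )


def reject_artifacts(
    epochs: EpochSet,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD_UV,
) -> EpochSet:
    """Remove epochs with large amplitudes or amplifier-like drift.

    Deterministic stand-in for visual artifact inspection: an epoch is
    dropped if any site's peak absolute amplitude exceeds ``amp_threshold``
    (µV), or if the range of the within-epoch least-squares linear trend at
    any site exceeds ``drift_threshold`` (µV per epoch).
    """
    if amp_threshold <= 0 or drift_threshold <= 0:
        raise PreprocessError("artifact thresholds must be positive")
    if epochs.n_epochs == 0:
        return epochs

    x = epochs.epochs
    peak = np.abs(x).max(axis=2)  # epoch x site

    n = x.shape[2]
    t = np.arange(n) - (n - 1) / 2.0
    # slope of the LS linear fit per epoch/site; trend range = |slope|*(n-1)
    slope = (x * t).sum(axis=2) / (t * t).sum()
    trend_range = np.abs(slope) * (n - 1)

    bad = (peak > amp_threshold).any(axis=1) | (
        trend_range > drift_threshold
    ).any(axis=1)
    keep = ~bad
    return EpochSet(
        epochs=x[keep],
        fs=epochs.fs,
        epoch_length=epochs.epoch_length,
        site_names=epochs.site_names,
        kept_epoch_indices=epochs.kept_epoch_indices[keep],
    )


def check_inclusion(
    epochs: EpochSet,
    min_epochs: int = MIN_USABLE_EPOCHS,
    n_sites_required: int = 8,
) -> InclusionDecision:
    """Apply the usable-data inclusion rule.

    Pass iff at least ``min_epochs`` surviving epochs (sixty 2-s epochs ==
    >120 s of usable data) and all sites carry signal. A site that is
    identically zero across every epoch counts as not recorded.
    """
    if epochs.n_sites < n_sites_required:
        return InclusionDecision(False, "missing-channel", epochs.n_epochs)
    if epochs.n_epochs > 0:
        dead = np.all(epochs.epochs == 0.0, axis=(0, 2))
        if dead.any():
            return InclusionDecision(False, "missing-channel", epochs.n_epochs)
    if epochs.n_epochs < min_epochs:
        return InclusionDecision(False, "insufficient-data", epochs.n_epochs)
    return InclusionDecision(True, None, epochs.n_epochs)


def preprocess_session(
    session: RawSession,
    montage: BipolarMontage | None = None,
    epoch_length: float = DEFAULT_EPOCH_LENGTH_S,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD_UV,
    min_epochs: int = MIN_USABLE_EPOCHS,
) -> tuple[EpochSet, InclusionDecision]:
    """Full raw-to-epochs chain: bipolar, segment, screen, inclusion check."""
    montage = montage or BipolarMontage()
    recording = to_bipolar(session, montage)
    epochs = segment_epochs(recording, epoch_length)
    epochs = reject_artifacts(epochs, amp_threshold, drift_threshold)
    decision = check_inclusion(epochs, min_epochs=min_epochs,
                               n_sites_required=montage.n_sites)
    return epochs, decision
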