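"""Welch cross-spectral estimation and band-averaged coherence features.

Spectra are estimated with the Welch method: Hamming-windowed, mean-removed
segments with 50% overlap taken *within* each 2-s epoch, with periodograms
and cross-periodograms averaged over every segment of every surviving
epoch. Averaging across epochs is what makes the magnitude-squared
coherence

    C_xy(f) = |G_xy(f)|**2 / (G_xx(f) * G_yy(f))

well defined (a single segment gives identically 1). Band values are the
unweighted mean of C_xy(f) over the frequency bins whose center falls in
the band.

The default segmentation is 1-s segments with 50% overlap inside each 2-s
epoch (three segments per epoch), giving 1 Hz resolution — enough to cover
the 1 Hz lower edge of the delta band.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import get_window

from .preprocess import EpochSet


class SpectralError(ValueError):
    """Invalid spectral-estimation input."""


class TooFewSegmentsError(SpectralError):
    """Fewer than two Welch segments: coherence is degenerate."""


@dataclass(frozen=True)
class BandDefinition:
    """A canonical EEG frequency band.

    Membership is half-open ``[low, high)`` so the printed shared edges
    (4, 8, 13 Hz) never land in two bands; the top band may close its
    upper edge (beta = [13, 30]).
    """

    name: str
    low: float
    high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise SpectralError(f"bad band edges for {self.name!r}")

    def contains(self, f: np.ndarray | float) -> np.ndarray | bool:
        f = np.asarray(f, dtype=float)
        inside = (f >= self.low) & (f < self.high)
        if self.closed_high:
            inside |= f == self.high
        return inside


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0, closed_high=True)

STANDARD_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA)
BAND_BY_NAME = {b.name: b for b in STANDARD_BANDS}

DEFAULT_SEGMENT_LENGTH_S = 1.0
DEFAULT_OVERLAP_FRACTION = 0.5


@dataclass
class SpectralEstimate:
    """Averaged auto- and cross-spectral densities for a set of sites.

    ``csd[i, j, :]`` holds G_{x_i, x_j}(f) in µV²/Hz (one-sided density
    normalization: integrating the auto-spectrum over frequency recovers
    the signal variance up to windowing loss). Hermitian in (i, j).
    """

    freqs: np.ndarray
    csd: np.ndarray  # site x site x freq, complex
    n_segments: int
    site_names: tuple[str, ...]

    @property
    def auto(self) -> np.ndarray:
        """Real auto-spectral densities, shape (site, freq)."""
        return np.real(np.einsum("iif->if", self.csd))

    def _index(self, site) -> int:
        if isinstance(site, str):
            try:
                return self.site_names.index(site)
            except ValueError:
                raise SpectralError(f"unknown site {site!r}") from None
        return int(site)

    def coherence(self, site_x, site_y) -> np.ndarray:
        """Magnitude-squared coherence C_xy(f) on the frequency grid.

        Bins where either auto-spectrum vanishes are undefined and
        returned as NaN (they are excluded from band averages).
        """
        if self.n_segments < 2:
            raise TooFewSegmentsError(
                "coherence needs >= 2 averaged segments; a single segment "
                "gives identically 1"
            )
        i, j = self._index(site_x), self._index(site_y)
        gxx = np.real(self.csd[i, i])
        gyy = np.real(self.csd[j, j])
        gxy = self.csd[i, j]
        denom = gxx * gyy
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.abs(gxy) ** 2 / denom
        c = np.where(denom > 0, c, np.nan)
        # numerical safety: the estimator is bounded by construction
        return np.clip(c, 0.0, 1.0)


@dataclass
class CoherenceFeatures:
    """Band-averaged coherences for all pairings of the montage sites.

    For the 8-site study montage this is the canonical 28-vector; the pair
    order is lexicographic in montage site order and recorded in
    ``pair_names`` so classifier weights stay interpretable.
    """

    band: str
    values: np.ndarray
    pair_names: tuple[str, ...]
    metadata: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.pair_names):
            raise SpectralError("values/pair_names length mismatch")


def site_pairs(site_names: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """All unordered site pairings, lexicographic in montage order."""
    return tuple(combinations(site_names, 2))


def pair_labels(site_names: Sequence[str]) -> tuple[str, ...]:
    return tuple(f"{a}|{b}" for a, b in site_pairs(site_names))


def welch_spectra(
    epochs: EpochSet,
    segment_length: float = DEFAULT_SEGMENT_LENGTH_S,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> SpectralEstimate:
    """Welch auto/cross spectra averaged over all segments of all epochs.

    Each epoch is cut into Hamming-windowed, mean-removed segments of
    ``segment_length`` seconds with the given overlap; the full site x site
    cross-spectral matrix is averaged over every segment. Matches
    ``scipy.signal.csd`` (density scaling, constant detrend) bin for bin,
    computed here with one FFT per site and segment so all 36 auto/cross
    combinations of the 8 sites come out of a single pass.
    """
    fs = epochs.fs
    nperseg = int(round(segment_length * fs))
    n_epoch_samples = epochs.epochs.shape[2] if epochs.n_epochs else 0
    if segment_length <= 0:
        raise SpectralError("segment_length must be positive")
    if not 0 <= overlap_fraction < 1:
        raise SpectralError("overlap_fraction must be in [0, 1)")
    if epochs.n_epochs == 0:
        raise TooFewSegmentsError("no epochs to estimate spectra from")
    if nperseg > n_epoch_samples:
        raise SpectralError(
            "segment_length exceeds epoch length "
            f"({segment_length} s > {n_epoch_samples / fs} s)"
        )

    noverlap = int(round(nperseg * overlap_fraction))
    step = nperseg - noverlap
    starts = np.arange(0, n_epoch_samples - nperseg + 1, step)
    n_segments = epochs.n_epochs * len(starts)
    if n_segments < 2:
        raise TooFewSegmentsError(
            f"only {n_segments} Welch segment(s); coherence is undefined"
        )

    win = get_window("hamming", nperseg, fftbins=True)
    # segments: epoch x site x segment x sample
    segs = np.stack(
        [epochs.epochs[:, :, s : s + nperseg] for s in starts], axis=2
    )
    segs = segs - segs.mean(axis=3, keepdims=True)
    Z = np.fft.rfft(win * segs, axis=3)  # epoch x site x segment x freq

    # collapse epoch and segment axes: all segments are weighted equally
    n_sites = epochs.n_sites
    Zf = Z.transpose(1, 0, 2, 3).reshape(n_sites, -1, Z.shape[3])
    # scipy's csd convention: G_xy = E[conj(X) * Y]
    csd = np.einsum("xsf,ysf->xyf", np.conj(Zf), Zf) / Zf.shape[1]

    # one-sided density normalization (scipy.signal convention)
    scale = 1.0 / (fs * (win * win).sum())
    csd *= scale * 2.0
    csd[..., 0] /= 2.0
    if nperseg % 2 == 0:
        csd[..., -1] /= 2.0

    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return SpectralEstimate(
        freqs=freqs,
        csd=csd,
        n_segments=int(n_segments),
        site_names=tuple(epochs.site_names),
    )


def coherence(est: SpectralEstimate, site_x, site_y) -> np.ndarray:
    """Per-frequency magnitude-squared coherence between two sites."""
    return est.coherence(site_x, site_y)


def band_coherence(
    c_of_f: np.ndarray, freqs: np.ndarray, band: BandDefinition
) -> float:
    """Unweighted mean of C(f) over the bins whose center lies in the band."""
    inside = band.contains(freqs)
    if not np.any(inside):
        raise SpectralError(
            f"band {band.name!r} [{band.low}, {band.high}] overlaps no "
            "frequency bins"
        )
    vals = np.asarray(c_of_f, dtype=float)[inside]
    if np.all(np.isnan(vals)):
        raise SpectralError(f"all bins undefined in band {band.name!r}")
    return float(np.nanmean(vals))


def extract_features(
    epochs: EpochSet,
    bands: Iterable[BandDefinition] = STANDARD_BANDS,
    segment_length: float = DEFAULT_SEGMENT_LENGTH_S,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    metadata: dict | None = None,
) -> dict[str, CoherenceFeatures]:
    """Band-averaged coherence for every site pairing, one vector per band."""
    est = welch_spectra(epochs, segment_length, overlap_fraction)
    pairs = site_pairs(est.site_names)
    labels = pair_labels(est.site_names)
    out: dict[str, CoherenceFeatures] = {}
    coh = {
        (a, b): est.coherence(a, b) for a, b in pairs
    }
    for band in bands:
        vals = np.array(
            [band_coherence(coh[p], est.freqs, band) for p in pairs]
        )
        out[band.name] = CoherenceFeatures(
            band=band.name, values=vals, pair_names=labels,
            metadata=dict(metadata or {}),
        )
    return out


class CoherenceFeaturizer:
    """Transformer mapping epoch sets to per-band coherence feature rows.

    scikit-learn style: ``fit`` is stateless validation, ``transform``
    takes a list of :class:`EpochSet` and returns an
    ``(n_sessions, n_pairs * n_bands)`` array; ``feature_names_`` records
    the ``pair|band`` column order.
    """

    def __init__(
        self,
        bands: Sequence[BandDefinition] = STANDARD_BANDS,
        segment_length: float = DEFAULT_SEGMENT_LENGTH_S,
        overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    ) -> None:
        self.bands = tuple(bands)
        self.segment_length = segment_length
        self.overlap_fraction = overlap_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "bands": self.bands,
            "segment_length": self.segment_length,
            "overlap_fraction": self.overlap_fraction,
        }

    def set_params(self, **params) -> "CoherenceFeaturizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[EpochSet], y=None) -> "CoherenceFeaturizer":
        if len(X) == 0:
            raise SpectralError("no epoch sets")
        return self

    def transform(self, X: Sequence[EpochSet]) -> np.ndarray:
        rows = []
        names: list[str] | None = None
        for es in X:
            feats = extract_features(
                es, self.bands, self.segment_length, self.overlap_fraction
            )
            row = np.concatenate([feats[b.name].values for b in self.bands])
            if names is None:
                names = [
                    f"{p}|{b.name}"
                    for b in self.bands
                    for p in feats[b.name].pair_names
                ]
            rows.append(row)
        self.feature_names_ = tuple(names or ())
        return np.vstack(rows)

    def fit_transform(self, X: Sequence[EpochSet], y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
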