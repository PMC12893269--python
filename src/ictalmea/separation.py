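"""PCA/ICA source separation of multichannel MEA recordings.

The multielectrode signal is modelled as a linear instantaneous mixture of a
few network sources over correlated electrodes plus per-channel noise.  After
light preprocessing (DC removal, optional high-pass/notch, anti-aliased
downsampling, robust bad-channel handling), PCA reduces the dimensionality and
fixed-point ICA with a log-cosh contrast unmixes the retained subspace — the
standard EEG-style pipeline.  Each independent component (IC) comes with a
per-electrode weight vector (the share of the raw signal attributed to the IC)
whose thresholded support defines the source's spatial extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal
from sklearn.decomposition import PCA, FastICA

from ictalmea.errors import ConfigError, DecompositionError
from ictalmea.mea_io import ElectrodeLayout, Recording


@dataclass
class PreprocessConfig:
    highpass_hz: float | None = 1.0
    notch_hz: float | None = None
    notch_q: float = 30.0
    target_fs_hz: float = 1000.0
    bad_channel_mad_factor: float = 8.0


@dataclass
class DecomposeConfig:
    variance_target: float = 0.95
    max_ics: int | None = None
    seed: int = 0
    max_iter: int = 1000
    tol: float = 1e-5


@dataclass
class SourceModel:
    """ICA decomposition: one weight vector and one trace per independent component.

    ``weights`` is (n_ics x n_electrodes) with each row max-|w|-normalized to 1;
    ``ic_traces`` is (n_ics x n_samples) in units such that
    reconstruction = ic_traces.T @ weights + channel_mean.
    """

    ic_traces: np.ndarray
    weights: np.ndarray
    fs_hz: float
    channel_mean: np.ndarray
    pca_variance_retained: float
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise DecompositionError("non-finite ICA weights")
        if not 0.0 < self.pca_variance_retained <= 1.0 + 1e-12:
            raise DecompositionError("pca_variance_retained outside (0, 1]")

    @property
    def n_ics(self) -> int:
        return self.weights.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Channels x samples reconstruction from (weights, traces)."""
        return (self.ic_traces.T @ self.weights).T + self.channel_mean[:, None]

    def weight_grid(self, ic: int, layout: ElectrodeLayout) -> np.ndarray:
        """8x8 heat-map grid of one IC's weights (NaN off-array / at reference)."""
        grid = np.full((8, 8), np.nan)
        for ch, (r, c) in enumerate(layout.recording_positions):
            grid[r, c] = self.weights[ic, ch]
        return grid

    def save(self, path: "str | Path") -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("ic_traces", data=self.ic_traces.astype(np.float32))
            f.create_dataset("channel_mean", data=self.channel_mean)
            f.attrs["fs_hz"] = self.fs_hz
            f.attrs["pca_variance_retained"] = self.pca_variance_retained
            f.attrs["preprocessing"] = repr(self.preprocessing)
        return path

    @classmethod
    def load(cls, path: "str | Path") -> "SourceModel":
        with h5py.File(path, "r") as f:
            return cls(
                ic_traces=f["ic_traces"][()].astype(float),
                weights=f["weights"][()],
                fs_hz=float(f.attrs["fs_hz"]),
                channel_mean=f["channel_mean"][()],
                pca_variance_retained=float(f.attrs["pca_variance_retained"]),
                preprocessing={"raw": str(f.attrs.get("preprocessing", ""))},
            )


def export_weight_grids(model: SourceModel, layout: ElectrodeLayout, out_dir: "str | Path") -> list[Path]:
    """Write one 8x8 CSV heat-map grid per IC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ic in range(model.n_ics):
        p = out_dir / f"ic{ic:02d}_weights.csv"
        np.savetxt(p, model.weight_grid(ic, layout), delimiter=",", fmt="%.6g")
        paths.append(p)
    return paths


def preprocess(rec: Recording, config: PreprocessConfig | None = None) -> Recording:
    """DC removal, optional high-pass and notch, anti-aliased downsampling.

    Channels whose robust (MAD-based) standard deviation is an outlier by more
    than ``bad_channel_mad_factor`` MADs are zeroed and listed in the returned
    recording's ``preprocessing`` record, preserving the channel indexing.
    """
    cfg = config or PreprocessConfig()
    if cfg.target_fs_hz > rec.fs_hz:
        raise ConfigError(f"target_fs_hz {cfg.target_fs_hz} exceeds recording rate {rec.fs_hz}")
    x = rec.data.astype(np.float64)
    x -= x.mean(axis=1, keepdims=True)

    # robust variance criterion on a log scale
    ch_sd = 1.4826 * np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    nonzero = ch_sd > 0
    bad = np.zeros(x.shape[0], dtype=bool)
    if nonzero.sum() >= 3:
        log_sd = np.log(ch_sd[nonzero])
        med = np.median(log_sd)
        mad = 1.4826 * np.median(np.abs(log_sd - med))
        if mad > 0:
            bad[nonzero] = np.abs(log_sd - med) > cfg.bad_channel_mad_factor * mad
    x[bad] = 0.0

    if cfg.highpass_hz:
        sos = signal.butter(4, cfg.highpass_hz, btype="highpass", fs=rec.fs_hz, output="sos")
        for ch in range(x.shape[0]):
            x[ch] = signal.sosfiltfilt(sos, x[ch])
    if cfg.notch_hz:
        b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs_hz)
        for ch in range(x.shape[0]):
            x[ch] = signal.filtfilt(b, a, x[ch])

    fs_out = rec.fs_hz
    if cfg.target_fs_hz < rec.fs_hz:
        frac = Fraction(cfg.target_fs_hz / rec.fs_hz).limit_denominator(10_000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
        fs_out = rec.fs_hz * frac.numerator / frac.denominator

    ratio = rec.fs_hz / fs_out
    out = Recording(
        data=x.astype(np.float32),
        fs_hz=fs_out,
        layout=rec.layout,
        condition=dict(rec.condition),
        epochs=list(rec.epochs),
        preprocessing={
            "highpass_hz": cfg.highpass_hz,
            "notch_hz": cfg.notch_hz,
            "downsample_ratio": ratio,
            "bad_channels": np.flatnonzero(bad).tolist(),
        },
    )
    return out


def decompose(rec: Recording, config: DecomposeConfig | None = None) -> SourceModel:
    """PCA (smallest subspace reaching the variance target) followed by FastICA.

    One IC per retained PC; PCs with numerically equal eigenvalues are kept
    together.  Each IC is oriented so its largest-amplitude deflection is
    negative (LFP convention) and its weight vector is scaled to max |w| = 1,
    with the trace rescaled so the reconstruction is unchanged.  When
    ``max_ics`` caps the subspace below the variance target, the achieved
    fraction is recorded in ``pca_variance_retained``.
    """
    cfg = config or DecomposeConfig()
    if rec.data.shape[0] < 2:
        raise DecompositionError("need >= 2 channels")
    X = rec.data.T.astype(np.float64)
    mean = X.mean(axis=0)
    if not np.any(X - mean):
        raise DecompositionError("rank-deficient input: recording is constant")

    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, cfg.variance_target - 1e-12) + 1)
    k = min(k, evr.size)
    # equal-eigenvalue tie-break: keep both
    while k < evr.size and np.isclose(pca.explained_variance_[k - 1], pca.explained_variance_[k], rtol=1e-9):
        k += 1
    if cfg.max_ics is not None:
        k = min(k, cfg.max_ics)
    k = max(k, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence warnings are recorded below
        ica = FastICA(
            n_components=k,
            whiten="unit-variance",
            fun="logcosh",
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            random_state=cfg.seed,
        )
        S = ica.fit_transform(X)  # samples x k
    A = ica.mixing_  # channels x k

    traces = np.empty((k, S.shape[0]))
    weights = np.empty((k, A.shape[0]))
    for i in range(k):
        s, a = S[:, i], A[:, i].copy()
        peak = s[np.argmax(np.abs(s))]
        if peak > 0:  # orient largest deflection negative
            s, a = -s, -a
        scale = np.max(np.abs(a))
        if scale == 0:
            scale = 1.0
        weights[i] = a / scale
        traces[i] = s * scale

    return SourceModel(
        ic_traces=traces,
        weights=weights,
        fs_hz=rec.fs_hz,
        channel_mean=mean,
        pca_variance_retained=float(cum[k - 1]),
        preprocessing=dict(rec.preprocessing, n_iter=int(ica.n_iter_), ica_config=asdict(cfg)),
    )


def spatial_map(model: SourceModel, ic: int, theta: float = 0.2) -> np.ndarray:
    """Electrode indices with |weight| >= theta * max|weight| for one IC.

    The count of this set is the "number of electrodes recording" the source's
    events.  Sign flips of the IC leave the set unchanged.
    """
    if not 0.0 < theta < 1.0:
        raise ConfigError("theta must be in (0, 1)")
    if not 0 <= ic < model.n_ics:
        raise IndexError(f"ic {ic} out of range [0, {model.n_ics})")
    w = np.abs(model.weights[ic])
    return np.flatnonzero(w >= theta * w.max())
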