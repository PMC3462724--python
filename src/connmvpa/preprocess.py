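"""Time-series cleaning before connectivity estimation.

Three stages, each operating column-wise on a T x R matrix:

* linear detrend — subtract the least-squares line per region;
* band-pass — ideal rectangular filter in the discrete Fourier domain,
  keeping strictly 0.01 Hz < f < 0.08 Hz by default (the convention of
  the REST-style resting-state toolchain: boundary bins and DC removed);
* nuisance regression — OLS residualization against confound columns
  (motion, global/white-matter/CSF signals or their simulated analogues).

All three are linear projections, hence idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_STAGES = ("detrend", "bandpass", "regress")


@dataclass
class ConfoundSet:
    """Per-subject nuisance regressor matrix (T x C) with column names."""

    subject_id: str
    matrix: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not self.names:
            self.names = [f"confound_{i}" for i in range(self.matrix.shape[1])]
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("confound names do not match matrix columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"confounds for {self.subject_id} contain non-finite values")


@dataclass(frozen=True)
class PreprocessConfig:
    """Which cleaning stages run, in which order, with which band."""

    steps: tuple[str, ...] = ("detrend", "bandpass", "regress")
    f_low: float = 0.01
    f_high: float = 0.08

    def __post_init__(self) -> None:
        for s in self.steps:
            if s not in _STAGES:
                raise ValueError(f"unknown preprocessing step {s!r}; choose from {_STAGES}")


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the per-column least-squares line (intercept + slope * t)."""
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    if t < 3:
        raise ValueError(f"need at least 3 timepoints to detrend, got {t}")
    x = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    beta, *_ = np.linalg.lstsq(x, series, rcond=None)
    return series - x @ beta


def bandpass(series: np.ndarray, tr_seconds: float,
             f_low: float = 0.01, f_high: float = 0.08) -> np.ndarray:
    """Ideal band-pass: zero every DFT bin outside the open band (f_low, f_high).

    DC and the boundary bins are removed; the result is real-valued.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0.0 <= f_low < f_high:
        raise ValueError(f"need 0 <= f_low < f_high, got ({f_low}, {f_high})")
    if f_high > nyquist + 1e-12:
        raise ValueError(f"f_high={f_high} Hz exceeds Nyquist {nyquist} Hz at TR={tr_seconds}s")
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs > f_low) & (freqs < f_high)
    spectrum = np.fft.rfft(series, axis=0)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=0)


def _drop_dependent_columns(design: np.ndarray, names: list[str]) -> np.ndarray:
    """Remove linearly dependent design columns (pivoted-QR style sweep)."""
    kept: list[int] = []
    for c in range(design.shape[1]):
        cand = design[:, kept + [c]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(c)
        else:
            logger.warning("dropping linearly dependent confound column %r", names[c])
    return design[:, kept]


def regress_confounds(series: np.ndarray, confounds: ConfoundSet | np.ndarray | None) -> np.ndarray:
    """OLS residuals of each region on the confounds (intercept added).

    With no confounds this reduces to mean removal. Rank-deficient
    confound matrices are handled by dropping dependent columns with a
    logged warning. Residuals are orthogonal to every kept column.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    if confounds is None:
        mat = np.empty((t, 0))
        names: list[str] = []
    elif isinstance(confounds, ConfoundSet):
        mat, names = confounds.matrix, confounds.names
    else:
        mat = np.atleast_2d(np.asarray(confounds, dtype=float))
        names = [f"confound_{i}" for i in range(mat.shape[1])]
    if mat.shape[0] not in (t,) and mat.size:
        raise ValueError(f"confounds have {mat.shape[0]} rows, series has {t}")
    design = np.column_stack([np.ones(t), mat]) if mat.size else np.ones((t, 1))
    all_names = ["intercept"] + list(names)
    design = _drop_dependent_columns(design, all_names)
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def preprocess_series(series: np.ndarray, tr_seconds: float,
                      config: PreprocessConfig | None = None,
                      confounds: ConfoundSet | np.ndarray | None = None) -> np.ndarray:
    """Apply the configured stages in order (default detrend -> bandpass -> regress)."""
    config = config or PreprocessConfig()
    out = np.asarray(series, dtype=float)
    for step in config.steps:
        if step == "detrend":
            out = detrend_linear(out)
        elif step == "bandpass":
            out = bandpass(out, tr_seconds, config.f_low, config.f_high)
        elif step == "regress":
            out = regress_confounds(out, confounds)
    return out
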