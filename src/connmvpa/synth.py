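"""Synthetic two-group ROI time-series cohorts with planted edge effects.

No scan data ships with this package; instead this module generates
cohorts whose structure mirrors a typical resting-state case/control
study — two groups of subjects, 90 cortical/subcortical regions, a few
minutes of signal at TR = 2 s — with a chosen set of region-pair
correlations shifted in the patient group. Every downstream stage
(preprocessing, connectivity, ranking, classification, reconstruction)
is exercised against these cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATIENT = -1
CONTROL = +1

_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated two-group cohort.

    ``planted_edges`` is a list of ``(i, j, delta_r)`` triples with
    ``i < j``: the patient-group correlation of region pair (i, j) is
    shifted by ``delta_r`` relative to the shared base covariance.
    ``base_density`` in [0, 1] scales the strength of background
    (non-planted) correlations; 0 gives independent regions.
    ``drift_amplitude`` bounds the per-region linear drift slope and
    ``noise_sd`` is the standard deviation of added white noise — both
    exist so the detrend and band-pass stages have work to do.
    """

    n_patients: int = 22
    n_controls: int = 22
    n_regions: int = 90
    n_timepoints: int = 175
    tr_seconds: float = 2.0
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    base_density: float = 0.3
    drift_amplitude: float = 0.5
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j), float(d)) for i, j, d in self.planted_edges))
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups need at least one subject")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError("base_density must lie in [0, 1]")
        if self.drift_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("drift_amplitude and noise_sd must be nonnegative")
        seen = set()
        for i, j, _ in self.planted_edges:
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"planted edge ({i}, {j}) is not 0 <= i < j < n_regions")
            if (i, j) in seen:
                raise ValueError(f"planted edge ({i}, {j}) listed twice")
            seen.add((i, j))


@dataclass
class Subject:
    subject_id: str
    group: int  # PATIENT (-1) or CONTROL (+1)
    series: np.ndarray  # T x R

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError("group must be -1 (patient) or +1 (control)")


@dataclass
class Cohort:
    """A set of subjects sharing region labels and sampling rate."""

    region_labels: list[str]
    tr_seconds: float
    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        r = len(self.region_labels)
        shapes = {s.series.shape for s in self.subjects}
        if len(shapes) > 1:
            raise ValueError(f"subjects disagree on series shape: {sorted(shapes)}")
        for s in self.subjects:
            if s.series.shape[1] != r:
                raise ValueError(
                    f"subject {s.subject_id}: {s.series.shape[1]} regions, "
                    f"{r} region labels")
            if not np.all(np.isfinite(s.series)):
                raise ValueError(f"subject {s.subject_id}: non-finite values")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects], dtype=int)


def default_region_labels(n_regions: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(n_regions)]


def _unit_diagonal(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    out = cov / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def make_base_covariance(n_regions: int, base_density: float, seed: int,
                         n_factors: int = 5) -> np.ndarray:
    """Random factor-structured correlation matrix with unit diagonal.

    A few latent components with Gaussian loadings produce block-like
    correlation resembling resting-state networks. The returned matrix is
    ``base_density * C + (1 - base_density) * I`` where C is the factor
    correlation matrix, hence symmetric positive definite for density < 1
    and exactly the identity at density 0.
    """
    if n_regions < 3:
        raise ValueError("n_regions must be >= 3")
    if not 0.0 <= base_density <= 1.0:
        raise ValueError("base_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    loadings = rng.standard_normal((n_regions, max(1, n_factors)))
    raw = loadings @ loadings.T + 0.5 * np.eye(n_regions)
    factor_corr = _unit_diagonal(raw)
    cov = base_density * factor_corr + (1.0 - base_density) * np.eye(n_regions)
    cov = _repair_spd(cov)
    return cov


def _repair_spd(cov: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Symmetrize, floor eigenvalues at ``floor``, rescale to unit diagonal."""
    sym = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < floor:
        sym = (vecs * np.maximum(vals, floor)) @ vecs.T
        sym = 0.5 * (sym + sym.T)
    out = _unit_diagonal(sym)
    if np.linalg.eigvalsh(out).min() <= 0:
        raise np.linalg.LinAlgError("SPD repair failed to produce a positive-definite matrix")
    return out


def plant_effects(base_cov: np.ndarray,
                  planted_edges: tuple[tuple[int, int, float], ...]) -> np.ndarray:
    """Shift selected correlations of ``base_cov``, then repair to SPD.

    Each planted ``(i, j, delta_r)`` moves that pair's correlation by
    ``delta_r``; a shift that would push |r| above 0.99 is rejected. The
    shifted matrix is symmetrized, eigenvalue-floored at 1e-6 and rescaled
    to unit diagonal, so non-planted entries move only by the (small)
    repair perturbation.
    """
    if not planted_edges:
        return base_cov.copy()
    cov = base_cov.copy()
    for i, j, delta in planted_edges:
        target = cov[i, j] + delta
        if abs(target) > 0.99:
            raise ValueError(
                f"planted edge ({i}, {j}): correlation {cov[i, j]:.3f} + "
                f"{delta:+.3f} leaves [-0.99, 0.99]")
        cov[i, j] = cov[j, i] = target
    return _repair_spd(cov)


def _sample_group(rng: np.random.Generator, chol: np.ndarray, n_subjects: int,
                  cfg: SimulationConfig, prefix: str, group: int,
                  start: int = 1) -> list[Subject]:
    t, r = cfg.n_timepoints, cfg.n_regions
    tgrid = np.linspace(-0.5, 0.5, t)[:, None]
    out = []
    for s in range(n_subjects):
        z = rng.standard_normal((t, r))
        series = z @ chol.T
        if cfg.drift_amplitude > 0:
            slopes = rng.uniform(-cfg.drift_amplitude, cfg.drift_amplitude, size=r)
            series = series + tgrid * slopes
        if cfg.noise_sd > 0:
            series = series + cfg.noise_sd * rng.standard_normal((t, r))
        out.append(Subject(f"{prefix}{start + s:03d}", group, series))
    return out


def _simulate(cfg: SimulationConfig, patient_cov: np.ndarray,
              control_cov: np.ndarray) -> Cohort:
    rng = np.random.default_rng(cfg.seed)
    chol_p = np.linalg.cholesky(patient_cov)
    chol_c = np.linalg.cholesky(control_cov)
    subjects = _sample_group(rng, chol_p, cfg.n_patients, cfg, "pat", PATIENT)
    subjects += _sample_group(rng, chol_c, cfg.n_controls, cfg, "con", CONTROL)
    return Cohort(default_region_labels(cfg.n_regions), cfg.tr_seconds, subjects)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a two-group cohort; patients use the planted covariance.

    Controls are sampled from a zero-mean multivariate normal with the
    base covariance, patients from the base covariance with the planted
    edge shifts applied. Linear drift and white noise are then added.
    Fully reproducible from ``config.seed``.
    """
    base = make_base_covariance(config.n_regions, config.base_density, config.seed)
    patient = plant_effects(base, config.planted_edges)
    return _simulate(config, patient, base)


def simulate_null_cohort(config: SimulationConfig) -> Cohort:
    """As :func:`simulate_cohort` but both groups share the base covariance."""
    base = make_base_covariance(config.n_regions, config.base_density, config.seed)
    return _simulate(config, base, base)
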