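"""Modality calling for per-species CpG_o/e distributions.

A species with gene body methylation confined to a subset of genes shows a
mixture of a low-CpG_o/e (methylated) and a high-CpG_o/e (unmethylated) gene
class.  Two procedures decide how many components the per-gene distribution
supports, and both are reported side by side because they routinely disagree:

* a kernel-density mode count with explicit stringency criteria (minimum
  relative peak height, minimum basin probability mass, minimum separation
  between retained peaks) — the stringency is a parameter, not a constant,
  because default criteria tuned on bilaterian data are too strict for many
  other taxa;
* univariate Gaussian mixture models with unequal component variances fitted
  by EM, with the component count selected by BIC (ties broken toward the
  smaller k).

Values above a ceiling (default 2.0; short-gene tail artifacts) are dropped
before either estimate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_CEILING = 2.0
MIN_VALUES = 50
SD_FLOOR = 1e-3

LABEL_UNIMODAL = "unimodal"
LABEL_BIMODAL = "bimodal"
LABEL_MULTIMODAL = "multimodal"
LABEL_NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density evaluated on a fixed grid over [0, ceiling]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


class Mode(NamedTuple):
    location: float
    height: float
    mass: float


@dataclass(frozen=True)
class GmmFit:
    """One fitted univariate Gaussian mixture (best of several EM restarts)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_obs: int
    loglik_trace: np.ndarray


@dataclass
class ModalityCall:
    """Per-species modality verdicts from KDE and GMM, reported side by side."""

    species: str
    kde_modes: list[Mode] = field(default_factory=list)
    kde_label: str = LABEL_NOT_ASSESSED
    gmm_best_k: int | None = None
    gmm_bic_table: dict[int, float] = field(default_factory=dict)
    gmm_fits: dict[int, GmmFit] = field(default_factory=dict)
    final_label_kde: str = LABEL_NOT_ASSESSED
    final_label_gmm: str = LABEL_NOT_ASSESSED
    n_used: int = 0


@dataclass(frozen=True)
class ModalityConfig:
    ceiling: float = DEFAULT_CEILING
    grid_n: int = 512
    bandwidth: float | str = "silverman"
    min_height_frac: float = 0.05
    min_mass: float = 0.05
    min_separation: float = 0.10
    k_max: int = 5
    restarts: int = 20
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500


def species_seed(master_seed: int, species: str) -> int:
    """Deterministic per-species seed independent of panel composition."""
    return (master_seed * 1_000_003 + zlib.crc32(species.encode())) % (2**31)


def _clean(values: Sequence[float], ceiling: float) -> np.ndarray:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    return vals[vals <= ceiling]


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(values, ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread < 1e-12:  # constant sample up to float rounding
        raise ValueError("degenerate (constant) sample: bandwidth undefined")
    return 0.9 * spread * len(values) ** (-1 / 5)


def kde_estimate(
    values: Sequence[float],
    bandwidth: float | str = "silverman",
    grid_n: int = 512,
    ceiling: float = DEFAULT_CEILING,
    min_n: int = MIN_VALUES,
) -> DensityCurve:
    """Gaussian-kernel density of CpG_o/e values on a grid over [0, ceiling].

    Values above the ceiling are dropped first.  Raises when fewer than
    ``min_n`` values remain or when the sample is constant.
    """
    vals = _clean(values, ceiling)
    if len(vals) < min_n:
        raise ValueError(
            f"only {len(vals)} values <= {ceiling}; need {min_n} — skip modality"
        )
    h = silverman_bandwidth(vals) if bandwidth == "silverman" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, ceiling, grid_n)
    z = (grid[:, None] - vals[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (len(vals) * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=h)


def _basin_masses(curve: DensityCurve, mode_idx: list[int]) -> list[float]:
    """Probability mass of each retained mode's basin (split at inter-mode minima)."""
    total = curve.integral()
    order = np.argsort([curve.grid[i] for i in mode_idx])
    sorted_idx = [mode_idx[j] for j in order]
    bounds = [0]
    for a, b in zip(sorted_idx[:-1], sorted_idx[1:]):
        bounds.append(a + int(np.argmin(curve.density[a : b + 1])))
    bounds.append(len(curve.grid) - 1)
    masses_sorted = [
        float(np.trapezoid(curve.density[lo : hi + 1], curve.grid[lo : hi + 1])) / total
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    # back to the caller's order
    out = [0.0] * len(mode_idx)
    for pos, j in enumerate(order):
        out[j] = masses_sorted[pos]
    return out


def count_modes(
    curve: DensityCurve,
    min_height_frac: float = 0.05,
    min_mass: float = 0.05,
    min_separation: float = 0.10,
) -> list[Mode]:
    """Retain local density maxima that pass height, mass and separation criteria.

    A local maximum is kept iff its height is >= min_height_frac of the global
    maximum, it lies >= min_separation (in CpG_o/e units) from any taller
    retained maximum, and its basin holds >= min_mass of the probability mass.
    Dropping a mode merges basins, so the mass criterion is re-applied until
    stable.  Modes are returned sorted by location.
    """
    d = curve.density
    n = len(d)
    cand = [i for i in range(1, n - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    if d[0] > d[1]:
        cand.insert(0, 0)
    if d[-1] > d[-2]:
        cand.append(n - 1)
    if not cand:
        return []
    peak = float(d.max())
    cand = [i for i in cand if d[i] >= min_height_frac * peak]
    # separation filter: greedy from tallest
    retained: list[int] = []
    for i in sorted(cand, key=lambda i: -d[i]):
        if all(abs(curve.grid[i] - curve.grid[j]) >= min_separation for j in retained):
            retained.append(i)
    # mass filter, iterated because removing a mode merges basins
    while True:
        masses = _basin_masses(curve, retained)
        keep = [i for i, m in zip(retained, masses) if m >= min_mass]
        if len(keep) == len(retained) or not keep:
            retained = keep
            break
        retained = keep
    masses = _basin_masses(curve, retained) if retained else []
    modes = [
        Mode(float(curve.grid[i]), float(d[i]), m) for i, m in zip(retained, masses)
    ]
    return sorted(modes, key=lambda m: m.location)


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def _em_once(
    x: np.ndarray,
    means0: np.ndarray,
    sd0: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, np.ndarray]:
    n, k = len(x), len(means0)
    weights = np.full(k, 1 / k)
    means = means0.astype(float).copy()
    sds = np.full(k, max(sd0, SD_FLOOR))
    reseeded = np.zeros(k, dtype=bool)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        logp = np.stack([_log_gauss(x, means[j], sds[j]) for j in range(k)])
        logp += np.log(weights)[:, None]
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        loglik = float(lse.sum())
        resp = np.exp(logp - lse)
        trace.append(loglik)
        # relative convergence test: loglik scales with n, an absolute test would not
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(loglik)):
            converged = True
            break
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        sds = np.sqrt(np.maximum(var, 0.0))
        for j in range(k):
            if sds[j] < SD_FLOOR:
                if not reseeded[j]:
                    # singular component: re-seed once at a random data point
                    means[j] = float(rng.choice(x))
                    sds[j] = max(float(np.std(x)), SD_FLOOR)
                    reseeded[j] = True
                else:
                    sds[j] = SD_FLOOR
    return weights, means, sds, trace[-1], converged, np.array(trace)


def _kmeanspp_means(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    means = [float(rng.choice(x))]
    for _ in range(k - 1):
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        if d2.sum() <= 0:
            means.append(float(rng.choice(x)))
            continue
        means.append(float(rng.choice(x, p=d2 / d2.sum())))
    return np.array(means)


def fit_gmm_em(
    values: Sequence[float],
    k: int,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GmmFit:
    """Fit a k-component univariate Gaussian mixture (unequal variances) by EM.

    Means are seeded k-means++-style; the best of ``restarts`` runs by final
    log-likelihood is kept.  BIC = -2*loglik + (3k-1)*ln(n), counting k-1 free
    weights, k means and k standard deviations.
    """
    # sorted input makes the seeded initialisations order-independent
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 10 * k:
        raise ValueError(f"need n >= {10 * k} observations for k={k}, got {n}")
    rng = np.random.default_rng(seed)
    sd0 = float(np.std(x))
    best: tuple | None = None
    any_converged = False
    for _ in range(restarts):
        means0 = _kmeanspp_means(x, k, rng) if k > 1 else np.array([float(np.mean(x))])
        out = _em_once(x, means0, sd0, rng, tol, max_iter)
        any_converged = any_converged or out[4]
        if best is None or out[3] > best[3]:
            best = out
    weights, means, sds, loglik, _, trace = best
    if not any_converged:
        logger.warning("EM did not converge in any of %d restarts (k=%d)", restarts, k)
    order = np.argsort(means)
    bic = -2.0 * loglik + (3 * k - 1) * np.log(n)
    return GmmFit(
        k=k,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=loglik,
        bic=float(bic),
        converged=any_converged,
        n_obs=n,
        loglik_trace=trace,
    )


def select_k_bic(
    values: Sequence[float],
    k_max: int = 5,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[int, dict[int, float], dict[int, GmmFit]]:
    """Fit k = 1..k_max and pick the BIC-minimal k (ties toward smaller k)."""
    bic_table: dict[int, float] = {}
    fits: dict[int, GmmFit] = {}
    for k in range(1, k_max + 1):
        try:
            fit = fit_gmm_em(values, k, restarts=restarts, seed=seed, tol=tol, max_iter=max_iter)
        except ValueError as exc:
            logger.warning("GMM k=%d skipped: %s", k, exc)
            continue
        bic_table[k] = fit.bic
        fits[k] = fit
    if not bic_table:
        raise ValueError("no mixture size could be fitted")
    best_k = min(bic_table, key=lambda k: (bic_table[k], k))
    return best_k, bic_table, fits


def _label_from_count(n: int) -> str:
    if n <= 1:
        return LABEL_UNIMODAL
    if n == 2:
        return LABEL_BIMODAL
    return LABEL_MULTIMODAL


def classify_species(
    values: Sequence[float],
    species: str = "",
    config: ModalityConfig | None = None,
) -> ModalityCall:
    """Run both modality procedures on one species' CpG_o/e values.

    The KDE label counts retained density modes; the GMM label maps the
    BIC-selected component count the same way.  The two verdicts are never
    merged.  Species with too few usable values get ``not_assessed``.
    """
    cfg = config or ModalityConfig()
    call = ModalityCall(species=species)
    vals = _clean(values, cfg.ceiling)
    call.n_used = len(vals)
    if len(vals) < MIN_VALUES or np.std(vals) == 0:
        logger.warning("species %s: %d usable values — not assessed", species, len(vals))
        return call
    seed = species_seed(cfg.seed, species)
    curve = kde_estimate(vals, bandwidth=cfg.bandwidth, grid_n=cfg.grid_n, ceiling=cfg.ceiling)
    call.kde_modes = count_modes(
        curve,
        min_height_frac=cfg.min_height_frac,
        min_mass=cfg.min_mass,
        min_separation=cfg.min_separation,
    )
    call.kde_label = _label_from_count(len(call.kde_modes))
    call.final_label_kde = call.kde_label
    best_k, bic_table, fits = select_k_bic(
        vals, k_max=cfg.k_max, restarts=cfg.restarts, seed=seed,
        tol=cfg.tol, max_iter=cfg.max_iter,
    )
    call.gmm_best_k = best_k
    call.gmm_bic_table = bic_table
    call.gmm_fits = fits
    call.final_label_gmm = _label_from_count(best_k)
    return call
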