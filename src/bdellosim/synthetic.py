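"""Seeded synthetic-data generators for every pipeline stage.

Emulates the three kinds of measurement the analysis consumes, with the
statistical structure the summary stage assumes, so the whole package is
testable without any external data:

* **Event tables** — per-cell appearance times of replisome / segrosome /
  divisome markers. Within a cell, times share a latent "tempo" factor
  (a slow cell is slow throughout); marginal means and SDs target the
  measured values, with SDs back-derived from the printed 95% CI
  half-widths at n = 100. Cells violating the within-cell event ordering
  or positivity are rejected and resampled. Because rejection distorts
  the marginals, the generator first calibrates its pre-rejection means
  (deterministically, with an internal fixed seed) so that the
  *post-rejection* means match the targets; see docs/methods.md.
* **Size tables** — paired prey length / bdelloplast diameter draws from
  a linear model whose residual noise is calibrated in closed form to a
  target pooled correlation.
* **Kill curves** — Weibull decay evaluated on a 20-min plate-reader
  grid over 42 h plus i.i.d. Gaussian OD noise.

Every generator is a pure function of (config, seed): identical inputs
yield identical tables.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cellstats import EVENT_KEYS, ORDER_CHAINS
from .killcurve import KillCurve, WeibullFit, weibull4
from .params import PreyParams, load_prey_params

__all__ = [
    "SizeModel",
    "GeneratorConfig",
    "gen_event_table",
    "gen_size_table",
    "calibrate_noise",
    "gen_killcurve",
]

#: Internal seed for the deterministic mean calibration (independent of
#: the user-facing seed, so calibration is a fixed property of a config).
_CALIBRATION_SEED = 424242
_CALIBRATION_ITERATIONS = 10
_CALIBRATION_N = 25_000

_SIZE_DEFAULTS = {
    # prey cell length ~ N(mean, sd) μm, truncated > 0. Anchored only
    # qualitatively (P. mirabilis < 2 μm; sizes increase toward
    # S. flexneri); the pooled correlation target is the measured number.
    "P_mirabilis": (1.7, 0.2),
    "S_enterica": (2.6, 0.35),
    "S_flexneri": (3.6, 0.5),
}


class SizeModel(BaseModel):
    """Linear prey-length → bdelloplast-diameter model with noise target."""

    length_mean: dict[str, float] = Field(
        default_factory=lambda: {k: v[0] for k, v in _SIZE_DEFAULTS.items()})
    length_sd: dict[str, float] = Field(
        default_factory=lambda: {k: v[1] for k, v in _SIZE_DEFAULTS.items()})
    intercept: float = 0.4
    slope: float = 0.55
    target_pooled_r: float = Field(default=0.87, gt=0, lt=1)

    @model_validator(mode="after")
    def _positive(self) -> "SizeModel":
        if any(v <= 0 for v in self.length_mean.values()):
            raise ValueError("length means must be positive")
        if any(v <= 0 for v in self.length_sd.values()):
            raise ValueError("length sds must be positive")
        return self


class GeneratorConfig(BaseModel):
    """Configuration shared by all generators."""

    species: list[str] = Field(
        default_factory=lambda: ["P_mirabilis", "S_enterica", "S_flexneri"])
    n_cells: int = Field(default=100, ge=1)
    seed: int = 0
    tempo_share: float = Field(default=0.81, ge=0, le=1)
    size_model: SizeModel = Field(default_factory=SizeModel)
    noise_sd_od: float = Field(default=0.01, ge=0)
    #: Abort threshold for the event-time rejection sampler. The built-in
    #: prey configs reject heavily by construction (tight printed gaps vs
    #: wide back-derived SDs), so the guard is set high; it still catches
    #: genuinely unsatisfiable configs.
    max_rejection_rate: float = Field(default=0.999, gt=0, lt=1)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def _constraint_mask(t: np.ndarray, keys: Sequence[str]) -> np.ndarray:
    """Rows of ``t`` satisfying positivity and the ordering chains."""
    ok = (t > 0).all(axis=1)
    index = {k: i for i, k in enumerate(keys)}
    for chain in ORDER_CHAINS:
        idx = [index[k] for k in chain if k in index]
        for a, b in zip(idx, idx[1:]):
            ok &= t[:, a] < t[:, b]
    return ok


def _sample_event_times(
    keys: Sequence[str],
    mu: np.ndarray,
    sigma: np.ndarray,
    tempo_share: float,
    n: int,
    rng: np.random.Generator,
    max_rejection_rate: float,
) -> np.ndarray:
    """Draw ``n`` accepted per-cell event-time rows by rejection sampling."""
    sw = math.sqrt(tempo_share)
    se = math.sqrt(1.0 - tempo_share)
    k = len(keys)
    chunks: list[np.ndarray] = []
    have = 0
    proposed = 0
    rate_est = 1.0
    while have < n:
        if proposed >= 50_000 and 1.0 - rate_est > max_rejection_rate:
            raise RuntimeError(
                f"event-time rejection rate {1 - rate_est:.4f} exceeds "
                f"max_rejection_rate={max_rejection_rate}; the timing means, "
                "SDs and ordering constraints are mutually inconsistent"
            )
        m = min(2_000_000,
                max(4096, int(1.2 * (n - have) / max(rate_est, 0.002))))
        z = rng.standard_normal((m, 1))
        eps = rng.standard_normal((m, k))
        t = mu + sigma * (sw * z + se * eps)
        ok = _constraint_mask(t, keys)
        chunks.append(t[ok])
        have += int(ok.sum())
        proposed += m
        rate_est = max(have, 1) / proposed
    return np.concatenate(chunks, axis=0)[:n]


_CALIB_CACHE: dict[tuple, np.ndarray] = {}


def _calibrated_means(
    keys: tuple[str, ...],
    target_mu: np.ndarray,
    sigma: np.ndarray,
    tempo_share: float,
    max_rejection_rate: float,
) -> np.ndarray:
    """Pre-rejection means whose post-rejection sample means hit the targets.

    Deterministic fixed-point iteration with common random numbers: each
    iteration redraws the *same* internal random stream, measures the
    post-rejection mean and shifts the input means by the residual. The
    result is cached per (keys, targets, tempo_share).
    """
    cache_key = (keys, tuple(target_mu), tuple(sigma), tempo_share)
    if cache_key in _CALIB_CACHE:
        return _CALIB_CACHE[cache_key]
    mu = target_mu.astype(float).copy()
    for _ in range(_CALIBRATION_ITERATIONS):
        rng = np.random.default_rng(_CALIBRATION_SEED)
        t = _sample_event_times(
            keys, mu, sigma, tempo_share, _CALIBRATION_N, rng,
            max_rejection_rate,
        )
        mu += target_mu - t.mean(axis=0)
    _CALIB_CACHE[cache_key] = mu
    return mu


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Positive normal draws; truncation by resampling, not clipping."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
        guard += 1
        if guard > 1000:
            raise RuntimeError("truncated-normal resampling did not converge")
    return out


def gen_event_table(cfg: GeneratorConfig, params: PreyParams) -> pd.DataFrame:
    """Generate a per-cell event table for one prey species.

    Per cell: a latent tempo factor z ~ N(0, 1); each event time
    ``t_e = μ_e* + σ_e·(√w·z + √(1−w)·ε_e)`` with w = ``cfg.tempo_share``,
    σ_e back-derived from the printed CI half-width, and μ_e* the
    internally calibrated pre-rejection mean. Cells violating event
    ordering or positivity are rejected and resampled. Progeny counts are
    drawn from the species pmf and progeny lengths from a truncated
    normal. Fully reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    data: dict[str, object] = {}

    timings = params.event_timings
    if timings:
        keys = tuple(k for k in EVENT_KEYS if k in timings)
        target_mu = np.array([timings[k].mean for k in keys], dtype=float)
        sigma = np.array([timings[k].sd for k in keys], dtype=float)
        mu = _calibrated_means(
            keys, target_mu, sigma, cfg.tempo_share, cfg.max_rejection_rate)
        t = _sample_event_times(
            keys, mu, sigma, cfg.tempo_share, n, rng, cfg.max_rejection_rate)
        for j, k in enumerate(keys):
            data[k] = t[:, j]

    support = np.array(sorted(params.progeny_pmf), dtype=int)
    probs = np.array([params.progeny_pmf[k] for k in support], dtype=float)
    counts = rng.choice(support, size=n, p=probs)
    data["progeny_count"] = counts

    if params.progeny_length is not None:
        pl = params.progeny_length
        flat = _truncated_normal(pl.mean, pl.sd, int(counts.sum()), rng)
        split = np.split(flat, np.cumsum(counts)[:-1])
        data["progeny_lengths"] = [list(map(float, s)) for s in split]

    table = pd.DataFrame(data)
    table.insert(0, "species", params.species)
    table.insert(0, "cell_id", [f"{params.species}_{i:04d}" for i in range(n)])
    return table


def gen_event_tables(cfg: GeneratorConfig) -> pd.DataFrame:
    """Event tables for every species in ``cfg.species``, concatenated.

    Each species consumes an independent child stream of ``cfg.seed``.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.species))
    frames = []
    for sp, ss in zip(cfg.species, seeds):
        sub = cfg.model_copy(update={"seed": int(ss.generate_state(1)[0] & 0x7FFFFFFF)})
        frames.append(gen_event_table(sub, load_prey_params(sp)))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# size tables
# ---------------------------------------------------------------------------

def calibrate_noise(slope: float, pooled_length_sd: float, target_r: float) -> float:
    """Residual SD giving a target correlation in a linear model.

    In ``diameter = a + slope·length + ε`` the correlation is
    ``r = slope·σx / √(slope²σx² + σ_ε²)``; inverting,
    ``σ_ε = |slope|·σx·√(1/r² − 1)``.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero (target correlation unreachable)")
    if pooled_length_sd <= 0:
        raise ValueError("pooled_length_sd must be positive")
    if not 0 < target_r < 1:
        raise ValueError(f"target_r must lie in (0, 1), got {target_r}")
    return abs(slope) * pooled_length_sd * math.sqrt(1.0 / target_r**2 - 1.0)


def pooled_length_sd(model: SizeModel, species: Sequence[str]) -> float:
    """Pooled SD of prey length across equally weighted species.

    Mixture variance: mean of within-species variances plus variance of
    the species means (truncation at 0 is negligible at the default
    means/SDs and ignored here).
    """
    means = np.array([model.length_mean[s] for s in species], dtype=float)
    sds = np.array([model.length_sd[s] for s in species], dtype=float)
    return float(math.sqrt(np.mean(sds**2) + np.var(means)))


def gen_size_table(
    cfg: GeneratorConfig, noise_sd: Optional[float] = None
) -> pd.DataFrame:
    """Generate paired (prey length, bdelloplast diameter) measurements.

    Lengths are truncated-normal per species; diameters follow the linear
    size model plus Gaussian residual noise whose SD defaults to the
    closed-form calibration against ``target_pooled_r``.
    """
    model = cfg.size_model
    species = [s for s in cfg.species if s in model.length_mean]
    if not species:
        raise ValueError("no configured species has a size model entry")
    if noise_sd is None:
        noise_sd = calibrate_noise(
            model.slope, pooled_length_sd(model, species), model.target_pooled_r)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for sp in species:
        length = _truncated_normal(
            model.length_mean[sp], model.length_sd[sp], cfg.n_cells, rng)
        diameter = model.intercept + model.slope * length
        if noise_sd > 0:
            diameter = diameter + rng.normal(0.0, noise_sd, cfg.n_cells)
        rows.append(pd.DataFrame({
            "species": sp, "prey_length": length, "bdelloplast_diameter": diameter,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# kill curves
# ---------------------------------------------------------------------------

def gen_killcurve(
    truth,
    grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> KillCurve:
    """Weibull decay sampled on a plate-reader grid with Gaussian OD noise.

    ``truth`` is a :class:`WeibullFit` or any object/tuple providing
    (b, c, d, e). The default grid is 20-min steps over 42 h
    (0 … 2520 min, 127 points).
    """
    if isinstance(truth, WeibullFit):
        b, c, d, e = truth.b, truth.c, truth.d, truth.e
    elif hasattr(truth, "b"):
        b, c, d, e = truth.b, truth.c, truth.d, truth.e
    else:
        b, c, d, e = truth
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, 2521.0, 20.0) if grid is None else np.asarray(grid, float)
    od = weibull4(t, b, c, d, e)
    if noise_sd > 0:
        od = od + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return KillCurve(times=t, od=od, meta={
        "source": "gen_killcurve", "noise_sd": noise_sd, "seed": seed,
        "truth": {"b": b, "c": c, "d": d, "e": e},
    })
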