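"""Mixture model linking aberrant-cell fraction to folded BAF and log2R.

A tumor sample is modelled as a mixture of diploid normal cells and a
fraction ``rho`` of aberrant cells carrying ``n_total`` copies of a segment,
``m_minor`` of which are the minor allele (the NOMA — number of minor
alleles at a heterozygous site).  The sample-average copy number is

    c = 2 (1 - rho) + n_total * rho

so the expected log2 ratio is ``log2(c / 2)`` and the expected B-allele
frequency at germline-heterozygous probes is

    b = ((1 - rho) + m_minor * rho) / c

Allele labels on an array are arbitrary, so all model math uses the folded
BAF ``min(b, 1 - b)`` in [0, 0.5]: 0.5 means balanced heterozygous, 0 means
complete loss of heterozygosity (LOH).

Per-segment hypothesis fitting enumerates a finite grid of hypotheses
(N, m, rho) and minimises a weighted squared distance to the observed
(folded BAF, log2R) pair.  Only NOMA = 0 hypotheses with N in a qualifying
set (hemizygous loss N=1, copy-neutral LOH N=2 by default) contribute to
the clonal-composition count downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AberrationHypothesis",
    "AberrationFit",
    "ModelConfig",
    "expected_total_copy",
    "expected_log2r",
    "expected_folded_baf",
    "rho_from_folded_baf",
    "rho_from_log2r",
    "fit_segment",
    "fitting_curve",
]


class NonInvertibleError(ValueError):
    """Raised when a hypothesis cannot be inverted from the observed signal."""


@dataclass(frozen=True)
class AberrationHypothesis:
    """One candidate aberration: total copies N, minor-allele copies m, fraction rho."""

    n_total: int
    m_minor: int
    rho: float

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.m_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.m_minor > self.n_total - self.m_minor:
            raise ValueError(
                f"m_minor={self.m_minor} exceeds the major allele count for N={self.n_total}"
            )
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")

    @property
    def ac_percent(self) -> float:
        """Percentage of aberrant cells (%AC)."""
        return 100.0 * self.rho


@dataclass(frozen=True)
class AberrationFit:
    """Best-fitting hypothesis for one segment, with residuals and gating flags."""

    hypothesis: AberrationHypothesis | None
    total_copies: float
    expected_log2r: float
    expected_folded_baf: float | None
    residual_baf: float
    residual_log2r: float
    is_aberrant: bool
    qualifies_for_cc: bool
    note: str = ""


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters for fitting and clonal-composition calling.

    ``qualifying_n_set`` holds the aberrant copy states whose NOMA = 0
    segments count toward the CC number: 1 (hemizygous loss) and 2
    (copy-neutral LOH) by default.  ``gate_eps_baf`` / ``gate_eps_log2r``
    are the fitting-curve gates: a segment whose best NOMA = 0 fit leaves a
    larger residual is "off the fitting curve" and cannot be assigned.
    """

    hypothesis_n_range: tuple[int, ...] = (0, 1, 2, 3, 4)
    qualifying_n_set: frozenset[int] = frozenset({1, 2})
    rho_grid_step: float = 0.01
    rho_min: float = 0.05
    gate_eps_baf: float = 0.025
    gate_eps_log2r: float = 0.10
    weight_baf: float = 1.0
    weight_log2r: float = 0.25
    aberrance_baf_floor: float = 0.45
    aberrance_log2r_band: float = 0.10
    min_probes: int = 50
    merge_delta_ac: float = 5.0
    stage1_tol_baf: float = 0.02
    stage1_tol_log2r: float = 0.08
    count_subclones_only: bool = False

    def __post_init__(self) -> None:
        if self.rho_grid_step <= 0 or self.rho_grid_step > 0.1:
            raise ValueError("rho_grid_step must be in (0, 0.1]")
        for name in ("gate_eps_baf", "gate_eps_log2r", "stage1_tol_baf",
                     "stage1_tol_log2r", "merge_delta_ac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        extra = set(self.qualifying_n_set) - (set(self.hypothesis_n_range) - {0})
        if extra:
            raise ValueError(f"qualifying_n_set members outside hypothesis range: {extra}")

    def rho_grid(self) -> np.ndarray:
        """The rho search grid over (0, 1], inclusive of 1."""
        n = int(round(1.0 / self.rho_grid_step))
        return np.arange(1, n + 1) * self.rho_grid_step


def expected_total_copy(rho: float, n_total: int) -> float:
    """Sample-average copy number c = 2(1 - rho) + N rho."""
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    return 2.0 * (1.0 - rho) + n_total * rho


def expected_log2r(rho: float, n_total: int) -> float:
    """Expected log2 ratio log2(c / 2); diploid baseline is 0."""
    c = expected_total_copy(rho, n_total)
    if c <= 0.0:
        raise ValueError("total copy number is zero: log2R undefined")
    return math.log2(c / 2.0)


def expected_folded_baf(rho: float, n_total: int, m_minor: int) -> float:
    """Expected folded BAF min(b, 1-b) at germline-heterozygous probes."""
    if m_minor < 0 or m_minor > n_total - m_minor:
        raise ValueError("m_minor must satisfy 0 <= m <= N - m")
    c = expected_total_copy(rho, n_total)
    if c <= 0.0:
        raise ValueError("total copy number is zero: BAF undefined")
    b = ((1.0 - rho) + m_minor * rho) / c
    return min(b, 1.0 - b)


def rho_from_folded_baf(b: float, n_total: int, m_minor: int) -> float:
    """Invert the folded-BAF map for a fixed (N, m) hypothesis.

    Solves ``b = ((1 - rho) + m rho) / c`` for rho, giving
    ``rho = (1 - 2b) / (1 - m + (N - 2) b)``.  Raises
    :class:`NonInvertibleError` for hypotheses whose folded BAF does not
    depend on rho (e.g. N = 2, m = 1, where it is identically 0.5).
    """
    if not (0.0 <= b <= 0.5):
        raise ValueError(f"folded BAF must lie in [0, 0.5], got {b}")
    denom = (1.0 - m_minor) + (n_total - 2.0) * b
    if denom <= 0.0:
        raise NonInvertibleError(
            f"hypothesis (N={n_total}, m={m_minor}) is not invertible at b={b}"
        )
    # Flat map: folded BAF == 0.5 for every rho (balanced hypotheses).
    if 2 * m_minor == n_total:
        raise NonInvertibleError(
            f"hypothesis (N={n_total}, m={m_minor}) has constant folded BAF 0.5"
        )
    return (1.0 - 2.0 * b) / denom


def rho_from_log2r(r: float, n_total: int) -> float:
    """Invert the log2R map: rho = (2 - 2*2^r) / (2 - N); undefined at N = 2."""
    if n_total == 2:
        raise NonInvertibleError("log2R is identically 0 for N = 2 (copy-neutral)")
    return (2.0 - 2.0 * 2.0 ** r) / (2.0 - n_total)


def _hypothesis_grid(config: ModelConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                                   np.ndarray, np.ndarray]:
    """Flattened (N, m, rho) grid in tie-break order, with model expectations.

    Rows are ordered by (N, m, rho) ascending so that ``argmin`` (first
    occurrence) realises the deterministic smaller-N, smaller-m, smaller-rho
    tie-break.
    """
    rho = config.rho_grid()
    ns, ms, rs = [], [], []
    for n in sorted(config.hypothesis_n_range):
        for m in range(0, n // 2 + 1):
            ns.append(np.full_like(rho, n, dtype=float))
            ms.append(np.full_like(rho, m, dtype=float))
            rs.append(rho)
    n_arr = np.concatenate(ns)
    m_arr = np.concatenate(ms)
    rho_arr = np.concatenate(rs)
    c = 2.0 * (1.0 - rho_arr) + n_arr * rho_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        exp_r = np.log2(c / 2.0)
        b = ((1.0 - rho_arr) + m_arr * rho_arr) / c
    exp_b = np.minimum(b, 1.0 - b)
    # c = 0 happens only at (N=0, rho=1): unreachable state, exclude via inf.
    bad = ~np.isfinite(exp_r)
    exp_r[bad] = np.inf
    exp_b[bad] = np.inf
    return n_arr, m_arr, rho_arr, exp_b, exp_r


_GRID_CACHE: dict[ModelConfig, tuple[np.ndarray, ...]] = {}


def _grid(config: ModelConfig) -> tuple[np.ndarray, ...]:
    try:
        return _GRID_CACHE[config]
    except KeyError:
        g = _hypothesis_grid(config)
        if len(_GRID_CACHE) > 32:
            _GRID_CACHE.clear()
        _GRID_CACHE[config] = g
        return g


def screen_observation(b_obs: float | None, r_obs: float, config: ModelConfig) -> bool:
    """Aberrance screen on the observed signal, before any fitting."""
    baf_hit = b_obs is not None and b_obs < config.aberrance_baf_floor
    log2r_hit = abs(r_obs) > config.aberrance_log2r_band
    return baf_hit or log2r_hit


def fit_segment(b_obs: float | None, r_obs: float,
                config: ModelConfig | None = None) -> AberrationFit:
    """Fit the best (N, m, rho) hypothesis to one segment's (folded BAF, log2R).

    Minimises ``weight_baf * (b_obs - b_hat)^2 + weight_log2r * (r_obs - r_hat)^2``
    over the full hypothesis grid; ties break toward smaller N, then smaller
    m, then smaller rho.  With ``b_obs`` missing (no heterozygous probes)
    the fit uses log2R alone and can never qualify for the CC count.
    """
    if config is None:
        config = ModelConfig()
    if not np.isfinite(r_obs):
        raise ValueError("observed log2R must be finite")
    if b_obs is not None and not (0.0 <= b_obs <= 0.5):
        raise ValueError(f"observed folded BAF must lie in [0, 0.5], got {b_obs}")

    n_arr, m_arr, rho_arr, exp_b, exp_r = _grid(config)
    if b_obs is None:
        obj = config.weight_log2r * (r_obs - exp_r) ** 2
    else:
        obj = (config.weight_baf * (b_obs - exp_b) ** 2
               + config.weight_log2r * (r_obs - exp_r) ** 2)
    k = int(np.argmin(obj))
    hyp = AberrationHypothesis(int(n_arr[k]), int(m_arr[k]), float(rho_arr[k]))
    res_b = abs(b_obs - exp_b[k]) if b_obs is not None else math.inf
    res_r = abs(r_obs - exp_r[k])
    aberrant = screen_observation(b_obs, r_obs, config)
    qualifies = (
        b_obs is not None
        and aberrant
        and hyp.m_minor == 0
        and hyp.n_total in config.qualifying_n_set
        and res_b <= config.gate_eps_baf
        and res_r <= config.gate_eps_log2r
        and hyp.rho >= config.rho_min
    )
    return AberrationFit(
        hypothesis=hyp,
        total_copies=expected_total_copy(hyp.rho, hyp.n_total),
        expected_log2r=float(exp_r[k]),
        expected_folded_baf=float(exp_b[k]) if b_obs is not None else None,
        residual_baf=float(res_b),
        residual_log2r=float(res_r),
        is_aberrant=aberrant,
        qualifies_for_cc=bool(qualifies),
        note="" if b_obs is not None else "no-het-probes",
    )


def fitting_curve(n_total: int, m_minor: int,
                  rho_grid: "np.ndarray | list[float]") -> list[tuple[float, float]]:
    """Parametric (folded BAF, log2R) curve of one hypothesis as rho varies."""
    if m_minor < 0 or m_minor > n_total - m_minor or n_total < 0:
        raise ValueError(f"invalid hypothesis (N={n_total}, m={m_minor})")
    pts = []
    for rho in rho_grid:
        pts.append((expected_folded_baf(rho, n_total, m_minor),
                    expected_log2r(rho, n_total)))
    return pts
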