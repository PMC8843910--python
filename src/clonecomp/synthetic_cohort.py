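"""Seeded synthetic cohorts with known clone structure and survival endpoints.

The generator emulates OncoScan-style molecular-inversion-probe output:
per-probe log2R and unfolded BAF over genomic segments, produced by the
same normal/aberrant mixture equations the fitting model assumes, plus a
clinical table with group-dependent exponential recurrence-free-survival
(RFS) times under administrative censoring.

Default cohort composition mirrors the surgical hepatocellular-carcinoma
study this package re-analyzes: 8 mono-CC samples (no qualifying
aberration), 26 poly-CC samples (1–3 clones with hemizygous-loss or
copy-neutral-LOH events), and 2 samples whose LOH-like segments fall off
every fitting curve (CC undetermined).  Poly-arm median RFS defaults to
7.0 months; the mono arm encodes "median not reached" as a 60-month median
inside a 60-month administrative window.  Exponential times are the
minimal model with a specified median (rate = ln 2 / median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clone_model import (ModelConfig, expected_folded_baf, expected_log2r)
from .segments_io import ProbeRecord, SegmentRecord, summarize_probes

__all__ = [
    "CloneSpec",
    "TumorSpec",
    "NoiseModel",
    "SurvivalModel",
    "CohortSpec",
    "simulate_tumor",
    "simulate_cohort",
    "PATIENT_COLUMNS",
]

PATIENT_COLUMNS = ["patient_id", "group_true", "rfs_months", "event",
                   "age_ge_70", "pivka_ge_40", "size_ge_4"]

# Covariate prevalence by true group, loosely shaped on the study cohort's
# clinical table; values are Bernoulli probabilities.
DEFAULT_COVARIATE_PREVALENCE = {
    "age_ge_70": {"mono": 0.6, "poly": 0.6, "undetermined": 0.6},
    "pivka_ge_40": {"mono": 0.25, "poly": 0.72, "undetermined": 0.5},
    "size_ge_4": {"mono": 0.4, "poly": 0.6, "undetermined": 0.5},
}


@dataclass(frozen=True)
class CloneSpec:
    """One clone: its cell fraction and its copy-number events."""

    rho: float
    events: tuple[tuple[str, int, int, int, int], ...]  # (chrom, start, end, N, m)

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")
        ivs = sorted((e[0], e[1], e[2]) for e in self.events)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("events overlap within a clone")
        for _, _, _, n, m in self.events:
            if m < 0 or m > n - m:
                raise ValueError(f"invalid hypothesis N={n}, m={m}")


@dataclass(frozen=True)
class TumorSpec:
    sample_id: str
    clones: tuple[CloneSpec, ...]
    n_normal_segments: int = 4
    probes_per_segment: tuple[int, int] = (100, 2000)
    het_fraction: float = 0.25
    # When set, these segments are written with raw (folded_baf, log2r)
    # targets that ignore the mixture model — used for off-curve samples.
    off_curve_segments: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class NoiseModel:
    sigma_log2r_probe: float = 0.25
    sigma_baf_probe: float = 0.04

    def __post_init__(self) -> None:
        if self.sigma_log2r_probe < 0 or self.sigma_baf_probe < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class SurvivalModel:
    median_rfs_poly: float = 7.0
    median_rfs_mono: float = 60.0
    admin_censor: float = 60.0

    def __post_init__(self) -> None:
        if min(self.median_rfs_poly, self.median_rfs_mono) <= 0:
            raise ValueError("medians must be > 0")
        if self.admin_censor < 0:
            raise ValueError("admin_censor must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    n_mono: int = 8
    n_poly: int = 26
    n_undetermined: int = 2
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_mono, self.n_poly, self.n_undetermined) < 0:
            raise ValueError("cohort counts must be >= 0")


def _check_cross_clone_overlap(clones) -> None:
    ivs = []
    for k, cl in enumerate(clones):
        for c, s, e, *_ in cl.events:
            ivs.append((c, s, e, k))
    ivs.sort()
    for (c1, s1, e1, k1), (c2, s2, e2, k2) in zip(ivs, ivs[1:]):
        if c1 == c2 and s2 < e1 and k1 != k2:
            raise ValueError(
                "events overlap across clones; nested subclonal events are not "
                "supported by this generator")


def _probe_block(rng: np.random.Generator, chrom: str, start: int, end: int,
                 n_probes: int, het_fraction: float,
                 exp_r: float, exp_b_unfolded: float | None,
                 noise: NoiseModel) -> list[ProbeRecord]:
    """Simulate probes over one segment.

    Heterozygous probes get the unfolded expected BAF with a random allele
    phase (b or 1-b per SNP) plus Gaussian noise, clipped to [0, 1] — this
    reproduces the mirror-band geometry of real arrays.  Homozygous probes
    sit near 0 or 1.
    """
    pos = np.sort(rng.integers(start, end, size=n_probes))
    is_het = rng.random(n_probes) < het_fraction
    log2r = exp_r + rng.normal(0.0, noise.sigma_log2r_probe, size=n_probes)
    baf = np.empty(n_probes)
    hom_allele = rng.random(n_probes) < 0.5
    baf[:] = np.where(hom_allele, 0.0, 1.0)
    if exp_b_unfolded is not None:
        phase = rng.random(n_probes) < 0.5
        het_b = np.where(phase, exp_b_unfolded, 1.0 - exp_b_unfolded)
        baf[is_het] = het_b[is_het]
    baf = baf + rng.normal(0.0, noise.sigma_baf_probe, size=n_probes)
    baf = np.clip(baf, 0.0, 1.0)
    return [ProbeRecord(chrom, int(p), float(r), float(b), bool(h))
            for p, r, b, h in zip(pos, log2r, baf, is_het)]


def simulate_tumor(spec: TumorSpec, noise: NoiseModel | None = None,
                   seed: int = 0) -> tuple[list[ProbeRecord], list[SegmentRecord]]:
    """Simulate probe data for one tumor; returns probes and true segment labels.

    True segments are probe summaries at zero noise — i.e. the model
    expectations — carrying the segment intervals used for summarisation.
    Deterministic given (spec, seed).
    """
    if noise is None:
        noise = NoiseModel()
    _check_cross_clone_overlap(spec.clones)
    rng = np.random.default_rng(seed)
    lo, hi = spec.probes_per_segment
    probes: list[ProbeRecord] = []
    truth: list[SegmentRecord] = []
    cursor = 0
    seg_len = 10_000_000

    def add_segment(chrom: str, exp_r: float, exp_b_unfolded: float | None,
                    n_probes: int) -> None:
        nonlocal cursor
        start, end = cursor, cursor + seg_len
        cursor = end
        blk = _probe_block(rng, chrom, start, end, n_probes, spec.het_fraction,
                           exp_r, exp_b_unfolded, noise)
        probes.extend(blk)
        n_het = sum(p.is_het for p in blk)
        folded = (min(exp_b_unfolded, 1 - exp_b_unfolded)
                  if (exp_b_unfolded is not None and n_het > 0) else None)
        truth.append(SegmentRecord(
            sample_id=spec.sample_id, chrom=chrom, start=start, end=end,
            n_probes=n_probes, n_het=n_het if folded is not None else 0,
            log2r=exp_r, folded_baf=folded))

    for clone in spec.clones:
        for chrom, _s, _e, n_total, m_minor in clone.events:
            n_probes = int(rng.integers(lo, hi + 1))
            exp_r = expected_log2r(clone.rho, n_total)
            c = 2 * (1 - clone.rho) + n_total * clone.rho
            exp_b = ((1 - clone.rho) + m_minor * clone.rho) / c
            add_segment(chrom, exp_r, exp_b, n_probes)
    for (b_target, r_target) in spec.off_curve_segments:
        n_probes = int(rng.integers(lo, hi + 1))
        add_segment("chr_off", r_target, b_target, n_probes)
    for _ in range(spec.n_normal_segments):
        n_probes = int(rng.integers(lo, hi + 1))
        add_segment("chr_norm", 0.0, 0.5, n_probes)
    return probes, truth


def observed_segments(spec: TumorSpec, noise: NoiseModel | None = None,
                      seed: int = 0) -> list[SegmentRecord]:
    """Simulate a tumor and summarise its probes into observed segments."""
    probes, truth = simulate_tumor(spec, noise, seed)
    return [summarize_probes(probes, (t.chrom, t.start, t.end), spec.sample_id)
            for t in truth]


def _draw_poly_spec(rng: np.random.Generator, sample_id: str,
                    merge_delta_ac: float, hard_mode: bool = False) -> TumorSpec:
    """Poly-CC tumor: 1–3 clones with NOMA = 0 loss / copy-neutral-LOH events.

    Clone fractions are drawn from [0.2, 0.9] with pairwise gaps greater
    than twice the cluster-merging tolerance so the true clone count is
    well-defined; ``hard_mode`` disables the separation constraint.
    """
    n_clones = int(rng.integers(1, 4))
    min_gap = 0.0 if hard_mode else 2.0 * merge_delta_ac / 100.0
    while True:
        rhos = np.sort(rng.uniform(0.2, 0.9, size=n_clones))
        if n_clones == 1 or np.min(np.diff(rhos)) > min_gap + 1e-9:
            break
    clones = []
    for k, rho in enumerate(rhos):
        n_events = int(rng.integers(1, 4))
        events = tuple((f"chr{k+1}", i * 20_000_000, i * 20_000_000 + 10_000_000,
                        int(rng.choice([1, 2])), 0)
                       for i in range(n_events))
        clones.append(CloneSpec(rho=float(rho), events=events))
    return TumorSpec(sample_id=sample_id, clones=tuple(clones),
                     probes_per_segment=(300, 800))


def _draw_mono_spec(sample_id: str) -> TumorSpec:
    return TumorSpec(sample_id=sample_id, clones=(), n_normal_segments=6,
                     probes_per_segment=(300, 800))


def _draw_undetermined_spec(rng: np.random.Generator, sample_id: str) -> TumorSpec:
    # LOH-like folded BAF paired with a strong gain-like log2R: inconsistent
    # with every NOMA = 0 curve, so the sample cannot be assigned.
    offs = tuple((float(rng.uniform(0.10, 0.20)), float(rng.uniform(0.7, 1.0)))
                 for _ in range(int(rng.integers(2, 4))))
    return TumorSpec(sample_id=sample_id, clones=(), n_normal_segments=3,
                     off_curve_segments=offs, probes_per_segment=(300, 800))


def simulate_cohort(spec: CohortSpec,
                    model_config: ModelConfig | None = None,
                    covariate_prevalence: dict | None = None,
                    ) -> tuple[list[SegmentRecord], pd.DataFrame]:
    """Simulate a full cohort: observed segment table + patient clinical table.

    Recurrence times are exponential with the configured group median
    (rate ln 2 / median) and administratively censored at
    ``survival.admin_censor`` months; undetermined samples draw from the
    mono arm (the study's two unassignable cases were recurrence-free).
    Deterministic given ``spec`` (which carries the seed).
    """
    if model_config is None:
        model_config = ModelConfig()
    if covariate_prevalence is None:
        covariate_prevalence = DEFAULT_COVARIATE_PREVALENCE
    rng = np.random.default_rng(spec.seed)
    groups = (["mono"] * spec.n_mono + ["poly"] * spec.n_poly
              + ["undetermined"] * spec.n_undetermined)
    segments: list[SegmentRecord] = []
    rows = []
    for i, group in enumerate(groups):
        sid = f"S{i+1:03d}"
        tumor_seed = int(rng.integers(0, 2**31 - 1))
        if group == "mono":
            tspec = _draw_mono_spec(sid)
        elif group == "poly":
            tspec = _draw_poly_spec(rng, sid, model_config.merge_delta_ac)
        else:
            tspec = _draw_undetermined_spec(rng, sid)
        segments.extend(observed_segments(tspec, spec.noise, tumor_seed))

        median = (spec.survival.median_rfs_poly if group == "poly"
                  else spec.survival.median_rfs_mono)
        t = rng.exponential(median / math.log(2.0))
        event = t < spec.survival.admin_censor
        row = {"patient_id": sid, "group_true": group,
               "rfs_months": round(min(t, spec.survival.admin_censor), 4),
               "event": int(event)}
        for cov, prev in covariate_prevalence.items():
            row[cov] = int(rng.random() < prev[group])
        rows.append(row)
    patients = pd.DataFrame(rows, columns=PATIENT_COLUMNS)
    return segments, patients


def draw_rfs_times(median: float, n: int, seed: int) -> np.ndarray:
    """Draw n exponential recurrence times with the given median (months)."""
    rng = np.random.default_rng(seed)
    return rng.exponential(median / math.log(2.0), size=n)
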