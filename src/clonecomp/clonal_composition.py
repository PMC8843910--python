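"""Per-sample clonal-composition (CC) calling.

The CC number of a sample is the count of distinct aberrant-cell fractions
(%AC) among its qualifying NOMA = 0 segments: every copy-number event is
assumed to arise once in a single clone, so segments sharing a %AC belong
to one clone.  CC = 0 means no qualifying aberration was found — a
homogeneous tumor mass (mono-CC); CC >= 1 is poly-CC.  A sample whose
LOH-like segments all fall off every fitting curve cannot be assigned and
is reported as undetermined.

Pipeline per sample: screen segments for aberrance, fit the mixture model
to each aberrant segment, gate on the fitting curves, single-linkage
cluster the qualifying segments in (folded BAF, log2R), then merge clusters
whose probe-weighted %AC agree within ``merge_delta_ac`` percentage points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .clone_model import AberrationFit, ModelConfig, fit_segment
from .segments_io import SegmentRecord

__all__ = [
    "CloneCluster",
    "ClonalCompositionResult",
    "screen_aberrant",
    "call_sample",
    "call_cohort",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["sample_id", "status", "cc_number", "classification",
                  "n_clusters", "ac_percents"]


@dataclass(frozen=True)
class CloneCluster:
    """One inferred clone: its %AC and the segments attributed to it."""

    ac_percent: float
    member_segments: tuple[SegmentRecord, ...]
    total_probes: int


@dataclass(frozen=True)
class ClonalCompositionResult:
    sample_id: str
    status: str                      # "estimated" | "undetermined"
    cc_number: int | None            # defined only when estimated
    clusters: tuple[CloneCluster, ...]
    classification: str              # "mono" | "poly" | "undetermined"
    n_dropped_off_curve: int = 0

    @property
    def ac_percents(self) -> list[float]:
        return [c.ac_percent for c in self.clusters]


def screen_aberrant(segment: SegmentRecord, config: ModelConfig) -> bool:
    """True iff the segment shows an aberrant signal and enough probes.

    Aberrance: folded BAF below the LOH floor, or |log2R| outside the
    copy-neutral band.  Segments with fewer than ``min_probes`` probes are
    too noisy to call and never pass.
    """
    if segment.n_probes < config.min_probes:
        return False
    baf_hit = (segment.folded_baf is not None
               and segment.folded_baf < config.aberrance_baf_floor)
    log2r_hit = abs(segment.log2r) > config.aberrance_log2r_band
    return baf_hit or log2r_hit


def _union_find_components(n: int, linked) -> list[list[int]]:
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if linked(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [comps[r] for r in sorted(comps)]


def _cluster_qualifying(segments: Sequence[SegmentRecord],
                        fits: Sequence[AberrationFit],
                        config: ModelConfig) -> list[CloneCluster]:
    """Stage 1: single-linkage in (folded BAF, log2R) with per-axis tolerances.
    Stage 2: single-linkage merge of stage-1 clusters by probe-weighted %AC."""
    def linked_s1(i: int, j: int) -> bool:
        si, sj = segments[i], segments[j]
        return (abs(si.folded_baf - sj.folded_baf) <= config.stage1_tol_baf
                and abs(si.log2r - sj.log2r) <= config.stage1_tol_log2r)

    stage1 = _union_find_components(len(segments), linked_s1)

    def weighted_ac(idxs: list[int]) -> float:
        w = np.array([segments[i].n_probes for i in idxs], dtype=float)
        rho = np.array([fits[i].hypothesis.rho for i in idxs])
        return float(100.0 * np.average(rho, weights=w))

    acs = [weighted_ac(c) for c in stage1]

    def linked_s2(i: int, j: int) -> bool:
        return abs(acs[i] - acs[j]) <= config.merge_delta_ac

    stage2 = _union_find_components(len(stage1), linked_s2)

    clusters = []
    for group in stage2:
        idxs = [i for g in group for i in stage1[g]]
        clusters.append(CloneCluster(
            ac_percent=weighted_ac(idxs),
            member_segments=tuple(segments[i] for i in idxs),
            total_probes=sum(segments[i].n_probes for i in idxs),
        ))
    clusters.sort(key=lambda c: -c.ac_percent)
    return clusters


def call_sample(segments: Sequence[SegmentRecord],
                config: ModelConfig | None = None) -> ClonalCompositionResult:
    """Estimate the clonal-composition number of one sample.

    Undetermined when at least one segment passes the LOH screen but no
    screened segment survives the fitting-curve gates — the observed
    (BAF, log2R) pairs do not plot onto any admissible curve.  When only
    some screened segments are off-curve they are dropped with a warning
    and the CC number is computed from the rest.
    """
    if config is None:
        config = ModelConfig()
    segments = list(segments)
    if not segments:
        raise ValueError("call_sample requires at least one segment")
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) != 1:
        raise ValueError(f"segments span multiple samples: {sorted(sample_ids)}")
    sample_id = segments[0].sample_id

    screened = [s for s in segments if screen_aberrant(s, config)]
    loh_screened = [s for s in screened
                    if s.folded_baf is not None
                    and s.folded_baf < config.aberrance_baf_floor]
    fits = {id(s): fit_segment(s.folded_baf, s.log2r, config) for s in screened}
    qualifying = [s for s in screened if fits[id(s)].qualifies_for_cc]
    off_curve_loh = [s for s in loh_screened if not fits[id(s)].qualifies_for_cc]

    if loh_screened and not qualifying:
        return ClonalCompositionResult(
            sample_id=sample_id, status="undetermined", cc_number=None,
            clusters=(), classification="undetermined",
            n_dropped_off_curve=len(off_curve_loh))

    if off_curve_loh:
        logger.warning("%s: dropping %d LOH-screened segment(s) off the fitting curve",
                       sample_id, len(off_curve_loh))

    clusters = _cluster_qualifying(qualifying, [fits[id(s)] for s in qualifying],
                                   config) if qualifying else []
    cc = len(clusters)
    if config.count_subclones_only and cc > 0:
        cc -= 1
    classification = "mono" if cc == 0 else "poly"
    return ClonalCompositionResult(
        sample_id=sample_id, status="estimated", cc_number=cc,
        clusters=tuple(clusters), classification=classification,
        n_dropped_off_curve=len(off_curve_loh))


def call_cohort(segments: Iterable[SegmentRecord],
                config: ModelConfig | None = None) -> list[ClonalCompositionResult]:
    """Call every sample in a segment table; order-stable by sample_id."""
    by_sample: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    if not by_sample:
        raise ValueError("no segments supplied")
    results = []
    for sid in sorted(by_sample):
        try:
            results.append(call_sample(by_sample[sid], config))
        except ValueError as exc:
            raise ValueError(f"sample {sid}: {exc}") from exc
    counts = {"mono": 0, "poly": 0, "undetermined": 0}
    for r in results:
        counts[r.classification] += 1
    logger.info("cohort: %d samples — mono %d, poly %d, undetermined %d",
                len(results), counts["mono"], counts["poly"], counts["undetermined"])
    return results


def write_results(results: Sequence[ClonalCompositionResult],
                  path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            cc = "." if r.cc_number is None else str(r.cc_number)
            acs = ";".join(f"{a:.1f}" for a in r.ac_percents)
            fh.write(f"{r.sample_id}\t{r.status}\t{cc}\t{r.classification}\t"
                     f"{len(r.clusters)}\t{acs}\n")


def read_results(path: str | Path) -> "pd.DataFrame":
    import pandas as pd
    return pd.read_csv(path, sep="\t", na_values=["."])
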