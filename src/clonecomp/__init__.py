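"""clonecomp: clonal-composition estimation from SNP-array BAF/log2R segments.

Estimates the number of copy-number-defined clones in a tumor (the CC
number) from segment-level folded B-allele frequency and log2 ratio,
classifies tumors as mono-CC (CC = 0) vs. poly-CC (CC >= 1), and provides
the cohort-level association and survival statistics used to relate CC
class to clinical outcome — together with a seeded synthetic-cohort
generator so the whole pipeline is testable without array data.
"""

from .clone_model import (
    AberrationFit,
    AberrationHypothesis,
    ModelConfig,
    expected_folded_baf,
    expected_log2r,
    expected_total_copy,
    fit_segment,
    fitting_curve,
    rho_from_folded_baf,
    rho_from_log2r,
)
from .clonal_composition import (
    ClonalCompositionResult,
    CloneCluster,
    call_cohort,
    call_sample,
    screen_aberrant,
)
from .cohort_stats import (
    NOT_REACHED,
    ContingencyTable2x2,
    KMCurve,
    SurvivalSample,
    build_contingency,
    fisher_exact_two_sided,
    km_curve,
    km_median,
    logrank_test,
    mann_whitney_u,
)
from .segments_io import (
    ProbeRecord,
    SegmentRecord,
    read_segments,
    summarize_probes,
    write_segments,
)
from .synthetic_cohort import (
    CloneSpec,
    CohortSpec,
    NoiseModel,
    SurvivalModel,
    TumorSpec,
    draw_rfs_times,
    simulate_cohort,
    simulate_tumor,
)

__version__ = "0.1.0"
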