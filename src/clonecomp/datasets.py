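"""Published 2x2 counts from the surgical HCC cohort re-analyzed here.

The source study profiled 36 resected hepatocellular carcinomas on a
genome-wide SNP array, estimated each tumor's clonal-composition (CC)
number, and reported univariate associations between CC class (mono-CC,
CC = 0, n = 8 vs. poly-CC, CC >= 1, n = 26) and clinicopathological
variables, plus early-recurrence risk factors over the full cohort
(n = 36: 22 with early recurrence, 14 without).  The printed 2x2 counts
are transcribed below so the Fisher exact p-values can be recomputed.

Mutation counts are reconstructed from the printed percentages over the
group sizes: TP53 pathogenic mutations in 12.5% of 8 mono-CC and 30.8% of
26 poly-CC tumors (1 and 8 patients); CTNNB1 in 37.5% and 7.7% (3 and 2).
"""

from __future__ import annotations

from .cohort_stats import ContingencyTable2x2

__all__ = ["CC_ASSOCIATION_TABLES", "EARLY_RECURRENCE_TABLES",
           "MUTATION_TABLES", "REPORTED_FISHER_P"]

# Rows: (mono-CC, poly-CC); columns: (first listed level, second level).
CC_ASSOCIATION_TABLES: dict[str, ContingencyTable2x2] = {
    "early_recurrence": ContingencyTable2x2(2, 6, 20, 6),       # yes/no
    "vascular_invasion": ContingencyTable2x2(4, 4, 24, 2),      # pos/neg
    "histologic_grade": ContingencyTable2x2(4, 3, 4, 21),       # well / mod-poor
    "pivka2_ge_40": ContingencyTable2x2(6, 2, 7, 18),           # <40 / >=40
    "tumor_number": ContingencyTable2x2(4, 4, 23, 3),           # single/multiple
}

# Rows: (early recurrence, no recurrence).
EARLY_RECURRENCE_TABLES: dict[str, ContingencyTable2x2] = {
    "tumor_size_ge_4": ContingencyTable2x2(6, 16, 12, 2),       # <4 / >=4 cm
    "pivka2_ge_40": ContingencyTable2x2(4, 17, 10, 4),          # <40 / >=40
    "nbnc": ContingencyTable2x2(13, 9, 2, 12),                  # yes/no
}

# Rows: (mono-CC, poly-CC); columns: (mutated, wild-type).
MUTATION_TABLES: dict[str, ContingencyTable2x2] = {
    "tp53": ContingencyTable2x2(1, 7, 8, 18),
    "ctnnb1": ContingencyTable2x2(3, 5, 2, 24),
}

# p-values printed in the source study, to 4 decimals.
REPORTED_FISHER_P: dict[str, float] = {
    "early_recurrence": 0.0127,
    "vascular_invasion": 0.0180,
    "histologic_grade": 0.0469,
    "pivka2_ge_40": 0.0351,
    "tumor_number": 0.0374,
    "tumor_size_ge_4": 0.0016,
    "pivka2_ge_40_recurrence": 0.0041,
    "nbnc": 0.0142,
    "tp53": 0.4030,
    "ctnnb1": 0.0721,
}

#: Median recurrence-free survival printed for the poly-CC arm (months);
#: the mono-CC median was not reached within follow-up.
REPORTED_MEDIAN_RFS_POLY = 7.0
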