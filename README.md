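# clonecomp

Estimation of tumor **clonal composition (CC)** from SNP-array segment data,
with the cohort-level statistics used to relate CC class to clinical outcome
in resectable hepatocellular carcinoma (HCC), and a seeded synthetic-cohort
generator so the entire pipeline runs and is tested without array data.

Intended users: cancer-genomics analysts working with allele-specific
copy-number segment tables (OncoScan-style log2R + B-allele frequency), and
anyone wanting a compact, fully tested reference for the CC statistic and
its downstream survival analysis.

## The model

A segment in a tumor sample is a mixture of diploid normal cells and a
fraction ρ of aberrant cells carrying N total copies, m of them the minor
allele (the NOMA). The sample-average copy number is

```
c = 2(1 − ρ) + Nρ
```

giving the expected log2 ratio `log2(c/2)` and, at germline-heterozygous
probes, the expected B-allele frequency `b = ((1 − ρ) + mρ)/c`. Allele
labels are arbitrary, so the model works with the folded BAF
`min(b, 1 − b) ∈ [0, 0.5]`: 0.5 is balanced heterozygous, 0 is complete
loss of heterozygosity (LOH).

Each aberration type traces a **fitting curve** in the (folded BAF, log2R)
plane as ρ varies. Fitting a segment means finding the (N, m, ρ) grid point
whose curve passes closest to the observed pair. Only NOMA = 0 segments
(hemizygous loss N = 1, copy-neutral LOH N = 2) are unambiguous enough to
carry clonal information; their fitted ρ is the percentage of aberrant
cells, %AC = 100ρ. Segments sharing a %AC are attributed to one clone, and
the **CC number** is the count of distinct %AC clusters:

* CC = 0 — no qualifying aberration: homogeneous tumor mass (**mono-CC**);
* CC ≥ 1 — **poly-CC**, a heterogeneous tumor;
* **undetermined** — the sample's LOH-like segments fall off every fitting
  curve and cannot be assigned.

Downstream, mono-CC vs. poly-CC groups are compared with two-sided Fisher
exact tests (association with clinical covariates), the Kaplan–Meier
product-limit estimator with median recurrence-free survival (RFS), and the
log-rank test — all implemented from first principles in
`clonecomp.cohort_stats` and cross-checked against scipy and lifelines.

## Worked example

The numbered scripts under `analysis/` run the study design end to end on
synthetic data (all outputs land in `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_clonal_composition.py
python analysis/03_cohort_statistics.py
python analysis/04_reported_associations.py
```

which prints (default seed 42):

```
simulated 36 samples (8 mono, 26 poly, 2 undetermined), 262 segments -> results
called 36 samples: mono 8, poly 26, undetermined 2 -> results/cc_results.tsv
excluded 2 undetermined sample(s)

survival (median RFS, log-rank):
group  n median_rfs logrank_chi2 logrank_p
 mono  8         NR      13.6060    0.0002
 poly 26     5.7960      13.6060    0.0002
```

Reading: of 36 simulated tumors the caller reproduces every generated class
(8 mono-CC, 26 poly-CC, 2 undetermined); the two undetermined samples are
excluded from statistics, and in the remaining 34 the poly-CC arm has a
median RFS of 5.8 months in this draw (the generating median is 7.0) while
the mono-CC median is never reached — the log-rank test separates the arms
at p = 0.0002. Script 04 recomputes the ten published univariate Fisher
p-values from the printed 2×2 counts and reports `10/10 … reproduced to 4
decimals`.

The same pipeline is available as a CLI over a single YAML config:

```bash
clonecomp simulate --config config.yaml --seed 42 --out results
clonecomp call    --segments results/segments.tsv --out results
clonecomp stats   --results results/cc_results.tsv --patients results/patients.tsv --out results
```

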