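# interva5

Probabilistic interpretation of verbal-autopsy (VA) data in the
InterVA-5 lineage: batch assignment of pregnancy status, up to three
WHO-2016 causes of death and a circumstance-of-mortality category
(COMCAT) per case, aggregation into cause-specific mortality fractions
(CSMFs), and concordance-based comparison of mortality profiles.

Around half of the world's deaths are never medically certified. VA —
a structured interview with relatives about the signs and symptoms
preceding a death — is the standard instrument for filling that gap,
and automated interpretation is the only way to process it at civil
registration scale. This package implements the knowledge-base-driven
engine for that task: a matrix of letter-graded conditional
probabilities P(indicator | cause) drives a naive-Bayes update

    L(c) ∝ P₀(c) · ∏_{i ∈ S} P(i | c)

over the 64 WHO-2016 cause categories, where *S* is the set of
indicators with a *substantive* response (the evidential polarity of
each item, which may be yes or no); missing and non-substantive
responses carry no evidence. Records in the older WHO-2012 and
Tariff-2 formats are handled by masking, since both item sets are
subsets of the WHO-2016 standard. Population tables are compared with
Lin's concordance correlation coefficient,
ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with population-moment
denominators and a Fisher-z confidence interval.

Intended users: epidemiologists and health-information teams running
mortality surveillance, and methodologists comparing VA interpretation
models. See `docs/methods.md` for the model, its assumptions and the
design decisions.

## Worked example

The published knowledge base is a separate download, so the quickest
end-to-end run uses the synthetic module, which generates a KB with a
known signature structure and a cohort drawn from a planted cause
distribution:

```
$ interva5 simulate --seed 5 --n-cases 500 --out-dir demo
$ interva5 classify --kb demo/kb.csv --input demo/records.csv --out demo/cases.csv
knowledge base demo/kb.csv (sha256 99213993f344)
records read: 500; excluded: 0; classified: 500
$ head -3 demo/cases.csv
ID,PREG_STATUS,PREG_LIK,CAUSE1,LIK1,CAUSE2,LIK2,CAUSE3,LIK3,INDET,COMCAT,COMCAT_LIK,WARNINGS
case00000,not pregnant or not applicable,0.9,05.01,0.9997,,,,,0.0003,sought care,0.4,
case00001,not pregnant or not applicable,0.9,02.01,0.999,,,,,0.001,sought care,0.4,
```

Each row carries the pregnancy-status argmax with its likelihood, the
reported causes (here one dominant cause per case — the synthetic
signal is strong), the indeterminate residual (reported likelihoods +
INDET always sum to 1), and the COMCAT argmax.

```
$ interva5 csmf --kb demo/kb.csv --input demo/records.csv --redistribute --out demo/csmf.csv
$ cat demo/csmf.csv
stratum,cause,label,broad_group,fraction
5plus,01.01,,Infections,22.358101580038237
5plus,02.01,,Neoplasms,18.768431587897318
5plus,03.01,,Other non-communicable diseases,19.71145002862558
5plus,04.01,,Cardiovascular diseases,16.11217714001433
5plus,05.01,,Other non-communicable diseases,23.049839663424592
```

The fractions are percentages per stratum (here all 500 synthetic
cases are adults, so one 5-plus stratum summing to 100 after
`--redistribute` removes the indeterminate fraction). The planted
distribution was uniform (20% each); the estimates sit within
sampling error of it. `interva5 compare --a ... --b ... --stratum
5plus` then reports agreement between two such tables:

```
CCC = 1.000 (95% CI 1.000 to 1.000), n = 5
```

The same pipeline is available as a library (`load_knowledge_base`,
`read_va_csv`, `check_consistency`, `classify_cohort`,
`aggregate_csmf`, `concordance_correlation`, ...), which is what the
test suite exercises.

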