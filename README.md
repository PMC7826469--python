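# pvscreen

Pharmacovigilance signal-screening toolkit: ingest FAERS-style spontaneous
adverse-event reports, deduplicate them to one case per case number, compute
reporting-odds-ratio (ROR) disproportionality statistics with stratified and
comedication-interaction variants, and run the downstream chart-review and
gene-expression comparison stages. Every stage is exercisable on synthetic
data or on the embedded reference count fixtures — no external downloads.

## What it does

| Module | Purpose |
| --- | --- |
| `pvscreen.faers_io` | Read "$"-delimited DEMO/DRUG/REAC triplets, validate, convert age units, normalize drug names through synonym maps, deduplicate to the latest report version per case |
| `pvscreen.signal_stats` | 2×2 contingency tables, ROR with log-scale Wald 95% CI, exact Fisher test (integer arithmetic for n ≤ 1000), signal classification, sex/age stratification |
| `pvscreen.interaction` | Within reports of a base drug, screen every co-reported drug for modification of an event's reporting odds (inverse-signal screen) |
| `pvscreen.cohort` | RECIST 1.0 response classification, ORR/DCR with Fisher/chi-square selection rule, Mann-Whitney U, CTCAE-style hypertension flagging, SBP-change summary |
| `pvscreen.expression` | Two-group log2 expression comparison (Welch t, fold change `2**Δmean`), ddCq qPCR quantification, Monte-Carlo Dunnett many-to-one test |
| `pvscreen.synthetic` | Seeded generators for report sets (planted drug-event and drug-drug odds ratios, duplication, missingness), cohorts, and expression matrices with truth sidecars |
| `pvscreen.datasets` | Embedded reference counts (contingency tables, stratum counts, comedication tables, cohort responses, expression group means) and materializers turning them into full inputs |

## CLI

```sh
# generate a synthetic report set with a planted protective comedication
pvscreen simulate reports --config gen.yaml --seed 1 --out faers/

# deduplicate to the canonical case table
pvscreen dedup --demo faers/DEMO23Q1.txt --drug faers/DRUG23Q1.txt \
    --reac faers/REAC23Q1.txt --out cases.tsv

# total + stratified ROR for one drug-event pair
pvscreen signal --reports cases.tsv --drug BEVACIZUMAB --out signals.tsv

# comedication inverse-signal screen
pvscreen screen --reports cases.tsv --base-drug BEVACIZUMAB \
    --min-coreports 100 --direction inverse --out screen.tsv

# chart-review endpoints and SBP summary
pvscreen simulate cohort --fixture --out cohort.tsv
pvscreen cohort --patients cohort.tsv --out cohort_summary.tsv

# expression comparison / qPCR quantification
pvscreen expression compare --matrix expr.tsv --group-a treated --group-b vehicle --out cmp.tsv
pvscreen expression ddct --plate plate.csv --control DMSO --target VEGFA --out ddct.tsv

# fixture end-to-end run with a reproducibility manifest
pvscreen all --seed 1 --out artifacts/
```

The event term set defaults to the packaged hypertension list
(`src/pvscreen/data/hypertension_smq.txt`) and the pathway gene list to the
packaged VEGF-signaling set; both are plain text and overridable with
`--event-terms` / `--genes`.

Exit codes: 0 success, 2 configuration error, 3 data error, 4 stage failure.

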