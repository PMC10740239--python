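# labcascade

Care-cascade analysis of type 2 diabetes from longitudinal laboratory
records, built for national public-sector laboratory databases (the
South African NHLS data structure: one row per specimen with identity
fields, test type, numeric result and facility context) and for the
epidemiologists who analyse them.

A laboratory database sees the diabetes care continuum as a sequence of
tests per patient: a first HbA1c or blood-glucose measurement
(screening), a value above the diagnostic cut-off (HbA1c ≥ 6.5 %,
fasting glucose ≥ 7.0 mmol/l, random glucose ≥ 11.1 mmol/l), a repeat
diabetes test between one month and 24 months later (retention-in-care),
and a follow-up value below the control cut-off (HbA1c < 7.0 %, fasting
glucose < 8.0 mmol/l, random glucose < 10.0 mmol/l — glycaemic
control). `labcascade` turns raw per-specimen extracts into that
cascade:

1. **simulate** — a synthetic cohort generator emulating the
   multi-morbidity laboratory database (facility ⊂ district ⊂ province
   hierarchy, HIV/TB co-testing, identity corruption) with withheld
   ground truth, since the real extract is not redistributable;
2. **link** — probabilistic record linkage: weighted identity-field
   similarity scores, blocking, graph clustering, and pairwise
   sensitivity/PPV evaluation against ground truth;
3. **cascade** — cohort eligibility (first diabetes-type test in
   2012-01-01..2015-03-31, age ≥ 30) and the three sequential outcomes
   with HIV (PLWH/PLWOH) and TB status flags;
4. **standardize** — direct age-standardization over 5-year bands
   30–34 … ≥ 75, `p_std = Σ w_b p_b`, with delta-method CIs;
5. **regress** — modified Poisson regression (log-link Poisson GLM with
   cluster-robust sandwich variance, facilities nested in districts)
   yielding crude and adjusted risk ratios for each cascade stage.

See `docs/methods.md` for the model, the calendar conventions, and
what the synthetic generator does and does not emulate.

## Worked example

```python
import labcascade as lc

cfg = lc.SimConfig(n_patients=20_000, seed=11)
cfg.corruption = lc.CorruptionSpec(p_char_edit=0.02, p_dob_error=0.01)
records, truth = lc.generate_cohort(cfg)
records = lc.corrupt_identities(records, cfg.corruption, seed=12)

links = lc.cluster_records(records.reset_index(drop=True))
ev = lc.evaluate_linkage(links, truth.record_map)
print(f"linkage: sensitivity={ev.sensitivity:.3f} ppv={ev.ppv:.3f}")

rows, excl = lc.build_cascade(records, links=links)
tab = lc.build_cascade_table(rows, weights=lc.load_weights())
o = tab[tab.stratifier == "overall"].iloc[0]
print(f"tested={o.n_tested}  diagnosed={o.n_diagnosed} ({100*o.p_diagnosed:.1f}%)")
print(f"retained={o.n_retained_dm} ({100*o.p_retained:.1f}% of diagnosed)")
print(f"controlled={o.n_controlled} ({100*o.p_controlled:.1f}% of diagnosed; "
      f"{100*o.p_controlled_given_retained:.1f}% of retained)")

fit = lc.fit_modified_poisson(rows, lc.ModelSpec(outcome="controlled"))
t = fit.table
r = t[(t.covariate == "hiv_status") & (~t.ref)].iloc[0]
print(f"adjusted RR, control, PLWH vs PLWOH: {r.rr:.2f} ({r.lo:.2f}, {r.hi:.2f})")
```

prints

```
linkage: sensitivity=1.000 ppv=0.999
tested=19996  diagnosed=9171 (45.9%)
retained=2837 (30.9% of diagnosed)
controlled=837 (9.1% of diagnosed; 29.5% of retained)
adjusted RR, control, PLWH vs PLWOH: 1.50 (1.29, 1.75)
```

Reading the output: mild identity corruption (2% character edits, 1%
date-of-birth errors) costs the linkage essentially nothing here —
every asserted match but a handful is correct (PPV 0.999), and 19,996
clusters emerge from 20,000 true patients. Of the patients tested,
45.9% have a lab value indicating diabetes; only 30.9% of those return
for a diabetes test in the qualifying window, and 9.1% reach a
controlled value within 24 months — the configured cascade, recovered
through the full linkage-plus-classification pipeline. The adjusted
risk ratio of 1.50 (95% CI 1.29–1.75) estimates the configured HIV
effect of 1.42 on glycaemic control.

The same pipeline runs from the shell:

```sh
labcascade simulate --n-patients 5000 --seed 1 --out run/extract.csv
labcascade link --extract run/extract.csv --out run/links.csv \
    --truth run/extract.truth_map.csv --evaluate
labcascade cascade --extract run/extract.csv --links run/links.csv --outdir run
labcascade run-all --outdir run --seed 1     # everything + manifest + figure
```

## Layout

```
src/labcascade/
  simulate.py        synthetic cohort + identity corruption
  linkage.py         scoring, blocking, clustering, evaluation
  cascade.py         eligibility, outcomes, cascade tables, trends
  standardize.py     direct age-standardization
  regression.py      modified Poisson risk ratios
  pipeline.py        orchestration, manifest, cascade figure
  cli.py             command-line entry points
  io.py              extract / ground-truth / mapping files
  reference_counts.py  published counts used as cross-check inputs
  data/              bundled synthetic age weights (not official estimates)
```
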