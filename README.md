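# sichpipe

A severity-analysis pipeline for spontaneous intracerebral hemorrhage
(sICH) cohorts, for researchers quantifying the link between circulating
neutrophil markers and clinical outcome. It implements four stages as a
tested Python library with a thin CLI:

* **CT volumetry** — bedside ABC/2 ellipsoid estimation and a
  semiautomated dual-clustering segmentation of brain, intraparenchymal
  hemorrhage (IPH) and perihematomal edema (PHE), with volumes in ml;
* **NET scoring** — segmentation of nuclei on DAPI-stained blood-smear
  fields and the circularity index
  `4π · (minimum enclosing circle area) / (traced perimeter)²`, with
  NET-positive defined as circularity < 0.8;
* **flow gating** — scatter-polygon selection of the neutrophil cloud,
  isotype/FMO-derived thresholds and quadrant counting of DEspR+CD11b+
  ("rogue") double positives;
* **severity statistics** — Spearman rank correlations (midranks,
  Pearson-on-ranks), Bonferroni correction, Fisher-z power, Mann–Whitney
  comparisons, Hedges' g, and composite markers such as
  ICH score + NLR + rogue-neutrophil count (K/μl) + NET+ count (K/μl).

A validated 13-patient pilot cohort ships with the package, and seeded
synthetic generators (CT phantoms with analytic volumes, star-polygon
smear nuclei with closed-form circularity, flow mixtures with planted
double-positive fractions, Gaussian-copula cohorts) provide ground truth
for every imaging stage. See `docs/methods.md` for the models and
parameter choices.

## Worked example

Correlate the packaged cohort's markers with 90-day modified Rankin
Scale (mRS) outcome:

```python
from sichpipe import packaged_cohort
from sichpipe.cohort import derive_fields
from sichpipe.stats import composite_marker, correlation_power, spearman

cohort = derive_fields(packaged_cohort())
r = spearman(cohort.column("rogue_n_count"), cohort.column("mrs_90d"))
print(round(r, 2))                         # 0.83
combo = composite_marker(
    cohort, ["ich_score", "nlr", "rogue_n_count", "net_n_count"])
print(round(spearman(combo, cohort.column("mrs_90d")), 3))  # 0.941
print(round(correlation_power(0.71, n=13, alpha=0.05), 3))  # 0.801
print(round(100 * cohort.column("ivh").mean(), 1))          # 84.6
```

The first number says higher circulating DEspR+CD11b+ neutrophil counts
rank-track worse 90-day outcome; the composite of the index ICH score
with all three neutrophil markers (counts on the K/μl scale) correlates
even more strongly (r = 0.941); any marker with |r| > 0.71 clears 0.8
power at this sample size; and 84.6% of the cohort (11/13) has
intraventricular extension by the modified-Graeb-score criterion.

The same tables come from the CLI as a deterministic JSON bundle:

```sh
sichpipe stats src/sichpipe/data/pilot_cohort.csv --out-dir out/
```

whose `table4` section contains, e.g.
`"ich_score": {"r": 0.917, ...}` and
`"ich_score+nlr+rogue_n+net_n": {"r": 0.941, "class": "strong", ...}`.

Synthetic inputs for the imaging stages:

```sh
sichpipe simulate phantom --seed 7 --out-dir phantom/
sichpipe volumes phantom/phantom.nii.gz --out volumes.json
sichpipe simulate flow --seed 7 --out-dir flow/
sichpipe flow flow/events.csv --out quadrants.json
```

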