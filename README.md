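# metalrisk

Dietary health-risk assessment of metal residues in small-ruminant muscle and
liver, for food-safety scientists and exposure modellers.

Surveys of slaughtered sheep and goats report concentrations of toxic (Cd,
Pb, Ni) and essential (Co, Se, Cu, Fe, Mg, Mn, Zn) elements in edible
tissues, typically as group means ± SD for sex-species groups, with
non-detect (ND) cells below the instrument's limit of detection.  `metalrisk`
turns such tables — or per-animal data — into a reproducible risk analysis:

- **Deterministic risk.**  For an adult consumer (body weight *BW*, tissue
  ingestion rate *IR*), the estimated daily intake of an element at tissue
  concentration *C* is

  EDI = IR · C / BW  (mg/kg-bw/day)

  The non-carcinogenic hazard quotient is
  HQ = (EF · ED · IR · C)/(RfD · BW · AT), which under the chronic defaults
  (EF = 365 d/y, ED = 70 y, AT = 25550 d) reduces exactly to EDI/RfD; the
  hazard index is HI = Σ HQ over co-occurring elements, and the incremental
  lifetime cancer risk is ILCR = EDI · CSF for the elements with an oral
  slope factor (Pb 0.0085, Cd 0.380, Ni 0.84 per mg/kg/day).  ILCR is banded
  per USEPA practice: < 10⁻⁶ negligible, 10⁻⁶–10⁻⁴ acceptable, > 10⁻⁴
  unacceptable.  Every concentration is also screened against its
  tissue-matched maximum residue level (EC/Codex/WHO/FAO-WHO).

- **Monte Carlo uncertainty.**  Candidate concentration distributions
  (lognormal, Weibull, scaled beta, normal) are fitted by maximum likelihood,
  ranked by the Anderson–Darling statistic, and propagated through the risk
  equations (10,000 iterations by default), reporting the mean and the 5th,
  50th and 95th percentiles of HQ, HI and ILCR.

- **Source identification.**  Pearson correlations with the conventional
  strength bands (r > 0.7 strong, 0.5–0.7 moderate), correlation-matrix PCA,
  and hierarchical clustering of elements (1 − r dissimilarity, average
  linkage) separate geogenic from anthropogenic element groups.

- **Synthetic cohorts.**  A generator reproduces the packaged study design
  (4 sex-species groups × 2 tissues × 10 elements, n = 20/group) with
  moment-matched marginals, a Gaussian copula for inter-element dependence,
  LOD-aware censoring, and a planted two-source cohort for validating the
  chemometric stage.

## Worked example

Run the deterministic risk report on the packaged study table (non-detects
treated as zero, equal-weight pooling of the four sex-species groups):

```python
import metalrisk as m

tox, params, lod = m.load_reference_bundle()
records = m.load_study_records()
muscle = m.tissue_risk(records, tox, params, "muscle")
print(f"muscle HI = {muscle.hi:.4f}")
for r in muscle.results:
    if r.element in ("Fe", "Ni", "Pb"):
        print(r.element, f"C={r.concentration:.4g}", f"HQ={r.hq:.4g}",
              f"ILCR={r.ilcr:.3e}" if r.ilcr is not None else "ILCR=--")
```

prints

```
muscle HI = 0.1577
Fe C=114.9 HQ=0.02017 ILCR=--
Ni C=0.9075 HQ=0.005576 ILCR=9.368e-05
Pb C=0.16 HQ=0.004916 ILCR=1.671e-07
```

Reading: the pooled muscle iron concentration of 114.9 mg/kg yields a hazard
quotient of 0.0202 — two orders of magnitude below the HQ = 1 safety
threshold — and the total muscle hazard index is 0.158, so chronic meat
consumption poses no appreciable non-carcinogenic risk.  Nickel's cancer
risk (9.4 × 10⁻⁵) falls in the *acceptable* USEPA band but close to its
upper edge, while lead's (1.7 × 10⁻⁷) is negligible.  Every one of the eight
Ni cells (0.76–1.2 mg/kg) exceeds the 0.5 mg/kg WHO residue limit:

```python
ni = [r for r in records if r.element == "Ni"]
print({m.screen_mrl(r, tox["Ni"]) for r in ni})   # {'exceeds'}
```

The same analyses are available from the shell:

```bash
metalrisk risk --output run                    # packaged table -> run_risk.csv/json
metalrisk simulate --seed 1 --output sim       # synthetic per-animal cohort
metalrisk mc --input sim_cohort.csv --tissue muscle --iters 10000 --seed 42 --output sim
metalrisk sources --input sim_cohort.csv --output sim   # PCC/PCA/HCA tables
```

Every run writes a manifest (config hash, seed, input checksum) so results
can be reproduced bit-for-bit.

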