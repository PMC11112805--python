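# symptomnet

Symptom-network analysis for longitudinal ordinal questionnaire cohorts,
built around the Karolinska Exhaustion Disorder Scale (KEDS): nine
symptoms of stress-induced exhaustion disorder, each self-rated 0–6 at
five waves of a treatment study.

The package answers two kinds of questions that arise in the network
view of mental disorders:

1. **Which symptoms are most tightly interrelated?**  At each wave the
   conditional association structure among the nine items is estimated
   as an unregularized **partial Spearman correlation network**: rank
   correlations `R` are inverted and standardized,
   `ρ_ij = −K_ij / √(K_ii K_jj)` with `K = R⁻¹`, so an edge is the
   association between two symptoms after controlling for all others.
   Node importance is quantified by strength (Σ|ρ| incident), closeness
   ((k−1)/Σ shortest-path distance with edge length 1/|ρ|), and
   fractional betweenness, each z-standardized across nodes.
   Estimation uncertainty comes from a non-parametric edge bootstrap
   (percentile 95% CIs) and a case-dropping bootstrap summarized by
   correlation-stability (CS) coefficients (largest droppable fraction
   retaining r ≥ 0.7 with the full sample in ≥ 95% of subsamples;
   CS ≥ 0.5 is conventionally "stable").
2. **Do networks differ between waves or between outcome groups?**
   Connectivity `S = Σ_{i<j} |ρ_ij|` is compared with a permutation
   **Network Comparison Test** (global strength, maximum edge
   difference, Holm-adjusted per-edge tests) in paired (longitudinal)
   or independent designs.  Treatment responders (total-score drop ≥ 9
   and follow-up total < 19) are compared to non-responders after exact
   matching on baseline totals.

Because real patient cohorts of this kind cannot be shared, the package
ships a **calibrated synthetic-cohort generator**: a latent Gaussian
copula whose partial-correlation structure is known exactly, with
per-item thresholds calibrated so that marginal item means reproduce a
realistic declining symptom trajectory, MCAR attrition per wave, and a
latent improver class producing responder heterogeneity.  Every
downstream method can therefore be validated against ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_estimate_networks.py --seed 1
python analysis/06_responders.py --seed 1 --permutations 500
```

prints (seed 1):

```
simulated 915 subjects, 4345 records
  timepoint  n_complete  total_mean  total_sd  missing_n  missing_pct
 assessment         914       34.59      4.50          1            0
      start         908       32.76      4.67          7            1
   midpoint         877       26.99      4.51         38            4
        end         865       22.76      4.39         50            5
followup12m         781       20.64      6.54        134           15

strongest baseline edges:
  concentration -- memory: 0.325
  mental_stamina -- recovery: 0.270
  mental_stamina -- experience_of_demands: 0.250

classification: {'non_responder': 483, 'responder': 297, 'unclassified': 134}
matched 281 per group; excluded 218
baseline connectivity: responders 2.94 vs non-responders 2.91 (p=0.954)
```

Reading this: total symptom scores decline from 34.6 to 20.6 over the
five waves while ~15% of follow-up records are missing; the strongest
conditional associations at baseline are memory–concentration and
recovery–mental stamina (the planted ground truth, recovered from the
ordinal data); and after exact baseline matching the responder and
non-responder networks do not differ in connectivity — both groups were
drawn from the same latent structure, so the permutation test correctly
finds nothing.  `analysis/03`–`05` add centrality tables, bootstrap
stability (strength/closeness stable, betweenness not), and paired
longitudinal comparisons.

The same steps are available as a CLI
(`symptomnet simulate|estimate|centrality|stability|compare|respond|match|run`)
and as library functions (`symptomnet.estimate_network`,
`symptomnet.nct`, ...).

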