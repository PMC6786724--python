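# fmtselect

Quantitative donor selection for fecal microbiota transplantation (FMT).

Stool banks and trial clinicians increasingly want to pick FMT donors
*rationally* — by what a donor's microbiome contains or produces — rather
than treating all screened donors as interchangeable. `fmtselect`
implements the three quantitative workflows that decision rests on:

1. **Taxon-panel scoring** (`fmtselect.taxa`). Score each donor by the
   summed relative abundance of a genus panel (by default, butyrate
   producers — the taxa most consistently depleted in IBD), and test
   whether patients who received high-panel donors responded more often.
   For donor score $s_d$ and patients grouped by clinical response, the
   test is the two-sided equal-variance two-sample t-test on the linked
   donors' scores.
2. **Metabolomics donor ranking** (`fmtselect.metabolites`). When community
   *function* matters more than taxonomy (e.g. liver cirrhosis / hepatic
   encephalopathy), rank donors directly on stool metabolites: the mean of
   the measured short-chain fatty acids (butyrate, isovalerate,
   propionate), and the bile-acid conversion ratio

   $$\rho_d = \frac{\mathrm{LC} + \mathrm{DC}}{\mathrm{CDC} + \mathrm{C}}$$

   (lithocholate + deoxycholate over chenodeoxycholate + cholate, i.e.
   secondary over primary bile acids). Donors inside the top quantile
   (default 25 %) of **both** rankings are flagged for follow-up.
3. **Retrospective-discovery power simulation** (`fmtselect.power`). How
   large must an FMT arm be before a post-hoc search for "taxa that
   differ between responders and non-responders" can succeed? A completed
   case-control dataset models the effect size: genera are ranked by
   signal-to-noise ratio

   $$\mathrm{SNR}_g = \frac{\overline{\log a_g}^{\,\text{case}} - \overline{\log a_g}^{\,\text{ctrl}}}{\mathrm{sd}(\log a_g)}$$

   on the full data, the top 10 |SNR| genera are the "true" hits, and
   simulated trials subsample cases as responders and controls as
   non-responders, test each genus with a tie-corrected Kruskal–Wallis
   rank test, apply Benjamini–Hochberg FDR across genera, and count how
   many true hits reach q < 0.05.

A synthetic-data module (`fmtselect.synthetic`) generates compositional
case-control genus tables with planted effects, donor metabolomes with
known latent rankings, and donor/patient trial cohorts with a controllable
donor→response effect — so every stage is testable end-to-end with known
ground truth and no downloads.

## Worked example

Rank 40 synthetic donors on SCFA production and bile-acid conversion:

```bash
$ echo '{"n_donors": 40, "sigma": 0.2, "seed": 7}' > met.json
$ fmtselect make-synthetic metabolome --spec met.json --out-prefix met
$ fmtselect rank-donors --metabolome met.metabolome.tsv --out ranks.tsv
3/40 donors in top 25% of both metrics: D003, D022, D038
```

With a 25 % quantile the rank cutoff is ceil(0.25·40) = 10; exactly the
donors ranked ≤ 10 on *both* metrics are selected (`ranks.tsv` holds the
full score/rank table — e.g. D003 is rank 1 on SCFAs and rank 2 on
conversion). Score a donor/patient cohort for butyrate producers and test
association with response:

```bash
$ fmtselect score-taxa --table coh.genus.tsv --metadata coh.metadata.tsv --out scores.tsv
panel=butyrate_producers n={'response': 17, 'no_response': 23} \
  means={'response': 0.446219, 'no_response': 0.429386} t=0.34352 p=0.733101
```

Here the cohort was generated under the null (`panel_effect: 0`), and the
t-test correctly finds nothing (p = 0.73). Finally, the power simulation on
a strong-effect synthetic dataset (10 planted genera, log-scale shift 2):

```bash
$ echo '{"n_fmt": [30, 100, 200], "response_rate": [0.5], "n_reps": 20, "seed": 11}' > grid.json
$ fmtselect simulate-power --table cc.genus.tsv --labels cc.labels.tsv --grid grid.json --out power.tsv
 n_fmt  response_rate  n_reps  mean_recovered  q25_recovered  median_recovered  q75_recovered
    30            0.5      20            1.25            0.0               1.0            2.0
   100            0.5      20            9.45            9.0               9.5           10.0
   200            0.5      20           10.00           10.0              10.0           10.0
```

A 30-patient FMT arm recovers on average 1.25 of the 10 top hits even for
this large an effect; 100+ patients are needed before retrospective
discovery becomes reliable — the quantitative case for powering trials (or
meta-analyses) explicitly for taxon discovery.

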