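# groomnet

Long-term behavioral monitoring of captive primate groups produces large
instantaneous scan-sampling datasets: at fixed timepoints (here every 2
minutes within 20-minute sessions) an observer records the current behavior
of every individual present, plus the partner and direction of social
interactions. `groomnet` turns such long-format scan records into
co-presence-corrected weighted directed grooming networks, per-individual
welfare and sociality indices, and a repeated-measures mixed-model analysis
of how group composition, seasonality and biographic background shape
behavior. It is written for researchers in animal welfare science and
social network analysis who follow a group through changes in its
composition — the bundled study design is a sanctuary chimpanzee group that
went from five males, to a mixed-sex group of seven, to a mixed-sex group
of five, observed across cold and warm seasons (six strata in total).

Because raw observational data of this kind is rarely public, the package
includes a first-class synthetic generator that emulates the sampling
protocol with known ground truth (per-individual behavior-class
probabilities, partner-preference vectors and injected covariate effects),
so every statistical property of the pipeline can be tested by parameter
recovery.

## The measures

For individuals $i, j$ within one stratum (phase × season):

* **Dyadic grooming rate** — $w_{ij} = 100 \cdot c_{ij} / p_{ij}$, where
  $c_{ij}$ counts scans at which $i$ groomed $j$ and $p_{ij}$ counts scans
  at which both were present. Dividing by co-presence rather than total
  scans corrects for absences (veterinary care etc.). Dyads that were
  never co-present are *missing*, not zero.
* **Vertex strength centrality** — $\mathrm{VSC}_i = s_i/(n-1)$ with
  $s_i = \sum_j w_{ij}$: the mean percentage of co-present scans spent
  grooming each potential partner, comparable across group sizes $n$.
* **Edge weight disparity** — $H_i = \sum_j (w_{ij}/s_i)^2$, ranging from
  $1/(n-1)$ (perfectly even grooming) to 1 (single partner); undefined for
  non-groomers.
* **DEWD** — $H_i - 1/(n-1)$, the deviation from the even-distribution
  floor, comparable across group sizes.
* **General activity index** — $\mathrm{GAI} = (A - I)/(A + I)$ over
  active and inactive scan counts, in $[-1, 1]$.
* **Undesired-behavior proportion** — scans of abnormal plus self-directed
  behaviors over all scans, in $[0, 1]$.

Each index is computed per individual per stratum (34 rows for the bundled
design) and modeled with a Gaussian linear mixed model: five binary fixed
factors — group size (5 vs 7), sex ratio (all-male vs mixed-sex),
seasonality (cold vs warm), sex (M vs F), origin (wild-caught vs
captive-born) — plus a per-individual random intercept. The model stage
reports REML coefficients, per-factor Wald F tests with Satterthwaite
denominator degrees of freedom (validated against lme4 + lmerTest), a
full-vs-null ML likelihood-ratio test, Bonferroni-adjusted level
contrasts, Cohen's d, variance inflation factors and a normal-QQ residual
diagnostic.

## Worked example

```python
import groomnet as gn

cfg = gn.default_sim_config(seed=42, sessions_per_stratum=60)
scans, truth = gn.generate_scans(cfg)          # 19420 records
table = gn.assign_strata(scans, cfg.phases, cfg.season_rule)
nets = gn.build_networks(table, cfg.catalog, cfg.phases, cfg.roster)
net = nets[("phase2", "cold")]                 # n=7, 42 defined edges
print(net.weight("BON", "JUA"))                # 2.59  (% of co-present scans)

idx = gn.build_index_table(table, nets, cfg.phases, cfg.roster, cfg.catalog)
print(gn.fit_lmm(idx, gn.ModelSpec("gai")).summary_text())
```

```
response: gai  (n = 34, 0 rows dropped, method = REML)
  full vs null: chi2(5) = 86.05, p = 4.542e-17
  variance components: individual = 0.0006901, residual = 0.001382
  group_size: F(1,24.8) = 0.82, p = 0.3744, d = -0.11
  sex_ratio: F(1,24.9) = 4.68, p = 0.04034, d = 0.16
  seasonality: F(1,24.0) = 181.76, p = 1.073e-12, d = 1.03
  sex: F(1,5.0) = 3.64, p = 0.1148, d = -0.34
  origin: F(1,4.5) = 183.91, p = 7.809e-05, d = -3.52
  QQ normality correlation: 0.9896
```

The generator's defaults inject a positive cold-season activity shift and
a strong negative wild-caught effect; the fit recovers both (seasonality
and origin significant with the right signs, d = 1.03 and d = −3.52),
while group size — for which no activity effect was injected — stays at
chance. Between-subject factors (sex, origin) get few denominator df
because only seven individuals carry them; within-subject factors are
tested against ~24–28 df.

The same analysis runs from the shell, stage by stage or end to end:

```sh
groomnet run --config cfg.yaml --seed 42 --out results/
# or: groomnet simulate|validate|networks|indices|fit|report ...
```

which writes the scan CSV, a validation report, six per-stratum networks
(edge-list CSV + GraphML), the index table, four model reports and
confidence-interval plots for significant factors.

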