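# pollinet

Quantitative plant–pollinator network analysis under two interaction-strength
currencies: **encounter-based** strength (the field standard — how often a
pollinator lands on a plant, corrected for sampling effort and flower
abundance) and **visit-based** strength (the same, multiplied by how many
flowers the pollinator actually works per landing). Because the number of
flowers visited per encounter varies strongly across pollinator groups and
increases with a plant's floral display, the two currencies can paint
different pictures of the same community. `pollinet` builds both networks
from raw survey records and quantifies how species roles and network
structure shift between them — for pollination ecologists comparing
measurement protocols, and for anyone analysing weighted bipartite networks.

## The model

From weekly survey records, the encounter-based strength of plant *i* with
pollinator *j* is

```
a_ij = Σ_w  (E_ijw / F_iw) · D_iw
```

where `E_ijw` is the number of encounters in week *w*, `F_iw` the open
flowers surveyed on the observed individuals of *i* that week, and `D_iw`
the plot-level flower abundance of *i* (flowers/m²). The visit-based
strength multiplies each link by its mean flowers visited per encounter,
`a_ij' = a_ij · v_ij`, where `v_ij` comes from timed (4-minute) pollinator
follows, with a fixed imputation hierarchy for unobserved links: own follows
→ donor value from a functionally similar pollinator on the same plant →
expert default → exclusion from all analyses.

On either matrix, with dependences `d_ij = a_ij / A_i` (row-wise) and
`d_ji = a_ij / A_j` (column-wise):

- **species strength** `S_i = Σ_j d_ji` — summed partner dependence on *i*;
- **push–pull index** `PP_i = (1/k_i) Σ_j (d_ji − d_ij)` — mean dependence
  asymmetry over the `k_i` partners (positive: "pusher");
- **d′** — standardized Kullback–Leibler specialization of a species'
  partner use against partner availability `q_j = A_j / m`;
- **weighted NODF** — nestedness from decreasing-fill row/column pairs;
- **H2′** — network-level standardized two-dimensional Shannon entropy;
- **interaction evenness** `IE = −Σ p_ij ln p_ij / ln(RC)`;
- **generality** — marginal-weighted mean exponential-entropy (effective)
  partner number per trophic level.

The comparison stage regresses visit-based on encounter-based descriptors
(slope ≈ 1 with high R² ⇒ robust to the currency), relates each plant's
ratio of change to its floral display, and bootstrap-subsamples the raw
encounter pool (25/50/75%, paired *t*-tests) to show the descriptor shifts
are not sampling artifacts. A synthetic survey generator (log-normal floral
displays, log–log display–visits relation, heavy-tailed preferences, weekly
phenology, overdispersed counts) makes every stage testable without field
data.

## Worked example

```python
import pollinet as pn
from pollinet.datasets import load_scrubland_plant_summary

# do plants with larger floral displays receive more visits per encounter?
table = load_scrubland_plant_summary()          # bundled 19-plant field summary
res = pn.fit_regression(table["floral_display"],
                        table["mean_visits_per_encounter"],
                        transform_x="log", transform_y="log")
print(f"F(1,{res.df[1]}) = {res.f_stat:.1f}, p = {res.p_value:.4f}, "
      f"adj R2 = {res.r2_adj:.2f}, slope = {res.slope:.2f}")

# a synthetic season, both networks, all five network descriptors
scenario = pn.generate_scenario(pn.ScenarioConfig(seed=3))
enc, vis, est = pn.build_networks(scenario.encounters,
                                  scenario.flower_surveys,
                                  scenario.visit_samples)
for net in (enc, vis):
    d = pn.network_descriptors(net)
    print(f"{net.measure:>9}: wNODF={d.wnodf:.2f}  H2'={d.h2_prime:.2f}  "
          f"IE={d.interaction_evenness:.2f}  G_plant={d.plant_generality:.2f}  "
          f"G_poll={d.pollinator_generality:.2f}")
```

prints

```
F(1,17) = 18.0, p = 0.0005, adj R2 = 0.49, slope = 0.28
encounter: wNODF=9.29  H2'=0.65  IE=0.46  G_plant=3.59  G_poll=2.47
    visit: wNODF=9.35  H2'=0.75  IE=0.40  G_plant=3.41  G_poll=1.88
```

The regression says visits per encounter rise with floral display (slope
0.28 on the log–log scale, explaining about half the interspecific
variance). In the simulated community, switching to the visit-based currency
leaves nestedness nearly unchanged but lowers interaction evenness and
pollinator generality — strength concentrates on the links of
many-flowered plants, the same qualitative behavior the descriptors show on
field data.

The same workflow is available from the shell:

```sh
pollinet simulate --seed 3 --out-dir survey
pollinet build-networks --encounters survey/encounters.csv \
    --flowers survey/flowers.csv --visits survey/visits.csv --out-prefix nets
pollinet network-metrics --network nets_encounter.csv --out metrics.csv
pollinet compare --encounters survey/encounters.csv --flowers survey/flowers.csv \
    --visits survey/visits.csv --traits survey/traits.csv \
    --reps 100 --seed 5 --out-dir comparison
```

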