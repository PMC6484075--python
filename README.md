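# disturbnet

Tools for asking how a microbial community responds to a **press
disturbance** — a sustained perturbation such as the multi-day temperature
drop applied to a mesophilic anaerobic digester. Given a taxon × time
relative-abundance table and a declaration of which samples fall before,
during, and after the disturbance, the package

1. **classifies every taxon** by abundance level (HA > 1% mean share, LA
   0.1–1%, RA below), presence (Core = detected in every sample vs Ncore),
   abundance-pattern stability (BS/BV/NC from an F test of before- vs
   after-window variances plus a coefficient-of-variation comparison), and
   disturbance response (induced/repressed when the during-window mean sits
   strictly above/below both flanking windows);
2. computes **community statistics** — Shannon diversity, richness,
   archaeal share, sample PCA, and a variance-test-then-one-tailed-t
   comparison of any metric across the disturbance;
3. infers a **signed, directed interaction network** for the before and
   after windows with an ensemble generalized Lotka–Volterra (gLV)
   regression: under the discrete map
   `x_{i,k+1} = x_{i,k}·exp(Δt(r_i + Σ_j a_ij x_{j,k}))` the log-ratio of
   consecutive abundances is linear in the community state; 1,000
   replicates each fit a random 90% of members, a pair is kept when one
   sign wins more than 90% of the replicates containing it, and only the
   strongest 10% of those reliable pairs enter the final network;
4. compares the two networks **topologically** (in-degree, betweenness,
   per-taxon niche labels, metabolic-pathway overlay).

A first-class synthetic-data module generates every input with known
ground truth: stochastic gLV disturbance time series (latent, observed
absolute, and closed relative tables) and classification fixtures with
prescribed labels. The target audience is microbial ecologists and
bioinformaticians working with 16S time series from engineered or natural
ecosystems.

## Worked example

Simulate the default disturbance scenario (15 members, 12/3/15 design,
weekly sampling) and run the full chain:

```python
import disturbnet as dn

scenario = dn.default_scenario(seed=7)
result = dn.simulate_glv(scenario)

labels = dn.classify_all(result.table, result.design)
print(labels.head(3).to_string(index=False))
```

```
  taxon abundance_class presence_class stability_class  response  present_mean  mean_all  cv_before  cv_after  f_test_p flags
taxon01              HA           Core              NC   induced      0.081265  0.081265   0.557643  0.465627  0.258259
taxon02              HA           Core              NC repressed      0.060717  0.060717   0.377035  0.370454  0.488596
taxon03              HA           Core              NC   induced      0.099370  0.099370   0.386062  0.507558  0.589668
```

Every taxon here is Core (present in all 30 samples) and HA (mean share
above 1% — the default community has 15 members, so shares are large);
`taxon01` is *induced*: its present-mean during the disturbance exceeds
both flanking windows. The `f_test_p` column is the two-sided variance
test whose rejection would split taxa into BS/BV.

```python
before = dn.infer_network(result.table, result.design, "before", seed=7)
after = dn.infer_network(result.table, result.design, "after", seed=7)
print("before:", before.number_of_edges(), "edges;",
      "after:", after.number_of_edges(), "edges")
print(dn.compare_networks(before, after).head(3).to_string(index=False))
```

```
before: 16 edges; after: 14 edges
  taxon  in_degree_a  in_degree_b niche
taxon01          0.0          1.0     B
taxon02          2.0          0.0     A
taxon03          3.0          2.0     A
```

`taxon02` received interactions only in the pre-disturbance network
(niche label A); `taxon01` gained influence afterwards (B). A `star`
would mark equal positive in-degree in both networks.

The same chain is available from a shell:

```sh
disturbnet simulate --out sim --seed 7
disturbnet run --table sim/table.tsv --design sim/design.yaml \
    --out results --seed 7
```

which writes `classification.tsv`, edge CSVs and GraphML for both
networks, per-sample summaries, PCA scores, niche labels, and a manifest
recording the configuration hash, seed and library versions. Runs with
the same seed are byte-identical.

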