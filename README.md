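# aggsdm — species aggregation distribution modelling

Pelagic predator surveys are zero-inflated and heavy-tailed: most
transect bins hold nothing, and a few hold enormous foraging flocks.
Abundance models fit to such data produce realistic spatial patterns but
unrealistic amplitudes, and miss the thing managers often care about —
where and when the *aggregations* occur. `aggsdm` is a pipeline for
modelling aggregation occurrence on gridded survey data, built for
spatial ecologists working with at-sea strip-transect counts (seabirds
being the motivating case) and daily gridded ocean-model covariates.

The core model is a two-stage binomial hurdle of boosted regression
trees. Per species, a count on the 0.1° analysis grid is labeled an
aggregation when it reaches the 90th percentile of that species'
positive counts; presence/absence and aggregation/non-aggregation are
then modelled separately and combined multiplicatively:

    Pr(Agg) = Pr(1) × Pr(Agg | 1)

Each stage is a 50-member ensemble (tree depth 3, learning rates
0.01/0.005, bag fraction 0.6, independent 75/25 splits) evaluated by
held-out AUC and TSS, including leave-one-year-out comparisons. Daily
hindcast fields are averaged into April–June monthly maps and condensed
into two interannual indices: the leading principal component of an EOF
decomposition of the year × cell anomaly matrix, and a hotspot-area
index (count of cells above the pooled climatological mean + 2 SD,
normalized). The indices are evaluated against independently observed
monthly SST and sea-level-anomaly fields via Spearman coherence and
lagged (January→May) per-cell correlation maps with p < 0.05 contours.

A synthetic seascape generator — spatially autocorrelated daily fields
sharing an interannual warm/cool mode, seeded survey effort, and
zero-inflated heavy-tailed counts whose upper-tail probability responds
to the warm mode with a controllable sign — makes every stage testable
against known ground truth at desk scale. See `docs/methods.md` for the
full model description and design choices.

## Worked example

A miniature end-to-end run (10×10 grid, six survey years of which one
fails the 50-record filter, two species with opposite warm-mode
responses) takes a few seconds:

```sh
aggsdm make-fixture --seed 2 --out cfg.yaml
aggsdm simulate --config cfg.yaml --out run
aggsdm process  --config cfg.yaml --dir run
aggsdm fit      --config cfg.yaml --dir run
aggsdm predict  --config cfg.yaml --dir run
aggsdm indices  --config cfg.yaml --dir run
aggsdm evaluate --config cfg.yaml --dir run
```

which prints

```
labeled 1320 records; cutoffs: resident=147.6, migrant=170.3
resident: presence AUC 0.756, aggregation AUC 0.781
migrant: presence AUC 0.801, aggregation AUC 0.588
resident: index agreement rho=0.493
migrant: index agreement rho=0.928
resident: rho_sst=0.486 (p=0.356), rho_sla=0.486 (p=0.356)
migrant: rho_sst=-0.257 (p=0.658), rho_sla=-0.257 (p=0.658)
```

Reading the numbers: the per-species cutoffs are the 90th percentiles of
gridded positive counts — a count of 147.6+ birds in one cell-day is an
aggregation for the "resident" species. The AUCs are held-out means over
ensemble members for each hurdle stage. The agreement rho compares the
EOF-PC1 and hotspot-area indices computed from the May prediction maps,
and rho_sst / rho_sla are their Spearman coherences with the PC1 of the
observed May SST and SLA fields. At fixture scale only five usable years
remain, so coherence p-values (exact permutation at this n) are
expectedly insignificant; the same experiment at 16 years is where the
inference pattern resolves — e.g.

```python
>>> from aggsdm.experiments import sign_recovery_run
>>> r = sign_recovery_run(seed=11, agg_forcing=+1.2)
>>> round(r.rho, 3), float(f"{r.p:.1e}")
(0.926, 2.6e-07)
```

a species whose aggregation probability rises in warm years yields a
strongly positive, significant coherence between its aggregation index
and the SST PC1 — and flipping the forcing sign flips the correlation.

`aggsdm run-all --config cfg.yaml --out run/` executes all stages at
once and writes a manifest with per-stage seeds and artifact checksums;
identical configs reproduce byte-identical artifacts.

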