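population: 87640000
reference_year: 2010
n_sims: 10000
seed: 20100101
top_k_chains: 4
inputs:
  registry: registry.csv
  metrics_table: burden_metrics.csv
  rankings: group_rankings.csv
  plenary_votes: plenary_votes.csv
  attributed_deaths: attributed_deaths_synthetic.csv
  chains: chains.yaml
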