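# Replication profile: every default pinned explicitly. Regenerates the
# packaged study's transition, spatial-transition and limiting tables with
#   effimarkov run --config examples/replication.yaml --out results/
input_mode: packaged_panel
breaks_pool: per_year        # each year's cross-section gets its own breaks
lag_classification: refit    # lag values classified by their own per-year breaks
k_states: 4
kde_years: [2011, 2013, 2015, 2017, 2019]
kde_regions: [all, central, western]
kde_c: null                  # Silverman robust rule 0.9*min(sd, IQR/1.34)
peak_prominence: 0.05
tol: 1.0e-12
max_iter: 1000000
dea:                         # used only in indicator_csv mode
  returns_to_scale: vrs
  frontier_pool: per_year
  epsilon: 1.0e-06
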