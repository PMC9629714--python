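# Demo pipeline configuration: a small synthetic fleet that runs end-to-end
# in a few minutes on one CPU.  Field names mirror PipelineConfig /
# WorldConfig / FleetConfig exactly.
out_dir: darkgaps_demo
seed: 0
n_vessels: 30
days: 60

# gap filters and rule model (published defaults)
min_gap_h: 12.0
min_shore_nmi: 50.0
min_reception: 10.0
rule_lookback_h: 12
rule_k: 14
select_model: true      # pick the rule by F0.5 CV instead of the fixed rule

# allocation
cap_h: 336.0
max_speed_knots: 10.0

# driver model
brt_iterations: 50
brt_train_frac: 0.75

world:
  west: -40.0
  south: -30.0
  east: -20.0
  north: -10.0
  cell_size_deg: 0.25
  reception_background: 35.0
  reception_bumps:
    - {lon: -26.0, lat: -24.0, amplitude: -34.0, sigma_deg: 3.5}
    - {lon: -33.0, lat: -14.0, amplitude: 8.0, sigma_deg: 3.0}
  shore: west_edge

fleet:
  n_vessels: 30
  gear_mix: {drifting_longlines: 0.30, squid_jigger: 0.20,
             tuna_purse_seine: 0.20, trawler: 0.20, other: 0.10}
  flag_mix: {CHN: 0.35, TWN: 0.20, ESP: 0.15, USA: 0.15, KOR: 0.15}
  device_class_mix: {A: 0.7, B: 0.3}
  base_ping_rate: {A: 100.0, B: 13.0}
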