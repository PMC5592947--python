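# Two-population split-with-growth scenario (AF = 0, EU = 1).
# Ancestral population at mutation-selection equilibrium (N_ref = 10,000)
# doubles instantly, splits after 100 generations through a 0.05 N_ref
# bottleneck, then the derived population grows exponentially to 5 N_ref
# over 900 generations, with weak symmetric migration and weakly
# deleterious codominant selection (2 N_ref s = -4).
run:
  num_sites: 2.0e9
  num_generations: 1000
  compact_interval: 10
  seed: 1
  initial_state: equilibrium
populations:
  - name: AF
    epochs:
      - {start: 0, end: 0, size: 10000}
      - {start: 1, end: 1000, size: 20000}
  - name: EU
    founded: {generation: 101, source: 0}
    epochs:
      - {start: 101, end: 1000, size_from: 500, size_to: 50000}
mutation:
  rate: 1.0e-9
selection:
  s: -0.0002
  h: 0.5
migration:
  - {source: 0, target: 1, rate: 5.0e-5, start: 101}
  - {source: 1, target: 0, rate: 5.0e-5, start: 101}
sampling:
  - {population: 1, n: 1001}
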