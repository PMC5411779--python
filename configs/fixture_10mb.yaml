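# Bundled 10-Mb evaluation fixture: four 2.5-Mb chromosomes, ~50k read
# pairs (depth 1.5 at 2x150), the full curation-event suite, 40 candidate
# sites.  Deterministic given the seed.
seed: 1
outdir: scratch/fixture_10mb
simulate:
  n_chromosomes: 4
  chromosome_length: 2500000
  segdup_count: 4
  segdup_length: 20000
  satellite_copy_count: 100
  depth: 1.5
  novel_length: 20000
  n_candidate_sites: 40
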