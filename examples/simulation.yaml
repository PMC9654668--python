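# Desk-scale synthetic study: three groups mirroring an exposed-unaffected
# control group and two disease groups, with a x3 variant-rate inflation
# planted in three MPM pathways and one shared with LC.
# Pathway ids refer to the database generated under seed 11.
seed: 11
n_pathways: 200
genes_per_pathway: [10, 40]
gene_pool: 2000
background_total: 20000
core_share: 0.4
private_rate: 300.0
quality_fail_rate: 0.02
ffpe_rate: 0.10
groups:
  - label: CTRL
    n_members: 5
  - label: LC
    n_members: 7
    planted:
      R-SIM-000004: 3.0
  - label: MPM
    n_members: 7
    planted:
      R-SIM-000001: 3.0
      R-SIM-000003: 3.0
      R-SIM-000004: 3.0
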