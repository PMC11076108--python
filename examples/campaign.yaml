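# Example campaign: the three synthetic venation classes, both attack kinds,
# at the standard experiment scale.  Run with:
#   venation campaign --config examples/campaign.yaml --out-dir campaign-out
n_attacks: 250
n_bins: 20
hole_range: [0, 2000]
hole_area_px: 60
master_seed: 1
make_plots: true
out_dir: campaign-out
leaves:
  - taxon: synthetic-branched
    venation_class: branched
    synthetic: {seed: 1}
  - taxon: synthetic-net
    venation_class: net
    synthetic: {seed: 1}
  - taxon: synthetic-hierarchical
    venation_class: hierarchical
    synthetic: {seed: 1}
# Image pairs load equivalently, e.g.:
#  - taxon: Linopteris subbrongniartii
#    venation_class: net
#    network_path: tracings/linopteris_network.gif
#    structural_path: tracings/linopteris_structural.gif
#    foreground: dark
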