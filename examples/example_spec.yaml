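n_nodes: 60
n_communities: 5
size_min: 6
size_max: 12
overlap_mode: disjoint
physical_edge_target: 160
conceptual_edge_target: 200
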