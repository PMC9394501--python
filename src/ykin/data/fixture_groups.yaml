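# Composite and paragroup definitions for the fixture phylogeny.
#
# A composite unions the atomic assignments of its member nodes (deep-node
# grouping to recover power for rare lineages). A paragroup (asterisk suffix)
# is the subtree of an ancestor minus the subtrees of its enumerated derived
# groups.
composites:
  IJK-S137:
    members: [IJ-M429, I-M170, I1-M253, I2-M438, J-M304, J1-M267, J2-M172,
              K-M9, P-M45, R1a-M420, R1b-M343, R1b1-L21, R1b2-U106]
  R-M207:
    members: [R1a-M420, R1b-M343, R1b1-L21, R1b2-U106]
paragroups:
  R1b-M343*:
    ancestor: R1b-M343
    exclude: [R1b1-L21, R1b2-U106]
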