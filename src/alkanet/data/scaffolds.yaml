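# Default alkaloid scaffold queries: the five cores mapped by the pipeline.
# Inclusion/exclusion patterns are package-authored SMILES for these scaffold
# classes; swap this file out to use your own query set.
#
# Exclusions veto structures the loose inclusion pattern also catches but
# that belong to a different class (e.g. quinolizidine/indolizidine alkaloids
# contain a piperidine ring; aporphines contain the benzylisoquinoline core).
scaffolds:
  - name: benzylisoquinoline
    inclusion: "C(c1ccccc1)C1NCCc2ccccc21"          # 1-benzyl-tetrahydroisoquinoline
    exclusions:
      - "N1CCc2cccc3c2C1Cc1ccccc1-3"                # aporphine tetracycle (counted separately)
      - "C1Cc2ccccc2CN2CCc3ccccc3C12"               # protoberberine tetracycle
    blocklist: []
  - name: aporphine
    inclusion: "N1CCc2cccc3c2C1Cc1ccccc1-3"          # 4H-dibenzo[de,g]quinoline core
    exclusions:
      - "c1ccc2ccc3ccccc3c2c1"                      # fully aromatic phenanthrenoids
    blocklist: []
  - name: piperolactam
    inclusion: "O=C1Nc2cccc3cc4ccccc4c1c23"          # phenanthrene-fused gamma-lactam (aristolactam skeleton)
    exclusions:
      - "O=[N+]([O-])c1ccc2ccccc2c1"                # aristolochic-acid-type nitroarenes
    blocklist: []
  - name: piperidine
    inclusion: "C1CCNCC1"
    exclusions:
      - "C1CCN2CCCCC2C1"                            # quinolizidine (lupin alkaloids)
      - "C1CCN2CCCC2C1"                             # indolizidine
    blocklist:
      - species: "Capsicum*"
        compound: "piperine"
        reason: "known database error (piperine misattributed to Capsicum)"
      - species: "Centaurea aegyptica"
        compound: "*"
        reason: "no NMR data in original report"
      - species: "Aglaia perviridis"
        compound: "*"
        reason: "no NMR data in original report"
  - name: seco-benzylisoquinoline
    inclusion: "NCCc1ccccc1C(=O)Cc1ccccc1"           # ring-opened (1,2-seco) benzylisoquinoline
    exclusions:
      - "O=C(/C=C/c1ccccc1)c1ccccc1"                # chalcones
    blocklist: []
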