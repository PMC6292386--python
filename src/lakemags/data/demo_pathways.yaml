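# Demonstration pathway catalog (synthetic).
#
# A small, hand-curated set of freshwater-relevant pathways in the catalog
# schema: each pathway lists enzymatic steps, each step the namespaced
# annotation ids (KEGG ortholog / COG / PFAM / TIGRFAM) accepted as evidence
# for it, and whether the step is unique (diagnostic) for the pathway.
# Annotation ids are illustrative stand-ins, not a curated KEGG/MetaCyc
# mapping; ids are disjoint across pathways so planted-truth simulations are
# unambiguous. The nitrogenase TIGRFAMs (TIGR1282 nifD, TIGR1286 nifK,
# TIGR1287 nifH) are the standard Mo-Fe nitrogenase subunit families.
- pathway_id: nitrogen_fixation
  steps:
    - step_id: nifH
      annotation_ids: [TIGR:TIGR1287, KO:K02588]
      unique: true
    - step_id: nifD
      annotation_ids: [TIGR:TIGR1282, KO:K02586]
      unique: true
    - step_id: nifK
      annotation_ids: [TIGR:TIGR1286, KO:K02591]
      unique: true
    - step_id: nifB
      annotation_ids: [KO:K02585]
      unique: false
    - step_id: nifE
      annotation_ids: [KO:K02587]
      unique: false
- pathway_id: polyamine_biosynthesis
  steps:
    - step_id: speA
      annotation_ids: [KO:K01585, COG:COG1166]
      unique: false
    - step_id: speB
      annotation_ids: [KO:K01480]
      unique: false
    - step_id: speC
      annotation_ids: [KO:K01581]
      unique: false
    - step_id: speE
      annotation_ids: [KO:K00797, PFAM:PF02440]
      unique: true
- pathway_id: polyamine_degradation
  steps:
    - step_id: puuA
      annotation_ids: [KO:K09470]
      unique: false
    - step_id: puuB
      annotation_ids: [KO:K09471]
      unique: false
    - step_id: puuC
      annotation_ids: [KO:K09472]
      unique: false
    - step_id: puuD
      annotation_ids: [KO:K09473, COG:COG2351]
      unique: false
- pathway_id: assimilatory_sulfate_reduction
  steps:
    - step_id: sat
      annotation_ids: [KO:K00958]
      unique: false
    - step_id: cysC
      annotation_ids: [KO:K00860]
      unique: false
    - step_id: cysH
      annotation_ids: [KO:K00390, TIGR:TIGR00434]
      unique: true
    - step_id: cysJI
      annotation_ids: [KO:K00380]
      unique: false
- pathway_id: dissimilatory_sulfate_reduction
  steps:
    - step_id: dsrA
      annotation_ids: [TIGR:TIGR02064]
      unique: true
    - step_id: dsrB
      annotation_ids: [TIGR:TIGR02066]
      unique: true
    - step_id: aprA
      annotation_ids: [KO:K00394]
      unique: false
    - step_id: aprB
      annotation_ids: [KO:K00395]
      unique: false
- pathway_id: cbb_carbon_fixation
  steps:
    - step_id: rbcL
      annotation_ids: [KO:K01601, PFAM:PF00016]
      unique: true
    - step_id: rbcS
      annotation_ids: [KO:K01602]
      unique: false
    - step_id: prkB
      annotation_ids: [KO:K00855]
      unique: true
    - step_id: tktA
      annotation_ids: [KO:K00615]
      unique: false
- pathway_id: reductive_tca
  steps:
    - step_id: aclA
      annotation_ids: [KO:K15230]
      unique: true
    - step_id: aclB
      annotation_ids: [KO:K15231]
      unique: true
    - step_id: korA
      annotation_ids: [KO:K00174]
      unique: false
    - step_id: frdA
      annotation_ids: [KO:K00244]
      unique: false
- pathway_id: mannose_degradation
  steps:
    - step_id: manP
      annotation_ids: [KO:K02793]
      unique: false
    - step_id: manA
      annotation_ids: [KO:K01809, COG:COG1482]
      unique: true
    - step_id: manB
      annotation_ids: [KO:K16011]
      unique: false
- pathway_id: xylose_degradation
  steps:
    - step_id: xylA
      annotation_ids: [KO:K01805]
      unique: true
    - step_id: xylB
      annotation_ids: [KO:K00854]
      unique: false
    - step_id: xylT
      annotation_ids: [COG:COG4213]
      unique: false
- pathway_id: aerobic_anoxygenic_phototrophy
  steps:
    - step_id: pufL
      annotation_ids: [TIGR:TIGR01157]
      unique: true
    - step_id: pufM
      annotation_ids: [TIGR:TIGR01115]
      unique: true
    - step_id: puhA
      annotation_ids: [PFAM:PF03967]
      unique: false
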