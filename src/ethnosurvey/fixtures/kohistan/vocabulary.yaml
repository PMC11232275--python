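# Controlled vocabulary for the Kohistan survey transcription.
#
# groups:     short language tags used in local-name and group columns
# synonyms:   free-text abbreviations -> canonical controlled terms
# categories: ICPC-2-style disease categories with the ailment terms mapped
#             to each (one term belongs to at most one category)

groups:
  K: Kohistani
  S: Shina
  B: Bateri
  P: Pushto
  G: Gujjari

synonyms:
  ap: aerial part
  aerial parts: aerial part
  lvs: leaves
  leaf: leaves
  rt: roots
  root: roots
  stm: stem
  fl: flower
  flowers: flower
  fr: fruit
  fruits: fruit
  sd: seed
  seeds: seed
  brk: bark
  rn: resin
  rnd: rind
  milk: milk/latex
  latex: milk/latex
  br: branches
  fresh: fresh part
  fresh leaves: fresh part
  fresh parts: fresh part
  orally: oral
  smoke: inhalation/smoke
  inhalation: inhalation/smoke
  flue: flu

categories:
  OTHA-A:
    description: General and unspecified
    terms:
      - fever
      - typhoid fever
      - allergy
      - sickness
      - smallpox
      - back pain
      - spiritual uses
  GAS-D:
    description: Digestive problems
    terms:
      - constipation
      - toothache
      - intestinal worms
      - ringworms
      - abdominal worms
      - worm killer
      - diarrhea
      - dysentery
      - jaundice
      - hepatitis
      - indigestion
      - weakness
      - body weakness
      - stomach pain
      - stomach disorder
      - stomach problem
      - abdominal pain
      - mouth gums
      - clean teeth
      - strengthen teeth
      - liver disorder
      - appetizer
      - intestinal wounds
      - internal wounds
      - intestinal ulcers
      - obesity
      - vomiting
  CAR-K:
    description: Cardiovascular diseases
    terms:
      - blood pressure
      - blood purifier
  Blood-B:
    description: Blood, blood-forming organs, and immune mechanism
    terms:
      - blood clots
      - bleeding injuries
      - internal injuries
      - stop bleeding
  SKE-L:
    description: Musculoskeletal disorders
    terms:
      - joint swelling
      - strengthen bones
      - backache
  NER-N:
    description: Neurological problems
    terms:
      - paralysis
  RES-R:
    description: Respiratory disorders
    terms:
      - flu
      - cough
      - corona symptoms
      - corona infection
      - chest infection
      - chest pain
      - asthma
      - common cold
      - bronchitis
      - throat infection
      - influenza
  DER-S:
    description: Skin diseases
    terms:
      - wound healing
      - wounds
      - external wounds
      - injuries
      - skin infection
      - eczema
      - skin rashes
      - dandruff
      - warts
      - face stains
      - mole removal
      - fungal infection
      - bacterial infection
      - anti-hair fall
  URO-U:
    description: Urological disorders
    terms:
      - urinary disorder
      - bladder infection
      - kidney inflammation
      - urinary tract infection
      - urinary bladder inflammation
  CAN-C:
    description: Cancer
    terms:
      - tumors
  PRE-W:
    description: Pregnancy, childbearing, family planning
    terms:
      - labor pain
  OTH:
    description: Others
    terms:
      - anti-rodents
      - mosquito repellent
      - pest repellent
      - fungus killer
      - poultry ailments
      - livestock diseases
      - antimicrobial
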