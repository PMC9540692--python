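# Default product-name catalog for the 15 quorum-sensing signal families.
#
# Matching is case-insensitive and whole-word (hyphen and underscore count as
# word boundaries).  This shipped catalog is a reconstruction from the gene
# names discussed in the screening literature; replace it with a full
# curated keyword table (same layout) for production runs.
families:
  AHL:
    - role: synthase
      keywords:
        - "N-acyl homoserine lactone synthase"
        - "acyl-homoserine-lactone synthase"
        - "autoinducer synthesis protein"
    - role: degradation
      keywords:
        - "N-acyl homoserine lactonase"
        - "acyl-homoserine lactone acylase"
    - role: regulator
      keywords:
        - "N-acyl homoserine lactone-responsive regulator"
  AIP:
    - role: regulator
      keywords: ["AgrA", "accessory gene regulator A"]
    - role: synthase
      keywords: ["AgrB", "accessory gene regulator B", "AgrD"]
  AI-2:
    - role: synthase
      keywords:
        - "S-ribosylhomocysteine lyase"
        - "S-ribosylhomocysteine"
        - "S-ribosylhomocysteinase"
        - "LuxS"
    - role: receptor
      keywords:
        - "LsrB"
        - "autoinducer 2-binding protein"
        - "LuxP"
        - "autoinducer 2-binding periplasmic protein"
  AI-3:
    - role: regulator
      keywords: ["QseB", "quorum sensing regulator QseB"]
    - role: receptor
      keywords: ["QseC", "sensor kinase QseC"]
  CAI-1:
    - role: receptor
      keywords: ["CqsS", "autoinducer sensor kinase/phosphatase CqsS"]
  DSF/BDSF:
    - role: receptor
      keywords: ["RpfC", "sensor kinase RpfC"]
    - role: regulator
      keywords: ["RpfG", "response regulator RpfG"]
  indole:
    - role: synthase
      keywords: ["TnaA", "tryptophanase"]
    - role: receptor
      keywords: ["BaeS", "CpxA"]
    - role: regulator
      keywords: ["GadX"]
  DKP:
    - role: synthase
      keywords:
        - "dimodular nonribosomal peptide synthase"
        - "dimodular nonribosomal peptide synthetase"
  PQS/HHQ:
    - role: synthase
      keywords: ["PqsA", "anthranilate-CoA ligase PqsA"]
    - role: regulator
      keywords: ["PqsR", "MvfR"]
  IQS:
    - role: synthase
      keywords: ["AmbB", "AmbC", "AmbD", "AmbE"]
  PPY:
    - role: synthase
      keywords: ["PpyS", "photopyrone synthase"]
  DAR/CHD:
    - role: synthase
      keywords: ["DarA", "DarB", "dialkylresorcinol synthase"]
  CSP:
    - role: synthase
      keywords: ["ComC", "competence stimulating peptide"]
    - role: receptor
      keywords: ["ComD"]
    - role: regulator
      keywords: ["ComE"]
  DPO:
    - role: regulator
      keywords: ["VqmA"]
  3-OH-PAME/3-OH-MAME:
    - role: synthase
      keywords: ["PhcB"]
    - role: receptor
      keywords: ["PhcS"]
    - role: regulator
      keywords: ["PhcR"]
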