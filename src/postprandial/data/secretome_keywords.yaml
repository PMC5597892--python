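# Default keyword map for rule-based gastric-secretome categorisation.
# Matching is case-insensitive substring, applied per category in priority
# order: mucosal > proteolytic > other_hydrolytic > other.  A protein whose
# annotation matches a not_secreted keyword is excluded from the secretome
# before the category keywords are consulted.  The map is data, not code:
# edit or replace this file to change the manual-reassessment convention.
version: 1
categories:
  mucosal:
    - mucin
    - gastrokine
    - trefoil
    - mucosa
  proteolytic:
    - pepsin
    - pepsinogen
    - gastricsin
    - chymosin
    - peptidase
    - protease
  other_hydrolytic:
    - phospholipase
    - lipase
    - lysozyme
    - amylase
    - hydrolase
    - ribonuclease
  other:
    - intrinsic factor
    - secreted
    - gastric
not_secreted:
  - calpain
  - dehydrogenase
  - tubulin
  - histone
  - ribosomal
  - heat shock
  - chaperon
  - cytoskelet
  - cytoplasmic
  - intracellular
  - proteasome
  - membrane
  - receptor
  - atpase
  - kinase
  - elongation factor
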