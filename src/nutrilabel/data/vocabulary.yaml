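# Closed ingredient-marker vocabulary for the NOVA rule ladder.
#
# NOVA guidance describes ultra-processed products by the presence of
# additives and refined industrial ingredients; this file is the package's
# editorial operationalisation of that guidance as three disjoint tag sets.
# Edit or replace it to track a different NOVA reading: the ladder only
# cares about set membership, and every verdict logs this file's hash.
up_markers:
  - colouring
  - flavouring
  - emulsifier
  - thickener
  - stabiliser
  - preservative_cosmetic
  - non_caloric_sweetener
  - hydrogenated_oil
  - interesterified_oil
  - protein_isolate
  - maltodextrin
  - hfcs
  - invert_sugar
  - flavour_enhancer
processing_markers:
  - added_salt
  - added_sugar
  - added_oil
  - canned
  - bottled_brine
  - fermented
  - smoked
  - cured
culinary_substances:
  - vegetable_oil
  - olive_oil
  - butter
  - lard
  - table_sugar
  - salt
  - starch
  - honey
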