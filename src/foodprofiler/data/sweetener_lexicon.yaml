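# Default sweetener lexicon for ingredient-list screening.
# added_sugar_terms: ingredient names that indicate added (free) sugars.
# nss_terms: non-sugar sweeteners, by name and by EU additive code.
# negative_contexts: phrases removed from the text before matching, so
# that e.g. "no added sugar" or "sugar snap peas" never trigger a flag.
# All entries lowercase; matching is whole-token / phrase based.
added_sugar_terms:
  - sugar
  - brown sugar
  - cane sugar
  - raw sugar
  - icing sugar
  - coconut sugar
  - invert sugar
  - invert sugar syrup
  - sucrose
  - glucose
  - dextrose
  - fructose
  - maltose
  - glucose syrup
  - glucose-fructose syrup
  - corn syrup
  - high fructose corn syrup
  - rice syrup
  - golden syrup
  - maple syrup
  - agave syrup
  - agave nectar
  - honey
  - molasses
  - treacle
  - caramel syrup
  - fruit juice concentrate
nss_terms:
  - aspartame
  - acesulfame k
  - acesulfame potassium
  - sucralose
  - saccharin
  - sodium saccharin
  - cyclamate
  - sodium cyclamate
  - stevia
  - steviol glycosides
  - neotame
  - advantame
  - thaumatin
  - neohesperidine dc
  - sorbitol
  - mannitol
  - xylitol
  - erythritol
  - maltitol
  - isomalt
  - lactitol
  - e420
  - e421
  - e950
  - e951
  - e952
  - e953
  - e954
  - e955
  - e957
  - e959
  - e960
  - e961
  - e962
  - e964
  - e965
  - e966
  - e967
  - e968
  - e969
negative_contexts:
  - no added sugar
  - no added sugars
  - no sugar added
  - without added sugar
  - without added sugars
  - sugar free
  - sugar-free
  - unsweetened
  - sugar snap pea
  - sugar snap peas
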