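# Default study lexicon: transcribed reason phrase patterns -> trait group.
# Patterns are matched as normalized substrings, longest pattern first.
# The grouping of transcribed answers is interpretive, so this table is data:
# edit or replace it to re-run an analysis under a different grouping.
entries:
  # Body Size and Growth: live weight, body size, lamb and ewe growth rate
  - {pattern: "big body", trait_group: "Body Size and Growth"}
  - {pattern: "large body", trait_group: "Body Size and Growth"}
  - {pattern: "small body", trait_group: "Body Size and Growth"}
  - {pattern: "body size", trait_group: "Body Size and Growth"}
  - {pattern: "live weight", trait_group: "Body Size and Growth"}
  - {pattern: "heavy", trait_group: "Body Size and Growth"}
  - {pattern: "growth rate", trait_group: "Body Size and Growth"}
  - {pattern: "grows fast", trait_group: "Body Size and Growth"}
  - {pattern: "slow growth", trait_group: "Body Size and Growth"}
  - {pattern: "lamb growth", trait_group: "Body Size and Growth"}
  - {pattern: "tall frame", trait_group: "Body Size and Growth"}
  # Condition: body fat cover
  - {pattern: "fat cover", trait_group: "Condition"}
  - {pattern: "good condition", trait_group: "Condition"}
  - {pattern: "poor condition", trait_group: "Condition"}
  - {pattern: "body condition", trait_group: "Condition"}
  - {pattern: "well fleshed", trait_group: "Condition"}
  - {pattern: "thin", trait_group: "Condition"}
  - {pattern: "fat", trait_group: "Condition"}
  # Milk Production
  - {pattern: "much milk", trait_group: "Milk Production"}
  - {pattern: "little milk", trait_group: "Milk Production"}
  - {pattern: "milk yield", trait_group: "Milk Production"}
  - {pattern: "good milker", trait_group: "Milk Production"}
  - {pattern: "no milk", trait_group: "Milk Production"}
  - {pattern: "milk", trait_group: "Milk Production"}
  # Reproduction and Mothering Ability: twinning, lamb survival, fertility
  - {pattern: "twinning", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "twins", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "lamb survival", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "lambs survive", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "good mother", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "mothering ability", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "lambs every year", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "fertile", trait_group: "Reproduction and Mothering Ability"}
  - {pattern: "loses lambs", trait_group: "Reproduction and Mothering Ability"}
  # Drought Tolerance
  - {pattern: "drought tolerant", trait_group: "Drought Tolerance"}
  - {pattern: "survives drought", trait_group: "Drought Tolerance"}
  - {pattern: "withstands drought", trait_group: "Drought Tolerance"}
  - {pattern: "walks far for water", trait_group: "Drought Tolerance"}
  - {pattern: "tolerates dry season", trait_group: "Drought Tolerance"}
  - {pattern: "drought", trait_group: "Drought Tolerance"}
  # Disease Resistance
  - {pattern: "disease resistant", trait_group: "Disease Resistance"}
  - {pattern: "rarely sick", trait_group: "Disease Resistance"}
  - {pattern: "often sick", trait_group: "Disease Resistance"}
  - {pattern: "worm resistant", trait_group: "Disease Resistance"}
  - {pattern: "tolerates parasites", trait_group: "Disease Resistance"}
  - {pattern: "disease", trait_group: "Disease Resistance"}
  # Breed Attributes: colour, legs, hoofs, breed-specific features
  - {pattern: "red coat", trait_group: "Breed Attributes"}
  - {pattern: "coat colour", trait_group: "Breed Attributes"}
  - {pattern: "colour", trait_group: "Breed Attributes"}
  - {pattern: "good legs", trait_group: "Breed Attributes"}
  - {pattern: "strong hoofs", trait_group: "Breed Attributes"}
  - {pattern: "breed type", trait_group: "Breed Attributes"}
  - {pattern: "fat tail", trait_group: "Breed Attributes"}
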