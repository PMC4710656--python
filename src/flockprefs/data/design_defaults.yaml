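# Default synthetic flock-survey design.
#
# Structure: 19 farms over two sites (10 + 9); 11 farms keep all three breed
# groups, six keep Red Maasai + Cross, two keep Dorper + Cross; every kept
# breed group contributes one Best, one Average and one Poor ewe, giving
# 11*9 + 8*6 = 147 ewes (51 Red Maasai, 39 Dorper, 57 Cross).
#
# Trait cells give [mean, sd] per breed x quality class pooled over sites;
# site_offset is the Isinya-minus-Amboseli shift per breed, applied half
# below / half above the pooled mean.  farmer_sd_frac is the fraction of the
# pooled cell sd attributed to a shared farmer (flock) effect.
sites:
  Amboseli: 10
  Isinya: 9
farm_patterns:
  Amboseli:
    - {breeds: [Red Maasai, Dorper, Cross], n_farms: 6}
    - {breeds: [Red Maasai, Cross], n_farms: 3}
    - {breeds: [Dorper, Cross], n_farms: 1}
  Isinya:
    - {breeds: [Red Maasai, Dorper, Cross], n_farms: 5}
    - {breeds: [Red Maasai, Cross], n_farms: 3}
    - {breeds: [Dorper, Cross], n_farms: 1}
ewes_per_group: 3
farmer_sd_frac: 0.4
traits:
  body_weight:
    site_offset: {Red Maasai: 1.6, Dorper: 5.9, Cross: 6.7}
    cells:
      Red Maasai: {Best: [41.6, 5.3], Average: [38.5, 4.3], Poor: [32.4, 4.5]}
      Dorper: {Best: [46.7, 9.2], Average: [44.8, 7.3], Poor: [37.0, 3.9]}
      Cross: {Best: [43.3, 7.8], Average: [39.2, 5.5], Poor: [34.1, 3.9]}
  body_length:
    site_offset: {Red Maasai: 3.9, Dorper: 3.0, Cross: 6.7}
    cells:
      Red Maasai: {Best: [62.9, 7.3], Average: [61.4, 6.4], Poor: [57.6, 4.6]}
      Dorper: {Best: [64.0, 8.0], Average: [64.8, 6.4], Poor: [58.8, 4.1]}
      Cross: {Best: [62.1, 6.8], Average: [62.1, 5.8], Poor: [58.5, 8.6]}
  heart_girth:
    site_offset: {Red Maasai: -1.5, Dorper: 0.3, Cross: 3.6}
    cells:
      Red Maasai: {Best: [79.2, 7.3], Average: [76.9, 7.2], Poor: [72.9, 4.7]}
      Dorper: {Best: [82.2, 6.4], Average: [81.7, 4.8], Poor: [76.2, 3.7]}
      Cross: {Best: [80.8, 6.0], Average: [76.8, 6.6], Poor: [74.3, 4.1]}
  bcs:
    site_offset: {Red Maasai: -0.6, Dorper: -0.9, Cross: -0.2}
    cells:
      Red Maasai: {Best: [3.03, 0.6], Average: [2.47, 0.7], Poor: [1.82, 0.5]}
      Dorper: {Best: [2.85, 0.7], Average: [3.04, 0.8], Poor: [2.08, 0.8]}
      Cross: {Best: [2.82, 0.5], Average: [2.63, 0.7], Poor: [2.00, 0.6]}
  milk_yield:
    site_offset: {Red Maasai: -0.2, Dorper: -0.2, Cross: 0.0}
    cells:
      Red Maasai: {Best: [0.43, 0.25], Average: [0.29, 0.17], Poor: [0.16, 0.15]}
      Dorper: {Best: [0.72, 0.37], Average: [0.45, 0.26], Poor: [0.21, 0.14]}
      Cross: {Best: [0.53, 0.21], Average: [0.35, 0.17], Poor: [0.30, 0.19]}
  price:
    site_offset: {Red Maasai: 820, Dorper: 4370, Cross: 2450}
    cells:
      Red Maasai: {Best: [5147, 1344], Average: [4341, 1229], Poor: [2988, 718]}
      Dorper: {Best: [8462, 4235], Average: [7000, 4439], Poor: [4462, 1785]}
      Cross: {Best: [5858, 2353], Average: [4532, 1668], Poor: [3405, 1166]}
# Latent across-breed preference (lower = more preferred, on the 1-9 rank
# scale) per site and breed, plus the shift per within-breed quality class
# and the sd of ewe-level preference noise.
rank_preference:
  latent:
    Amboseli: {Red Maasai: 4.9, Dorper: 4.8, Cross: 5.5}
    Isinya: {Red Maasai: 5.7, Dorper: 4.2, Cross: 5.0}
  quality_shift: {Best: -1.5, Average: 0.0, Poor: 1.5}
  noise_sd: 1.0
# Dentition-based integer age (years); probabilities over 1..9, mean ~3.5.
age_probs: [0.14, 0.23, 0.21, 0.15, 0.10, 0.07, 0.05, 0.03, 0.02]
coat_colours: [red, brown, white, "black head", spotted, tan]
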