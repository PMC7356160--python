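# Default reconciliation of diet-history-questionnaire (DHQ) items to the
# measured concentration table. Weights are fractions of the DHQ intake mass
# assigned to each concentration source; they must sum to 1 per item.
# `RICE_INDIVIDUAL` resolves to the subject's own rice Cd measurement
# (brown rice adjusted to polished-rice equivalent; the cohort GM backfills a
# missing measurement). Items marked `excluded` contribute no Cd: either Cd
# was not detected in them, or the DHQ does not assess them.
rules:
  rice:
    components:
      - {source: RICE_INDIVIDUAL, weight: 1.0}
  boiled_barley_rice:   # 70% rice / 30% wheat by assumption
    components:
      - {source: RICE_INDIVIDUAL, weight: 0.7}
      - {source: Wheat flour, weight: 0.3}
  kiritampo:
    components:
      - {source: Kiritampo, weight: 1.0}
  glutinous_rice:
    components:
      - {source: Glutinous rice, weight: 1.0}
  rice_cakes:
    components:
      - {source: Rice cakes, weight: 1.0}
  rice_crackers:
    components:
      - {source: Rice crackers, weight: 1.0}
  white_bread:
    components:
      - {source: White bread, weight: 1.0}
  ampan:
    components:
      - {source: Ampan, weight: 1.0}
  udon_soba:            # assessed jointly by DHQ; split into two halves
    components:
      - {source: Udon, weight: 0.5}
      - {source: Soba, weight: 0.5}
  chinese_noodles:      # wheat-flour noodles priced at the udon concentration
    components:
      - {source: Udon, weight: 1.0}
  spaghetti:
    components:
      - {source: Udon, weight: 1.0}
  butter_rolls:
    components:
      - {source: White bread, weight: 1.0}
  croissants:
    components:
      - {source: White bread, weight: 1.0}
  pizza:
    components:
      - {source: White bread, weight: 1.0}
  pancakes:
    components:
      - {source: White bread, weight: 1.0}
  okonomiyaki:
    components:
      - {source: White bread, weight: 1.0}
  snack_foods:
    components:
      - {source: Manju, weight: 1.0}
  japanese_sweets:
    components:
      - {source: Manju, weight: 1.0}
  cakes:
    components:
      - {source: Manju, weight: 1.0}
  cookies:
    components:
      - {source: Manju, weight: 1.0}
  doughnuts:
    components:
      - {source: Manju, weight: 1.0}
  sesame_seeds:
    components:
      - {source: Sesame seeds, weight: 1.0}
  potato:
    components:
      - {source: Potato, weight: 1.0}
  potato_chips:
    components:
      - {source: Potato chips, weight: 1.0}
  tubers:               # sweet potatoes / taro / yams assessed jointly
    components:
      - {average_of: [Sweet potato, Taro, Yams], weight: 1.0}
  soybeans:
    components:
      - {source: Soybeans, weight: 1.0}
  tofu:
    components:
      - {average_of: [Silken tofu, Cotton tofu], weight: 1.0}
  deep_fried_tofu:
    components:
      - {source: Deep-fried tofu, weight: 1.0}
  natto:
    components:
      - {source: Natto, weight: 1.0}
  miso:
    components:
      - {source: Miso, weight: 1.0}
  edamame:
    components:
      - {source: Edamame, weight: 1.0}
  soy_sauce:
    components:
      - {source: Soy sauce, weight: 1.0}
  carrot:
    components:
      - {source: Carrot, weight: 1.0}
  tomato:
    components:
      - {source: Tomato, weight: 1.0}
  squash:
    components:
      - {source: Squash, weight: 1.0}
  broccoli:
    components:
      - {source: Broccoli, weight: 1.0}
  japanese_white_radish:
    components:
      - {source: Japanese white radish, weight: 1.0}
  onions:
    components:
      - {source: Onions, weight: 1.0}
  cabbage:
    components:
      - {source: Cabbage, weight: 1.0}
  chinese_cabbage:
    components:
      - {source: Chinese cabbage, weight: 1.0}
  burdock:
    components:
      - {source: Burdock, weight: 1.0}
  japanese_parsley:
    components:
      - {source: Japanese parsley, weight: 1.0}
  eggplant:
    components:
      - {source: Eggplant, weight: 1.0}
  green_pepper:
    components:
      - {source: Green pepper, weight: 1.0}
  leafy_green_vegetables:
    components:
      - {average_of: [Spinach, Garland chrysanthemum, Japanese mustard spinach,
                      Bok choy, Japanese leek], weight: 1.0}
  pickled_vegetables:
    components:
      - {source: Pickled vegetables, weight: 1.0}
  smoked_daikon_pickles:
    components:
      - {source: Smoked daikon pickles, weight: 1.0}
  mushrooms:            # half shiitake, half other mushrooms (maitake)
    components:
      - {source: Raw shiitake mushroom, weight: 0.5}
      - {source: Maitake mushroom, weight: 0.5}
  wakame_seaweed:
    components:
      - {source: Wakame seaweed (raw), weight: 1.0}
  laver:
    components:
      - {source: Laver, weight: 1.0}
  salmon:
    components:
      - {source: Salmon, weight: 1.0}
  tuna:
    components:
      - {source: Tuna, weight: 1.0}
  cod:
    components:
      - {source: Cod, weight: 1.0}
  horse_mackerel:
    components:
      - {source: Horse mackerel, weight: 1.0}
  mackerel:
    components:
      - {source: Mackerel, weight: 1.0}
  sandfish:
    components:
      - {average_of: [Sandfish without eggs, Sandfish with eggs], weight: 1.0}
  squid:
    components:
      - {source: Squid, weight: 1.0}
  salted_squid_guts:
    components:
      - {source: Salted squid guts, weight: 1.0}
  octopus:
    components:
      - {source: Octopus, weight: 1.0}
  shrimp:
    components:
      - {average_of: [Prawn, Shrimp], weight: 1.0}
  fish_eggs:
    components:
      - {average_of: [Cod roe, Salmon roe], weight: 1.0}
  oysters:
    components:
      - {source: Oysters with innards, weight: 1.0}
  other_shellfish:
    components:
      - {average_of: [Scallops without innards, Japanese littleneck clam,
                      Freshwater clam], weight: 1.0}
  hampen:
    components:
      - {source: Hampen, weight: 1.0}
  dried_whitebait:
    components:
      - {source: Dried whitebait, weight: 1.0}
  broiled_eel:
    components:
      - {source: Broiled eel, weight: 1.0}
  liver:
    components:
      - {average_of: [Beef liver, Pork liver, Chicken liver,
                      Hinai chicken liver, Innards of Hinai chicken], weight: 1.0}
  horse_meat:
    components:
      - {source: Horse meat, weight: 1.0}
  sausage:
    components:
      - {source: Sausage, weight: 1.0}
  manju:
    components:
      - {source: Manju, weight: 1.0}
  chocolate:
    components:
      - {source: Chocolate, weight: 1.0}
  curry_roux:
    components:
      - {source: Curry roux, weight: 1.0}
  flavor_seasonings:
    components:
      - {source: Flavor seasonings, weight: 1.0}
  ketchup:
    components:
      - {source: Ketchup, weight: 1.0}
  # Cd not detected: contribute nothing to total intake.
  animal_meat: excluded
  eggs: excluded
  milk: excluded
  brewed_green_tea: excluded
  fruit: excluded
  fruit_juice: excluded
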