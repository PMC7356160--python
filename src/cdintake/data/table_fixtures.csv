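item,subgroup,area,n,mean_mg_per_kg,mean_kind,range_lo_mg_per_kg,range_hi_mg_per_kg,censored,lod_mg_per_kg
Rice,rice_products,A,711,0.158,GM,0.02,0.971,0,
Rice,rice_products,B,432,0.109,GM,0.008,0.687,0,
Kiritampo,rice_products,pooled,6,0.063,AM,0.070,0.102,0,
Glutinous rice,rice_products,pooled,10,0.098,AM,0.02,0.32,0,
Rice cakes,rice_products,pooled,5,0.069,AM,0.017,0.182,0,
Rice crackers,rice_products,pooled,4,0.091,AM,0.017,0.263,0,
White bread,cereals_tubers_roots,pooled,6,0.018,AM,0.016,0.023,0,
Ampan,cereals_tubers_roots,pooled,6,0.010,AM,0.010,0.014,0,
Wheat flour,cereals_tubers_roots,A,3,0.021,AM,0.019,0.024,0,
Udon,cereals_tubers_roots,pooled,6,0.005,AM,0.005,0.007,0,
Soba,cereals_tubers_roots,pooled,6,0.019,AM,0.007,0.034,0,
Sesame seeds,cereals_tubers_roots,pooled,6,0.055,AM,0.021,0.11,0,
Sweet potato,cereals_tubers_roots,pooled,6,0.008,AM,0.005,0.016,0,
Potato,cereals_tubers_roots,pooled,6,0.034,AM,0.005,0.098,0,
Taro,cereals_tubers_roots,pooled,6,0.289,AM,0.036,0.795,0,
Yams,cereals_tubers_roots,pooled,7,0.061,AM,0.005,0.167,0,
Potato chips,cereals_tubers_roots,A,3,0.059,AM,0.029,0.114,0,
Soybeans,soybeans,pooled,4,0.115,AM,0.05,0.25,0,
Silken tofu,soybeans,pooled,5,0.015,AM,0.009,0.028,0,
Cotton tofu,soybeans,pooled,6,0.027,AM,0.013,0.052,0,
Deep-fried tofu,soybeans,pooled,6,0.051,AM,0.033,0.083,0,
Natto,soybeans,pooled,6,0.028,AM,0.011,0.055,0,
Miso,soybeans,pooled,6,0.123,AM,0.026,0.259,0,
Edamame,soybeans,pooled,6,0.155,AM,0.085,0.293,0,
Soy sauce,soybeans,pooled,4,0.019,AM,0.015,0.026,0,
Carrot,vegetables,pooled,6,0.047,AM,0.013,0.107,0,
Spinach,vegetables,pooled,6,0.064,AM,0.030,0.122,0,
Tomato,vegetables,pooled,5,0.012,AM,0.005,0.022,0,
Squash,vegetables,pooled,6,0.016,AM,0.008,0.024,0,
Broccoli,vegetables,pooled,6,0.012,AM,0.005,0.027,0,
Japanese white radish,vegetables,pooled,6,0.009,AM,0.005,0.023,0,
Onions,vegetables,pooled,5,0.016,AM,0.005,0.031,0,
Cabbage,vegetables,pooled,6,0.008,AM,0.006,0.011,0,
Chinese cabbage,vegetables,pooled,6,0.020,AM,0.011,0.038,0,
Burdock,vegetables,pooled,6,0.063,AM,0.017,0.212,0,
Japanese parsley,vegetables,pooled,6,0.010,AM,0.005,0.019,0,
Eggplant,vegetables,pooled,6,0.017,AM,0.005,0.028,0,
Garland chrysanthemum,vegetables,pooled,5,0.074,AM,0.006,0.244,0,
Japanese mustard spinach,vegetables,pooled,5,0.065,AM,0.009,0.23,0,
Bok choy,vegetables,pooled,5,0.029,AM,0.01,0.101,0,
Green pepper,vegetables,pooled,5,0.006,AM,0.005,0.009,0,
Garlic,vegetables,pooled,6,0.051,AM,0.01,0.142,0,
Okra,vegetables,pooled,3,0.023,AM,0.012,0.043,0,
Belvedere fruit,vegetables,pooled,6,0.069,AM,0.041,0.095,0,
Japanese leek,vegetables,A,3,0.032,AM,0.005,0.083,0,
Pickled vegetables,vegetables,pooled,10,0.022,AM,0.009,0.095,0,
Smoked daikon pickles,vegetables,pooled,6,0.024,AM,0.017,0.035,0,
Raw shiitake mushroom,mushrooms,pooled,7,0.374,AM,0.065,0.527,0,
Maitake mushroom,mushrooms,pooled,6,0.043,AM,0.023,0.108,0,
Wakame seaweed (raw),seaweed,pooled,6,0.253,AM,0.069,0.544,0,
Wakame seaweed (dried),seaweed,A,3,4.64,AM,4.11,5.06,0,
Kelp,seaweed,pooled,6,0.682,AM,0.119,1.78,0,
Laver,seaweed,pooled,4,0.413,AM,0.209,0.66,0,
Hijiki seaweed,seaweed,pooled,5,1.066,AM,0.693,1.53,0,
Agar-agar,seaweed,A,3,0.024,AM,0.014,0.033,0,
Mozuku seaweed,seaweed,pooled,6,0.006,AM,0.005,0.01,0,
Salmon,fish_shellfish,pooled,6,,AM,,,1,0.005
Tuna,fish_shellfish,pooled,6,0.009,AM,0.005,0.013,0,
Cod,fish_shellfish,pooled,6,,AM,,,1,0.005
Horse mackerel,fish_shellfish,pooled,6,0.012,AM,0.007,0.015,0,
Mackerel,fish_shellfish,pooled,6,0.012,AM,0.005,0.018,0,
Sandfish without eggs,fish_shellfish,pooled,6,0.012,AM,0.009,0.017,0,
Sandfish with eggs,fish_shellfish,pooled,6,0.014,AM,0.01,0.018,0,
Squid,fish_shellfish,pooled,6,0.032,AM,0.018,0.081,0,
Salted squid guts,fish_shellfish,pooled,5,2.36,AM,0.978,6.57,0,
Octopus,fish_shellfish,pooled,6,0.007,AM,0.005,0.011,0,
Prawn,fish_shellfish,pooled,7,0.055,AM,0.005,0.17,0,
Shrimp,fish_shellfish,B,2,0.022,AM,0.009,0.035,0,
Cod roe,fish_shellfish,pooled,6,0.008,AM,0.005,0.015,0,
Salmon roe,fish_shellfish,pooled,3,,AM,,,1,0.005
Scallops without innards,fish_shellfish,pooled,5,0.0408,AM,0.012,0.103,0,
Scallops with innards,fish_shellfish,pooled,5,3.635,AM,0.684,5.54,0,
Oysters with innards,fish_shellfish,pooled,6,0.680,AM,0.486,1.03,0,
Japanese littleneck clam,fish_shellfish,pooled,4,0.160,AM,0.028,0.305,0,
Freshwater clam,fish_shellfish,pooled,4,0.375,AM,0.235,0.55,0,
Hampen,fish_shellfish,pooled,6,0.005,AM,0.005,0.006,0,
Dried whitebait,fish_shellfish,pooled,6,0.010,AM,0.005,0.02,0,
Broiled eel,fish_shellfish,pooled,6,0.008,AM,0.005,0.011,0,
Beef,livestock,pooled,6,,AM,,,1,0.005
Pork,livestock,pooled,5,,AM,,,1,0.005
Chicken,livestock,pooled,4,,AM,,,1,0.005
Hinai chicken,livestock,pooled,5,,AM,,,1,0.005
Horse meat,livestock,pooled,3,0.006,AM,0.005,0.007,0,
Beef liver,livestock,A,1,0.021,AM,,,0,
Pork liver,livestock,pooled,4,0.024,AM,0.016,0.028,0,
Chicken liver,livestock,pooled,5,0.015,AM,0.01,0.022,0,
Hinai chicken liver,livestock,A,2,0.039,AM,0.033,0.044,0,
Innards of Hinai chicken,livestock,pooled,6,0.021,AM,0.008,0.066,0,
Sausage,livestock,pooled,3,0.006,AM,0.005,0.008,0,
Egg,livestock,pooled,6,,AM,,,1,0.005
Milk,livestock,pooled,6,,AM,,,1,0.005
Apple,fruit,pooled,6,,AM,,,1,0.005
Apple juice,fruit,pooled,6,,AM,,,1,0.005
Kiwi fruit,fruit,pooled,5,,AM,,,1,0.005
Manju,others,pooled,10,0.022,AM,0.010,0.127,0,
Chocolate,others,A,3,0.042,AM,0.03,0.084,0,
Curry roux,others,A,3,0.015,AM,0.012,0.018,0,
Flavor seasonings,others,A,1,0.025,AM,,,0,
Ketchup,others,pooled,3,0.016,AM,0.016,0.017,0,
Japanese green tea leaves,others,A,3,0.026,AM,0.009,0.049,0,
Nutritional supplement drink,others,A,3,,AM,,,1,0.005
Well water,others,A,7,,AM,,,1,0.005
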