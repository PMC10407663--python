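food,category,n,df_pct,mrl,authority,olr_pct,median_all,median_above,max_conc,lod,loq,flag
Tomato,vegetable,4250,13.7,3,national_standard,0.00,ND,0.03,2.46,0.001,0.01,
Leguminous vegetables,vegetable,4305,17.1,0.5,national_standard,0.51,ND,0.05,2.13,0.001,0.01,
Eggplant,vegetable,3965,6.10,3,national_standard,0.00,ND,0.03,0.80,0.001,0.01,
Balsam pear,vegetable,1605,9.20,2,ministry_guideline,0.00,ND,0.04,1.20,0.001,0.01,
Pumpkin,vegetable,136,5.10,2,ministry_guideline,0.00,ND,0.05,0.28,0.001,0.01,
Summer squash,vegetable,2358,2.50,0.5,national_standard,0.00,ND,0.02,0.45,0.001,0.01,
Sponge gourd,vegetable,223,6.30,2,ministry_guideline,0.00,ND,0.03,0.07,0.001,0.01,
Chinese wax gourd,vegetable,124,3.20,2,ministry_guideline,0.00,ND,0.02,0.05,0.001,0.01,
Cucumber,vegetable,3967,15.7,2,national_standard,0.00,ND,0.04,0.78,0.001,0.01,
Okra,vegetable,12,0.00,0.5,ministry_guideline,0.00,ND,0.00,0.00,0.001,0.01,median_floor
Hot pepper,vegetable,4465,9.90,2,national_standard,0.02,ND,0.04,2.29,0.001,0.01,
Chinese Cabbage,vegetable,7423,6.30,0.5,ministry_guideline,0.86,ND,0.07,6.90,0.001,0.01,
Spinach,vegetable,1864,7.20,0.5,ministry_guideline,1.61,ND,0.11,110,0.001,0.01,
Amaranth,vegetable,318,10.7,0.5,ministry_guideline,0.94,ND,0.09,15.0,0.001,0.01,
Bok choy,vegetable,957,10.1,0.5,ministry_guideline,1.88,ND,0.08,24.0,0.001,0.01,
Water spinach,vegetable,1387,7.00,0.2,ministry_guideline,1.01,ND,0.05,3.61,0.001,0.01,
Chinese chive,vegetable,1984,10.3,2,national_standard,0.60,ND,0.08,15.0,0.001,0.01,
Cabbage flowering stalk,vegetable,1370,6.60,0.5,ministry_guideline,0.73,ND,0.06,2.73,0.001,0.01,
Coriander leaf,vegetable,291,6.90,0.5,ministry_guideline,0.00,ND,0.03,0.13,0.001,0.01,
Endive lettuce,vegetable,181,24.9,5,ministry_guideline,6.63,ND,0.09,22.0,0.001,0.01,
Romaine lettuce,vegetable,154,20.1,5,ministry_guideline,2.60,ND,0.11,19.0,0.001,0.01,
Vinespinach,vegetable,153,16.3,5,ministry_guideline,0.00,ND,0.05,2.60,0.001,0.01,
Celery stem,vegetable,3007,18.4,0.5,ministry_guideline,3.29,ND,0.08,35.0,0.001,0.01,
Cabbage,vegetable,3294,1.20,0.5,national_standard,0.03,ND,0.02,21.0,0.001,0.01,
Common spiderflower,vegetable,3919,1.60,0.5,ministry_guideline,0.03,ND,0.03,3.10,0.001,0.01,
Leaf mustard,vegetable,149,8.70,0.5,ministry_guideline,1.34,ND,0.04,0.65,0.001,0.01,
Crown daisy,vegetable,203,8.40,5,ministry_guideline,0.00,ND,0.05,2.09,0.001,0.01,
Yam,vegetable,1414,13.4,0.2,national_standard,3.25,ND,0.08,11.1,0.001,0.01,
Potato,potato,2078,0.60,0.2,ministry_guideline,0.00,ND,0.03,0.12,0.001,0.01,
Lotus root,vegetable,992,2.20,0.2,national_standard,0.10,ND,0.06,1.80,0.001,0.01,
Radish & Carrot,vegetable,4520,0.80,0.2,national_standard,0.00,ND,0.03,0.19,0.001,0.01,
Lettuce stem,vegetable,3825,11.2,5,national_standard,0.26,ND,0.12,21.0,0.001,0.01,
Manchurian wild rice,vegetable,2079,3.10,0.2,ministry_guideline,0.10,ND,0.02,2.40,0.001,0.01,
Water chestnut,vegetable,475,1.50,,,0.00,ND,0.02,0.21,0.001,0.01,
Arrowhead,vegetable,271,2.60,,,0.00,ND,0.02,0.10,0.001,0.01,
Asparagus,vegetable,35,0.00,0.5,national_standard,0.00,ND,0.00,0.01,0.001,0.01,median_floor
Allium vegetables,vegetable,6276,2.80,2,ministry_guideline,0.03,ND,0.06,4.27,0.001,0.01,
Watermelon,fruit,3500,6.00,2,national_standard,0.00,ND,0.03,0.40,0.001,0.01,
Casaba,fruit,73,15.1,,,0.00,ND,0.02,0.30,0.001,0.01,
Apple,fruit,2794,48.5,5,national_standard,0.00,ND,0.04,1.54,0.001,0.01,
Pear,fruit,1767,19.9,3,national_standard,0.00,ND,0.04,2.90,0.001,0.01,
Plum,fruit,72,16.7,0.5,national_standard,0.00,ND,0.04,0.09,0.001,0.01,
Peach,fruit,2666,47.1,2,national_standard,0.23,ND,0.06,8.39,0.001,0.01,
Chinese date,fruit,1410,41.9,0.5,national_standard,0.43,ND,0.05,1.10,0.001,0.01,
Pomegranate,fruit,115,53.9,0.5,ministry_guideline,13.04,0.02,0.17,6.05,0.001,0.01,
False sour cherry,fruit,347,35.7,0.5,national_standard,0.00,0.001,0.04,0.34,0.001,0.01,
Bayberry,fruit,800,16.3,1,national_standard,0.25,ND,0.00,2.32,0.001,0.01,median_floor
Loquat,fruit,58,5.20,3,national_standard,0.00,ND,0.10,0.30,0.001,0.01,
Lychee,fruit,110,5.50,0.5,national_standard,0.00,ND,0.01,0.02,0.001,0.01,median_floor
Banana,fruit,1598,33.8,2,national_standard,0.00,ND,0.05,1.67,0.001,0.01,
Citrus,fruit,2634,16.7,5,national_standard,0.00,ND,0.03,1.20,0.001,0.01,
Grape,fruit,3248,19.2,3,national_standard,0.00,ND,0.05,1.60,0.001,0.01,
Strawberry,fruit,2635,20.4,0.5,national_standard,0.80,ND,0.05,2.64,0.001,0.01,
Chinese kiwi fruit,fruit,780,32.1,5,national_standard,0.00,0.0006,0.07,2.59,0.001,0.01,
Shitake mushroom,mushroom,5025,13.4,3,ministry_guideline,0.02,ND,0.03,4.47,0.001,0.01,
Button mushroom,mushroom,1992,34.2,3,ministry_guideline,0.10,ND,0.10,4.85,0.001,0.01,
Oyster mushroom,mushroom,4244,2.90,3,ministry_guideline,0.00,ND,0.03,0.63,0.001,0.01,
Columnar agroc,mushroom,762,2.40,3,ministry_guideline,0.00,ND,0.04,1.20,0.001,0.01,
Gold needle mushroom,mushroom,3741,9.50,3,ministry_guideline,0.00,ND,0.05,2.13,0.001,0.01,
King oyster mushroom,mushroom,471,1.30,3,ministry_guideline,0.00,ND,0.03,0.08,0.001,0.01,
Straw mushroom,mushroom,363,13.8,3,ministry_guideline,0.00,ND,0.04,0.41,0.001,0.01,
Wood ear fungus,mushroom,629,6.70,3,ministry_guideline,0.48,ND,0.13,35.4,0.001,0.01,
Silver ear fungus,mushroom,48,2.10,3,ministry_guideline,0.00,ND,0.01,0.01,0.001,0.01,median_floor
Rice,cereal,498,2.20,2,national_standard,0.20,ND,0.02,5.20,0.01,0.01,
Wheat,cereal,410,13.2,0.5,national_standard,0.73,ND,0.03,0.94,0.01,0.01,
Tea,tea,470,0.90,5,national_standard,0.00,ND,0.02,0.04,0.001,0.01,
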