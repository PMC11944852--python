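item_name,form,method,grains,vegetables_legumes,fruit,dairy_alternatives,meat_alternatives,discretionary
All Bran,processed,not further defined,3.3,0.0,0.0,0.0,0.0,0.0
Apples,raw,not further defined,0.0,0.0,0.7,0.0,0.0,0.0
Apricots,raw,single,0.0,0.0,0.7,0.0,0.0,0.0
Avocado,raw,average,0.0,1.3,0.0,0.0,0.0,0.0
Bacon,cooked,average,0.0,0.0,0.0,0.0,1.4,1.9
Baked beans,processed,not further defined,0.0,1.3,0.0,0.0,0.7,0.0
Bananas,raw,average,0.0,0.0,0.7,0.0,0.0,0.0
"Bean sprouts, alfalfa sprouts",raw/cooked,average,0.0,1.4,0.0,0.0,0.0,0.0
Beef,cooked,average,0.0,0.0,0.0,0.0,1.5,0.0
Beer—full strength,processed,average,0.0,0.0,0.0,0.0,0.0,0.3
Beer—low alcohol,processed,average,0.0,0.0,0.0,0.0,0.0,0.2
Beetroot,raw/cooked,average,0.0,1.2,0.0,0.0,0.0,0.0
Bread—high fibre white,processed,average,2.7,0.0,0.0,0.0,0.0,0.0
Bread—multi-grain,processed,average,2.7,0.0,0.0,0.0,0.0,0.0
Bread—rye,processed,average,2.7,0.0,0.0,0.0,0.0,0.0
Bread—white,processed,average,2.7,0.0,0.0,0.0,0.0,0.0
Bread—wholemeal,processed,average,2.7,0.0,0.0,0.0,0.0,0.0
Broccoli,raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Butter,processed,not further defined,0.0,0.0,0.0,0.0,0.0,5.0
"Cabbage, Brussels sprouts",raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
"Cakes, sweet pies, tarts, other sweet pastries",cooked,average,0.9,0.0,0.2,0.1,0.1,2.3
Carrots,raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Cauliflower,raw/cooked,average,0.0,1.2,0.0,0.0,0.0,0.0
Celery,raw/cooked,average,0.0,1.2,0.0,0.0,0.0,0.0
Cheese—cream,processed,not further defined,0.0,0.0,0.0,2.5,0.0,0.0
"Cheese—firm (cheddar, edam)",processed,average,0.0,0.0,0.0,2.5,0.0,0.0
"Cheese—hard (parmesan, romano)",processed,average,0.0,0.0,0.0,2.5,0.0,0.0
Cheese—low fat,processed,single,0.0,0.0,0.0,2.5,0.0,0.0
"Cheese—ricotta, cottage",processed,average,0.0,0.0,0.0,0.8,0.0,0.0
"Cheese—soft (camembert, brie)",processed,not further defined,0.0,0.0,0.0,2.5,0.0,0.0
Chicken,cooked,average,0.2,0.0,0.0,0.0,1.1,0.0
Chocolate,processed,not further defined,0.0,0.0,0.0,0.8,0.0,3.5
"Corn chips, potato crisps, Twisties",processed,average,2.2,0.7,0.0,0.1,0.0,3.5
"Corned beef, luncheon meats, salami",processed,average,0.0,0.0,0.0,0.0,1.4,1.5
"Cornflakes, Nutrigrain, Special K",processed,average,3.3,0.0,0.0,0.0,0.0,0.0
"Crackers, crispbreads, dry biscuits",processed,not further defined,2.9,0.0,0.0,0.0,0.0,0.0
Cucumber,raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Eggs,cooked,average,0.0,0.0,0.0,0.0,0.8,0.0
Fish—fried (including take-away),cooked,average,0.0,0.0,0.0,0.0,1.0,0.0
"Fish—steamed, grilled, baked",cooked,average,0.0,0.0,0.0,0.0,1.0,0.0
"Fish—tinned (salmon, tuna, sardines)",processed,average,0.0,0.0,0.0,0.0,0.9,0.0
"Flavoured milk drink (cocoa, Milo)",processed,average,0.0,0.0,0.0,0.3,0.0,0.0
"Fortified wines (port, sherry)",processed,average,0.0,0.0,0.0,0.0,0.0,0.9
"Fruit—tinned, frozen",processed,average,0.0,0.0,0.6,0.0,0.0,0.0
Fruit juice,processed,not further defined,0.0,0.0,0.8,0.0,0.0,0.0
Garlic,raw/cooked,average,0.0,1.5,0.0,0.0,0.0,0.0
Green beans,raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Ham,processed,average,0.0,0.0,0.0,0.0,1.5,0.8
Hamburger with bun,mixed,average,0.9,0.2,0.0,0.2,0.5,1.7
Ice cream,processed,not further defined,0.0,0.0,0.0,0.5,0.0,1.3
"Jam, marmalade, honey, syrups",processed,average,0.0,0.0,0.2,0.0,0.0,1.6
Lamb,cooked,average,0.0,0.0,0.0,0.0,1.5,0.0
"Lettuce, endive, other salad greens",raw/cooked,average,0.0,1.5,0.0,0.0,0.0,0.0
"Mango, paw paw",raw,single,0.0,0.0,0.7,0.0,0.0,0.0
"Meat pies, pasties, quiche, other savoury pastries",cooked,average,0.7,0.3,0.0,0.1,0.3,1.7
Milk—full cream,processed,not further defined,0.0,0.0,0.0,0.4,0.0,0.0
Milk—reduced fat,processed,not further defined,0.0,0.0,0.0,0.4,0.0,0.0
Milk—skim,processed,not further defined,0.0,0.0,0.0,0.4,0.0,0.0
Milk—soya,processed,not further defined,0.0,0.0,0.0,0.4,0.0,0.0
Muesli,processed,average,2.3,0.0,0.5,0.0,0.4,0.0
Mushrooms,raw/cooked,average,0.0,1.2,0.0,0.0,0.0,0.0
Nuts,processed,average,0.0,0.0,0.0,0.0,3.3,0.0
"Onion, leeks",raw/cooked,average,0.0,1.1,0.0,0.0,0.0,0.0
"Oranges, other citrus",raw,average,0.0,0.0,0.7,0.0,0.0,0.0
"Other beans (chick peas, lentils)",cooked,average,0.0,1.3,0.0,0.0,0.6,0.0
Pasta or noodles (including lasagne),cooked,average,1.3,0.0,0.0,0.0,0.0,0.0
"Peaches, nectarines",raw,average,0.0,0.0,0.7,0.0,0.0,0.0
"Peanut butter, peanut paste",processed,not further defined,0.0,0.0,0.0,0.0,2.9,0.0
Pears,raw,not further defined,0.0,0.0,0.7,0.0,0.0,0.0
Peas,cooked,average,0.0,1.3,0.0,0.0,0.1,0.0
Peppers (capsicum),raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Pineapple,raw,single,0.0,0.0,0.7,0.0,0.0,0.0
Pizza,cooked,average,1.4,0.3,0.0,0.5,0.2,1.8
Pork,cooked,average,0.0,0.0,0.0,0.0,1.5,0.0
Porridge,cooked,average,0.8,0.0,0.0,0.3,0.0,0.0
Potatoes—cooked without fat,cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
"Potatoes—roasted, fried (including hot chips)",cooked,average,0.1,1.3,0.0,0.0,0.0,1.6
Pumpkin,cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
Red wine,processed,single,0.0,0.0,0.0,0.0,0.0,0.5
Rice,cooked,average,1.4,0.0,0.0,0.0,0.0,0.0
"Sausages, frankfurters",cooked,average,0.0,0.0,0.0,0.0,1.2,1.6
"Silverbeet, spinach",raw/cooked,average,0.0,1.3,0.0,0.0,0.0,0.0
"Soy beans, soy bean curd, tofu",processed,average,0.0,0.3,0.0,0.0,0.5,0.0
"Spirits, liqueurs",processed,average,0.0,0.0,0.0,0.1,0.0,1.8
Spread—butter and margarine blend,processed,not further defined,0.0,0.0,0.0,0.0,0.0,4.4
Spread—margarine,processed,average,0.0,0.0,0.0,0.0,0.0,0.0
Spread—monounsaturated margarine,processed,not further defined,0.0,0.0,0.0,0.0,0.0,0.0
Spread—polyunsaturated margarine,processed,not further defined,0.0,0.0,0.0,0.0,0.0,0.0
Strawberries,raw,single,0.0,0.0,0.7,0.0,0.0,0.0
Sugar,processed,average,0.0,0.0,0.0,0.0,0.0,2.7
"Sultana Bran, FibrePlus, Branflakes",processed,average,2.6,0.0,0.3,0.0,0.1,0.0
Sweet biscuits,processed,not further defined,1.6,0.0,0.0,0.1,0.0,3.3
"Tomato sauce, tomato paste, dried tomatoes",processed,average,0.0,2.3,0.0,0.0,0.0,0.0
"Tomatoes—fresh, tinned",raw/cooked,average,0.0,1.4,0.0,0.0,0.0,0.0
Veal,cooked,average,0.1,0.0,0.0,0.0,1.5,0.0
"Vegemite, Marmite, Promite",processed,not further defined,0.0,0.0,0.0,0.0,0.0,1.1
"Watermelon, rockmelon (cantaloupe), honeydew",raw,not further defined,0.0,0.0,0.7,0.0,0.0,0.0
"Weet Bix, Vita Brits, Weeties",processed,not further defined,3.3,0.0,0.0,0.0,0.0,0.0
White wine (including sparkling),processed,not further defined,0.0,0.0,0.0,0.0,0.0,0.5
Yoghurt,processed,not further defined,0.0,0.0,0.0,0.5,0.0,0.0
Zucchini,raw/cooked,average,0.0,1.2,0.0,0.0,0.0,0.0
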