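food_id,name,type,energy_kcal,mass_g,scaling
cheddar_cheese,Cheddar cheese,dairy,200,51,no
gouda_cheese,Gouda cheese,dairy,300,84,yes
avocado,Avocado,fruit,200,125,no
kiwi,Kiwi,fruit,200,328,no
brown_rice,Brown rice,grain,420,297.7,no
cereal,Cereal,grain,200,55,no
ham,Ham,meat,300,185.1,yes
salami,Salami,meat,300,72.9,yes
red_onion,Red onion,vegetable,200,475,no
potato,Potato,vegetable,100,141.7,no
broccoli,Broccoli,vegetable,200,588,no
cauliflower,Cauliflower,vegetable,300,1200,yes
cheeseburger,Cheeseburger,mixed,270,104,no
hot_dog,Hot dog,mixed,310,123,no
green_tea_cake,Green tea cake,mixed,136,40,no
long_cheeseburger,Long cheeseburger,mixed,590,213,no
pepperoni_and_sausage_pizza,Pepperoni and sausage pizza,mixed,240,97,no
swiss_roll,Swiss roll,mixed,251,96,no
tuna_sandwich,Tuna sandwich,mixed,720,420,yes
turkey_sandwich,Turkey sandwich,mixed,510,254,yes
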