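id,name,category,price_mean,price_sd,wastage_mean,wastage_sd,ghg_factor,tags,nut_energy,nut_protein,nut_fiber,nut_pufa,nut_sat_fat,nut_sodium,nut_potassium,nut_calcium,nut_iron,nut_zinc,nut_selenium,nut_vitamin_a,nut_thiamine,nut_vitamin_c,nut_vitamin_e
potatoes,Potatoes,fruit_veg,0.20792156153757319,0.024950587384508782,0.45,0.0142,0.5368191705675058,starchy_root;vegetable,501.72702953144216,2.2730701099285424,2.4065256878355545,0.1308694742726238,0.058459115638674064,9.797063338080068,672.6051693323,13.675309598863056,0.5589482475741043,0.44071114051927096,0.4980615237842576,80.46054746207133,0.09233752887197283,108.95111334600982,0.05671222381908016
kumara,Kumara,fruit_veg,0.3401401527144207,0.04081681832573048,0.38,0.03,0.7464658238064577,starchy_root;vegetable,447.00843420248043,2.2181629158484215,2.2571667762186594,0.11771271919462839,0.04919946797154181,12.145968222743036,593.5272622871827,12.398484745321971,0.5009814071845764,0.48973222729617755,0.5442025202800055,84.07753430586433,0.09678431733137684,83.91377530741973,0.055971590623555334
flour_wholemeal,"Flour, wholemeal",cereal_grain,0.14993475076458845,0.005997390030583538,0.05,0.01,1.0343961413506426,requires_cooking_skill,1828.6900842923328,11.726125019417058,9.957773301718063,1.8995084322566909,0.35793580243690104,2.8651460583953456,592.8330642286533,48.3699492159558,3.861197072098189,2.786035969807321,57.552972567556736,0.0,0.3860676241076151,0.0,0.7084484734079834
flour_white,"Flour, white",cereal_grain,0.11351875209128007,0.004540750083651203,0.05,0.01,1.0708150761187674,requires_cooking_skill,2150.0205167650656,7.821433160194758,4.034307886014733,0.9199923959974874,0.19081716208665994,3.187553002181585,178.73735972671776,19.639781961197123,0.9426274732665463,0.9418526166218619,15.504826295429174,0.0,0.12614241611428578,0.0,0.287723697451403
pasta,"Pasta, dry",cereal_grain,0.2615644900568138,0.010462579602272553,0.08,0.01,1.2772523436345484,,2152.4044393146014,14.507818538341327,3.745426710178271,1.0781187256563993,0.26347121675764534,5.329001109995933,361.6344161151856,28.96398599793136,1.8337219691126285,1.1888604836852414,61.28499331398239,0.0,0.18442490557803493,0.0,0.31112022654512494
dried_peas,Dried peas,pulse_seed_nut,0.3759731403499249,,0.05,0.01,0.9351949877358463,requires_cooking_skill,2251.358087348094,24.045256643538103,13.694923828286198,0.7600749819935807,0.18665482351282403,14.199693607617942,1191.392196035006,87.42615027651313,5.828834610677394,3.510979355936165,6.363590482911958,458.754212075583,0.6764183018976052,13.060165719127017,0.5265496846953094
skim_milk_powder,Skim milk powder,dairy,0.8619005150356308,0.04309502575178154,0.03,0.01,8.077494608865065,animal_product;dairy_product,2250.558623485456,30.146054381692966,0.0,0.06235276239590734,0.4813564479566651,395.63249973929567,2364.213121875864,1652.690279848155,0.30219006743417703,3.478655269335247,11.023163674113919,311.2373637732513,0.32603614446664886,41.81950284261895,0.03555544206775018
beef_mince,Beef mince,meat_fish_egg,1.314271642170378,0.07885629853022268,0.12,0.02,18.459049824943143,animal_product;meat,1206.4902902730144,17.734337750330813,0.0,0.7881724245386856,4.820116007667232,71.50277662155948,629.6443602436078,13.260328317732622,2.335307620348651,5.483650454209405,8.188942779364421,201.95183621990236,0.06560773660820364,0.0,0.36788040349404455
vegetable_oil,Vegetable oil,fat_oil,0.5794250564779173,0.028971252823895868,0.02,0.005,3.228617329519405,,5115.533394105121,0.0,0.0,25.982579878837875,6.322696750484279,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,27.567803049682915
salt,Salt,condiment,0.14981919181720965,0.0044945757545162895,0.01,0.003,0.2142788754250698,condiment_exempt_from_min,0.0,0.0,0.0,0.0,0.0,35459.852810038356,17.545445918731904,34.22101000379115,0.32433950252560784,0.0,0.0,0.0,0.0,0.0,0.0
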