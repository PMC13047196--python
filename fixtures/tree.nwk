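((((((('OTU_26':0.21043270955819246,'OTU_10':0.20963852583222528):0.05258688511650876,'OTU_55':0.24332500739805246):0.05551165412438597,('OTU_42':0.059831523224761256,(('OTU_34':0.0483667167978546,'OTU_44':0.08492513572370847):0.07307537438842086,'OTU_15':0.028137527717489105):0.021706169602613446):0.07220299362617161):0.07124318044615686,('OTU_29':0.7285064336168509,(('OTU_45':0.48129728237985886,'OTU_12':0.22266638376782907):0.0725997722217719,('OTU_60':0.00043786839478059266,('OTU_35':0.054525740464010077,'OTU_58':0.10322759146048613):0.16569729924979476):0.11525632535441695):0.04679032345822774):0.1659177174197751):0.38979958942828963,(((('OTU_24':0.22276286440016646,'OTU_38':0.08434725447031688):0.5449251001851573,'OTU_43':0.6878312497579695):0.00950571404546884,'OTU_16':0.05742120202261254):0.0010401184303329453,'OTU_33':0.00116005441146449):0.2808731634135589):0.21432895339314842,(('OTU_53':0.20381633570736216,'OTU_4':0.15711080538473157):0.1818581903382689,('OTU_9':0.5872476419900241,(('OTU_52':0.03880525407487515,'OTU_46':0.1190826131284834):0.4653669696551064,'OTU_49':0.22594905460561313):0.6452871993334544):0.000621996189342315):0.06182363508433595):0.024754019300439654,(((((('OTU_5':0.02920247566230568,'OTU_21':0.011677899452972073):0.204520302479029,(((('OTU_20':0.15166717505129293,'OTU_54':0.10751282166816693):0.06748940591893576,'OTU_41':0.2270123130050331):0.0991520461306648,('OTU_48':0.3337074033707344,'OTU_3':0.11181364032310086):0.14653922944833592):0.20536458354108195,'OTU_7':0.5238357358034742):0.11949785425864735):0.3936062537962509,(('OTU_31':0.08503911658632991,'OTU_25':0.2872595701081805):0.28025144113575107,(('OTU_1':0.09905569316707805,('OTU_36':0.04643411159244337,'OTU_47':0.16096861753539332):0.623677794543976):0.2555772688878743,'OTU_51':0.09678317313734998):0.11811272051338188):0.3170392820476218):0.01172573324868485,((((('OTU_19':0.06792442363618986,'OTU_40':0.02811791105197962):0.08475164658049014,'OTU_39':0.05632483350821913):0.03619061901768834,'OTU_59':0.22169809449954825):0.0987227530152493,('OTU_30':0.005133642850609019,'OTU_57':0.0691512957257467):0.07721936616190601):0.00024269766409431667,('OTU_17':0.03464951153350703,(('OTU_50':0.020920193630756728,'OTU_32':0.6000451726609565):0.006326004309249678,('OTU_6':0.0752532330303121,'OTU_11':0.013145607963341396):0.02677315885433536):0.04077651970553236):0.3620923910055061):0.18257824287607688):0.03934917157074021,(('OTU_56':0.44095952661751703,'OTU_28':0.45857159897568817):0.05356655999258185,('OTU_2':0.05838712673416581,'OTU_13':0.016046376510911377):0.07809965386366202):0.0022556317342438143):0.11934609817385318,((('OTU_27':0.1364778460089548,'OTU_22':0.018289715068588487):0.23595621866287841,'OTU_8':0.9616604299096926):0.05707175542430151,(('OTU_37':0.07256485862603729,('OTU_14':0.07804495656154382,'OTU_18':0.03719243821821709):0.017529650096441186):0.2809059448413407,'OTU_23':0.15097688865583306):0.16542654070005625):0.09442709380489696):0.18596999518247942);
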