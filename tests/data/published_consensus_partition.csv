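species_id,group_label,trophic_role
Acinonyx jubatus,0,carnivore
Crocuta crocuta,0,carnivore
Lycaon pictus,0,carnivore
Panthera leo,0,carnivore
Panthera pardus,0,carnivore
Canis aureus,1,carnivore
Canis mesomelas,1,carnivore
Caracal caracal,1,carnivore
Leptailurus serval,1,carnivore
Damaliscus korrigum,2,herbivore
Hippopotamus amphibius,2,herbivore
Kobus ellipsiprymnus,2,herbivore
Ourebia ourebi,2,herbivore
Pedetes capensis,2,herbivore
Phacochoerus africanus,2,herbivore
Redunca redunca,2,herbivore
Rhabdomys pumilio,2,herbivore
Taurotragus oryx,2,herbivore
Tragelaphus scriptus,2,herbivore
Aepyceros melampus,3,herbivore
Alcelaphus buselaphus,3,herbivore
Connochaetes taurinus,3,herbivore
Equus quagga,3,herbivore
Nanger granti,3,herbivore
Eudorcas thomsonii,3,herbivore
Heterohyrax brucei,4,herbivore
Procavia capensis,4,herbivore
Giraffa camelopardalis,5,herbivore
Loxodonta africana,5,herbivore
Madoqua kirkii,5,herbivore
Papio anubis,5,herbivore
Syncerus caffer,5,herbivore
Digitaria scalarum,6,plant
Dinebra retroflexa,6,plant
Hyparrhenia rufa,6,plant
Chloris gayana,7,plant
Combretum molle,7,plant
Digitaria diagonalis,7,plant
Duosperma kilimandscharica,7,plant
Eragrostis cilianensis,7,plant
Microchloa kunthii,7,plant
Sporobolus festivus,7,plant
Sporobolus fimbriatus,7,plant
Sporobolus spicatus,7,plant
Acacia tortilis,8,plant
Andropogon greenwayi,8,plant
Aristida spp.,8,plant
Balanites aegyptiaca,8,plant
Bothriochloa insculpta,8,plant
Brachiaria semiundulata,8,plant
Croton macrostachyus,8,plant
Cynodon dactylon,8,plant
Digitaria macroblephara,8,plant
Eragrostis tenuifolia,8,plant
Eustachys paspaloides,8,plant
Grewia bicolor,8,plant
Harpachne schimperi,8,plant
Heteropogon contortus,8,plant
Hibiscus spp.,8,plant
Hyparrhenia filipendula,8,plant
Indigofera hochstetteri,8,plant
Panicum coloratum,8,plant
Panicum maximum,8,plant
Pennisetum mezianum,8,plant
Sida spp.,8,plant
Solanum incanum,8,plant
Sporobolus ioclados,8,plant
Sporobolus pyramidalis,8,plant
Themeda triandra,8,plant
Pennisetum stramineum,9,plant
Acacia seyal,10,plant
Acacia xanthophloea,10,plant
Andropogon schirensis,10,plant
Chloris pycnothrix,10,plant
Chloris roxburghiana,10,plant
Crotalaria spinosa,10,plant
Cymbopogon excavatus,10,plant
Digitaria milanjiana,10,plant
Digitaria ternata,10,plant
Echinochloa haploclada,10,plant
Eragrostis exasperata,10,plant
Euphorbia candelabrum,10,plant
Hyperthelia dissoluta,10,plant
Kigelia africana,10,plant
Lonchocarpus eriocalyx,10,plant
Olea spp.,10,plant
Panicum deustum,10,plant
Panicum repens,10,plant
Phragmites mauritianus,10,plant
Psilolemma jaegeri,10,plant
Sarga versicolor,10,plant
Setaria pallidefusca,10,plant
Setaria sphacelata,10,plant
Typha capensis,10,plant
Acacia senegal,11,plant
Abutilon spp.,12,plant
Acalypha fruticosa,12,plant
Acacia robusta,12,plant
Achyranthes aspera,12,plant
Albizia harveyi,12,plant
Albuca spp.,12,plant
Allophylus rubifolius,12,plant
Aloe macrosiphon,12,plant
Aloe secundiflora,12,plant
Blepharis acanthodioides,12,plant
Capparis tomentosa,12,plant
Pennisetum ciliare,12,plant
Cissus quadrangularis,12,plant
Cissus rotundifolia,12,plant
Commelina africana,12,plant
Commiphora merkeri,12,plant
Commiphora schimperi,12,plant
Cordia ovalis,12,plant
Croton dichogamus,12,plant
Cyperus spp.,12,plant
Cyphostemma spp.,12,plant
Digitaria velutina,12,plant
Diheteropogon amplectens,12,plant
Emilia coccinea,12,plant
Eragrostis aspera,12,plant
Eriochloa nubica,12,plant
Ficus glumosa,12,plant
Ficus ingens,12,plant
Ficus thonningii,12,plant
Grewia fallax,12,plant
Grewia trichocarpa,12,plant
Heliotropium steudneri,12,plant
Hibiscus lunariifolius,12,plant
Hoslundia opposita,12,plant
Hypoestes forskaolii,12,plant
Iboza spp.,12,plant
Indigofera basiflora,12,plant
Ipomoea obscura,12,plant
Jasminum spp.,12,plant
Kalanchoe spp.,12,plant
Kedrostis foetidissima,12,plant
Kyllinga nervosa,12,plant
Lippia ukambensis,12,plant
Maerua cafra,12,plant
Ocimum spp.,12,plant
Pappea capensis,12,plant
Pavetta assimilis,12,plant
Pavonia patens,12,plant
Pellaea calomelanos,12,plant
Phyllanthus sepialis,12,plant
Pupalia lappacea,12,plant
Rhoicissus revoilii,12,plant
Sclerocarya birrea,12,plant
Senna didymobotrya,12,plant
Sansevieria ehrenbergii,12,plant
Sansevieria suffruticosa,12,plant
Solanum dennekense,12,plant
Solanum nigrum,12,plant
Sporobolus pellucidus,12,plant
Sporobolus stapfianus,12,plant
Tricholaena teneriffae,12,plant
Turraea fischeri,12,plant
Ximenia caffra,12,plant
Ziziphus spp.,12,plant
Boscia augustifolia,13,plant
Commiphora trothae,13,plant
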