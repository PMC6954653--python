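iscn,parsable,Diploid,Triploid,Male,Female,NumericalAbnormal,NumericalAbnormalAutosomalGain,NumericalAbnormalAutosomalLoss,NumericalAbnormalAllosomalGain,NumericalAbnormalAllosomalLoss,StructuralAbnormal,StructuralAbnormalDeletion,StructuralAbnormalTranslocation,StructuralAbnormalInversion,StructuralAbnormalDuplication,StructuralAbnormalIsochromosome
"46,XY",true,true,false,true,false,false,false,false,false,false,false,false,false,false,false,false
"46,XX",true,true,false,false,true,false,false,false,false,false,false,,,,,
"46,XN",true,true,false,false,false,false,,,,,false,,,,,
"45,X,-Y",true,true,false,true,false,true,false,false,false,true,false,false,,,,
"45,X",true,true,false,false,false,true,false,false,false,true,false,,,,,
"47,XX,+21",true,true,false,false,true,true,true,false,false,false,false,,,,,
"45,XY,-21",true,true,,true,false,true,false,true,false,false,false,,,,,
"47,XXY",true,true,false,true,false,true,false,false,true,false,false,,,,,
"69,XXY",true,false,true,true,false,false,,,,,false,,,,,
"46,XY,del(15)(q11q12)",true,true,,true,false,false,,,,,true,true,false,false,false,false
"46,XX,del(1)(p31p21)",true,true,,false,true,false,,,,,true,true,,,,
"46,XX,t(2;5)(q21;q31)",true,true,,false,true,false,,,,,true,false,true,false,,
"46,XY,inv(3)(p21q21)",true,true,,true,false,false,,,,,true,,,true,,
"46,XY,dup(1)(q21q31)",true,true,,true,,false,,,,,true,,,,true,
"46,XX,i(17)(q11)",true,true,,false,true,false,,,,,true,,,,,true
"47,XY,+mar",true,true,,true,false,,,,,,,,,,,
"46,XY,del(1)(p99)",false,,,,,,,,,,,,,,,
"46,XY,foo(1)(p31)",false,,,,,,,,,,,,,,,
"46,XY,t(2)(q21)",false,,,,,,,,,,,,,,,
"44,XX",false,,,,,,,,,,,,,,,
abc,false,,,,,,,,,,,,,,,
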