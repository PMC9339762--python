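resource,taxon_class,trophic,coefficient_a,exponent_b,se_log10_a,se_b,mass_threshold_kg,coefficient_a_above_threshold
land_density,mammal,carnivore,2.74,-1.018,,,,
land_density,mammal,herbivore,18.84,-0.583,,,,
land_density,mammal,omnivore,20.28,-0.915,,,,
land_density,bird,carnivore,0.65,-0.868,,,,
land_density,bird,herbivore,3.02,-0.693,,,,
land_density,bird,omnivore,5.61,-0.416,,,,
land_density,reptile,all,218.3,-0.656,,,,
land_density,insect,all,7852,-0.713,,,,
energy,mammal,carnivore,791.2,0.85,,,,
energy,mammal,herbivore,688.4,0.646,,,,
energy,mammal,omnivore,652.1,0.678,,,,
energy,bird,carnivore,1264,0.705,,,,
energy,bird,herbivore,1159.3,0.681,,,,
energy,bird,omnivore,716.6,0.628,,,,
energy,reptile,all,91.0,0.889,,,,
energy,insect,all,16832,0.832,,,1e-05,4208
water,mammal,all,9.9e-05,0.90,,,,
water,bird,all,5.9e-05,0.67,,,,
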