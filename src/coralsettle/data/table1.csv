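family,species,species_id,tc50,ci_lower,ci_upper,best_cue,precompetency_class,oocyte_diameter_um
Acroporidae,Acropora austera,Aaus,6.16,5.18,7.22,Rubble,long,627
Acroporidae,Acropora glauca,Agla,4.42,3.64,5.09,Rubble,mid,708
Acroporidae,Acropora hyacinthus,Ahya,4.55,3.90,5.43,Rubble,mid,520
Acroporidae,Acropora intermedia,Aint,5.35,4.59,6.10,Rubble,long,496
Acroporidae,Acropora longicyathus,Alon,4.40,3.45,5.35,CCA,mid,582
Acroporidae,Acropora loripes,Alor,5.44,4.58,6.35,Disc,long,543
Acroporidae,Acropora millepora,Amil,4.27,3.32,5.13,Disc,mid,582
Acroporidae,Acropora cf. kenti,Aken,4.24,3.36,5.07,Rubble,mid,517
Acroporidae,Montipora aequituberculata,Maeq,3.30,2.49,4.21,CCA,mid,310
Diploastraeidae,Diploastrea heliopora,Dhel,3.43,2.68,4.06,Rubble,mid,230
Euphylliidae,Galaxea fascicularis,Gfas,2.65,2.01,3.23,Rubble,short,453
Lobophyllidae,Lobophyllia corymbosa,Lcor,4.19,3.32,5.10,CCA,mid,600
Lobophyllidae,Lobophyllia hemprichii,Lhem,4.06,3.26,4.81,Rubble,mid,550
Merulinidae,Dipsastraea matthaii,Dmat,2.83,2.26,3.59,Rubble,short,412
Merulinidae,Dipsastraea pallida,Dpal,3.67,2.94,4.56,Rubble,mid,414
Merulinidae,Goniastrea retiformis,Gret,2.12,1.73,2.53,Rubble,short,377
Merulinidae,Mycedium elephantotus,Mele,3.97,3.24,4.76,Rubble,mid,387
Merulinidae,Oulophyllia crispa,Ocri,3.09,2.55,3.72,Rubble,mid,250
Merulinidae,Platygyra daedalea,Pdae,3.12,2.40,3.83,Rubble,mid,388
Poritidae,Porites cylindrica,Pcyl,4.44,3.76,5.15,Rubble,mid,233
Poritidae,Porites lobata,Plob,3.56,3.03,4.13,Rubble,mid,208
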