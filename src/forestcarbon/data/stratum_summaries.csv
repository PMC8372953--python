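stratum,n_plots,metric,mean,sd
DDF,21,n_species,22.57,5.46
DDF,21,density,890.48,220.60
DDF,21,basal_area,16.29,3.97
DDF,21,shannon,2.44,0.28
DDF,21,agb_stem,51.43,19.79
DDF,21,agb_branch,10.34,4.40
DDF,21,agb_leaf,1.82,0.62
DDF,21,agb_total,63.60,27.80
DDF,21,carbon,29.89,11.65
MDF,4,n_species,31.00,9.27
MDF,4,density,1214.06,581.74
MDF,4,basal_area,17.16,4.45
MDF,4,shannon,2.68,0.16
MDF,4,agb_stem,56.54,17.60
MDF,4,agb_branch,11.07,3.67
MDF,4,agb_leaf,2.06,0.60
MDF,4,agb_total,69.67,21.83
MDF,4,carbon,32.74,10.26
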