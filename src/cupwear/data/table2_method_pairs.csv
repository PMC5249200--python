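specimen_id,ct_mass_mg,grav_mass_mg
XLPE_1,2.97,5.40
XLPE_2,4.91,6.86
XLPE_3,9.83,9.51
STD_PE_1,23.26,20.37
STD_PE_2,21.38,23.06
STD_PE_3,19.24,17.77
XLPE_VE_1,21.89,23.94
XLPE_VE_2,13.79,16.43
XLPE_VE_3,15.04,18.41
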