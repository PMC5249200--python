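specimen_id,printed_difference_mg
XLPE_1,-2.42
XLPE_2,-1.95
XLPE_3,0.32
STD_PE_1,2.89
STD_PE_2,-1.69
STD_PE_3,1.47
XLPE_VE_1,-2.06
XLPE_VE_2,-2.64
XLPE_VE_3,-3.37
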