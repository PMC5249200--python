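cycles_Mc,material,mean_loss_mg,sd_loss_mg
0.4,STD_PE,4.0,0.4
0.4,XLPE,2.1,0.6
0.4,XLPE_VE,4.0,0.3
0.8,STD_PE,8.0,1.2
0.8,XLPE,3.7,1.3
0.8,XLPE_VE,7.1,0.5
1.2,STD_PE,13.2,1.7
1.2,XLPE,5.8,1.2
1.2,XLPE_VE,13.6,2.1
1.6,STD_PE,17.4,1.2
1.6,XLPE,8.1,2.1
1.6,XLPE_VE,20.6,3.9
2.0,STD_PE,21.3,14.4
2.0,XLPE,10.2,2.1
2.0,XLPE_VE,28.2,4.0
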