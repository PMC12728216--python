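compound_id,cc50_um,hc10_um,mic_lo_um,mic_hi_um
Re(CO)3(M1Y1),12.4,73,0.39,0.39
Re(CO)3(M20Y3),8.2,36,0.39,0.78
IrCN(M12Y1),7.3,81,0.20,0.39
IrCN(M8Y4),38.5,>200,0.39,0.78
Mn(CO)3(M19Y1),11.9,>200,0.39,0.78
Mn(CO)3(M22Y1),12.9,87,3.13,6.25
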