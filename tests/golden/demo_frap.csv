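true_speed_um_s,speed_um_s,direction_deg,fit_r2
2,2.019692402,0.228165054,0.9982643213
5,5.009043325,0.01505432466,0.9995175792
10,9.974394762,359.9192291,0.9998125758
20,19.96379979,0.01817742881,0.9999495801
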