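condition,replicate,alignment_coefficient,mean_angle_deg,fraction_70_110
aligned,0,0.9635985091,89.79334902,0.9827561926
aligned,1,0.9664810826,89.69878625,0.9847993343
aligned,2,0.965325532,89.72622831,0.9825663796
random,0,0.04989369921,132.643596,0.2210297923
random,1,0.0823868511,80.88399466,0.2798909398
random,2,0.06066097788,106.6191674,0.2420226962
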