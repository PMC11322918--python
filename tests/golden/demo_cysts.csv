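condition,replicate,aspect_ratio,roundness,shape_factor,curvature_ratio
symmetric,0,1.327527894,0.7434072692,0.6429662085,0.9538460382
symmetric,1,1.34158509,0.7355599896,0.6990270577,1.114331808
symmetric,2,1.329433884,0.7422151402,0.7010147032,0.8195735402
symmetric,3,1.322516833,0.7461451069,0.6856483401,1.159256461
symmetric,4,1.332798711,0.7403999473,0.6534243483,0.937206917
symmetric,5,1.34023473,0.7363366929,0.6982049567,1.289641385
symmetric,6,1.322030563,0.7463693151,0.6850339576,0.7245289089
symmetric,7,1.330133019,0.7419083465,0.7144812019,1.376762108
top_ruffled,0,1.228902064,0.7804342551,0.4902817077,5.350674591
top_ruffled,1,1.222562205,0.7539021851,0.3422841152,3.820522735
top_ruffled,2,1.259203975,0.7663055125,0.5253346588,4.653938956
top_ruffled,3,1.262747717,0.7581650131,0.5201848217,4.205848713
top_ruffled,4,1.269745839,0.7683850345,0.6023136457,4.732598743
top_ruffled,5,1.267495279,0.7567612536,0.4561592397,5.246011673
top_ruffled,6,1.282593397,0.7430051171,0.4983250751,3.511636286
top_ruffled,7,1.243254362,0.7615804293,0.4645997891,4.43721739
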