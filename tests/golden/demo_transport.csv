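formation_time_s,maintained_over_window,midpoint_steady_conc
1800,True,0.55
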