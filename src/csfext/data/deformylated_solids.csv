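treatment,fa_wt_percent,temperature_C,time_h,SY_pct,GC_pct,XC_pct,LC_pct,DD_pct,FC_pct,EGC6_pct,EGC72_pct
lime_4wt_pct,80,105,0.5,55.0,80.2,9.7,9.3,78.8,0.22,43.7,72.1
lime_4wt_pct,90,105,0.25,53.1,82.7,9.3,8.0,82.4,0.39,40.9,74.9
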