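year,n_individuals,n_stems_sampled,St,St_se,Fl,Fl_se,fruit_set,fruit_set_se,sound_seeds_per_fruit,sound_seeds_per_fruit_se,S,S_se,Sa,rrs_pct,rrs_pct_se
2014,20,40,18.9,3.67,11.71,0.95,0.29,0.06,0.58,0.06,7.26,1.23,,28.96,2.92
2015,20,40,9.65,1.49,21.55,3.03,0.34,0.06,0.76,0.16,9.24,2.79,0.85,34.06,1.99
2016,20,40,13.9,3.01,24.87,3.47,0.37,0.07,0.8,0.07,20.68,3.64,0.65,40,3.45
2017,20,40,12.5,2.3,20.94,1.75,0.33,0.07,0.65,0.09,13.04,1.66,0.9,32.3,4.43
2018,20,40,16.95,2.55,19.78,3.7,0.3,0.04,0.6,0.05,11.47,2.28,0.95,31.14,3.66
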