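subpopulation,year,n_mature,n_seedlings,n_nonreproductive,n_dead,local_eoo_m2
An-Pl,2014,28,0,8,0,9100.9
An-Pl,2015,22,5,5,2,9100.9
An-Pl,2016,20,3,4,0,9100.9
An-Pl,2017,25,8,18,0,9100.9
An-Pl,2018,28,6,22,2,9100.9
An-F,2014,30,2,10,0,961.6
An-F,2015,28,0,6,0,961.6
An-F,2016,12,0,9,0,930
An-F,2017,14,0,5,0,930
An-F,2018,25,5,12,0,930
An-PV,2014,46,3,1,0,44642
An-PV,2015,37,3,2,0,44642
An-PV,2016,25,0,7,1,44642
An-PV,2017,28,2,5,2,44642
An-PV,2018,33,2,7,2,44642
An-N,2014,20,2,0,0,16713
An-N,2015,13,0,3,0,14500
An-N,2016,5,0,2,0,11100
An-N,2017,10,0,5,0,11100
An-N,2018,19,1,9,2,14400
An-S,2014,6,1,2,0,12.9
An-S,2015,9,0,0,0,12.9
An-S,2016,6,0,0,3,12.9
An-S,2017,2,2,3,0,12.9
An-S,2018,5,0,3,0,12.9
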