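subpopulation,lon,lat,aoo_cells
An-Pl,20.771043,37.684911,1
An-F,20.805406,37.655566,1
An-PV,20.631753,37.830836,4
An-N,20.625887,37.862830,1
An-S,20.679972,37.781673,1
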