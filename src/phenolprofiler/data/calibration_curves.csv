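no,standard,wavelength_nm,slope,intercept,r_squared,lod_ug_ml,loq_ug_ml,recovery_pct,recovery_sd,rsd_intraday_pct,rsd_interday_pct
1,Gallic acid,280,18817,-10155,0.9996,0.014,0.042,,,,
2,Caffeic acid,320,43686,-19547,0.9998,0.010,0.030,,,,
3,Apigenin,320,29655,6320.6,0.9999,0.013,0.040,99.50,2.69,1.16,2.33
4,Acacetin,320,26463,9248.4,0.9999,0.013,0.041,102.19,3.10,0.68,1.54
5,Luteolin,360,24041,44178,0.9989,0.036,0.109,100.47,2.96,1.84,2.70
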