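peak_no,compound,group,area_pct,content_mg_per_g,content_sd
1,3-O-Caffeoyl-5-O-p-coumaroylquinic acid,Hydroxycinnamic acid,2.21,0.25,0.01
2,Coumaroyloleuropein,Hydroxycinnamic acid,9.69,0.42,0.03
3,Luteolin-O-glucoside,Flavonoid,2.49,0.16,0.01
4,"3,5-Dicaffeoylquinic acid monohydrate",Hydroxycinnamic acid,4.34,0.20,0.00
5,"3,5-Dicaffeoylquinic acid",Hydroxycinnamic acid,5.43,0.24,0.00
6,Gallic acid monohydrate,Hydroxybenzoic acid,2.80,0.31,0.02
7,Shikimic acid isomer,Hydroxybenzoic acid,3.07,0.34,0.02
8,Methoxyoleuropein isomer,Hydroxycinnamic acid,2.97,0.14,0.01
9,Luteolin,Flavonoid,19.75,1.61,0.11
10,Prenyl-dimethoxy-caffeoyl-p-coumaric acid,Hydroxycinnamic acid,20.88,0.89,0.06
11,Apigenin,Flavonoid,9.12,0.57,0.02
12,Chrysoeriol,Flavonoid,2.23,0.13,0.01
13,Tricin,Flavonoid,3.95,0.24,0.00
17,Acacetin,Flavonoid,11.09,0.92,0.02
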