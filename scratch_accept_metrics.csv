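config,seed,metric,value
pka_spine__ac_spine__neck0.3__default,7,auc_pka_catalytic,222.59023913590488
pka_spine__ac_spine__neck0.3__default,7,mean_phospho_I1,914.9027896466572
pka_spine__ac_spine__neck0.3__default,7,mean_phospho_PDE4,87.50975606910086
pka_spine__ac_spine__neck0.3__default,7,auc_phospho_PDE4,1378.2786580883385
pka_spine__ac_spine__neck0.3__default,7,mean_frac_pS845_GluR1,0.0700190355329949
pka_spine__ac_spine__neck0.3__default,7,peak_spine_Ca,254.4947414513328
pka_spine__ac_spine__neck0.3__default,7,peak_dend_Ca,116.23773470216923
pka_spine__ac_spine__neck0.3__default,7,auc_spine_cAMP,918.1387210821164
pka_spine__ac_spine__neck0.3__default,7,auc_dend_cAMP,788.3270843152236
pka_spine__ac_spine__neck0.3__default,1020,auc_pka_catalytic,217.2144070880668
pka_spine__ac_spine__neck0.3__default,1020,mean_phospho_I1,905.8736238447495
pka_spine__ac_spine__neck0.3__default,1020,mean_phospho_PDE4,90.33157403534116
pka_spine__ac_spine__neck0.3__default,1020,auc_phospho_PDE4,1422.7222910566234
pka_spine__ac_spine__neck0.3__default,1020,mean_frac_pS845_GluR1,0.0753013959390863
pka_spine__ac_spine__neck0.3__default,1020,peak_spine_Ca,293.6477785976917
pka_spine__ac_spine__neck0.3__default,1020,peak_dend_Ca,116.23773470216923
pka_spine__ac_spine__neck0.3__default,1020,auc_spine_cAMP,700.056304176897
pka_spine__ac_spine__neck0.3__default,1020,auc_dend_cAMP,571.6267360490368
pka_spine__ac_dendrite_focal__neck0.3__default,7,auc_pka_catalytic,175.25982284837522
pka_spine__ac_dendrite_focal__neck0.3__default,7,mean_phospho_I1,916.4969864595706
pka_spine__ac_dendrite_focal__neck0.3__default,7,mean_phospho_PDE4,69.36914859502308
pka_spine__ac_dendrite_focal__neck0.3__default,7,auc_phospho_PDE4,1092.5640903716137
pka_spine__ac_dendrite_focal__neck0.3__default,7,mean_frac_pS845_GluR1,0.0362785532994923
pka_spine__ac_dendrite_focal__neck0.3__default,7,peak_spine_Ca,293.6477785976917
pka_spine__ac_dendrite_focal__neck0.3__default,7,peak_dend_Ca,105.1674742543436
pka_spine__ac_dendrite_focal__neck0.3__default,7,auc_spine_cAMP,466.5084375988662
pka_spine__ac_dendrite_focal__neck0.3__default,7,auc_dend_cAMP,1687.730394398818
pka_spine__ac_dendrite_focal__neck0.3__default,1020,auc_pka_catalytic,225.4641923070642
pka_spine__ac_dendrite_focal__neck0.3__default,1020,mean_phospho_I1,906.3118854111
pka_spine__ac_dendrite_focal__neck0.3__default,1020,mean_phospho_PDE4,72.55428377054258
pka_spine__ac_dendrite_focal__neck0.3__default,1020,auc_phospho_PDE4,1142.7299693860457
pka_spine__ac_dendrite_focal__neck0.3__default,1020,mean_frac_pS845_GluR1,0.0311389593908629
pka_spine__ac_dendrite_focal__neck0.3__default,1020,peak_spine_Ca,352.37733431723
pka_spine__ac_dendrite_focal__neck0.3__default,1020,peak_dend_Ca,121.77286492608204
pka_spine__ac_dendrite_focal__neck0.3__default,1020,auc_spine_cAMP,410.911124851037
pka_spine__ac_dendrite_focal__neck0.3__default,1020,auc_dend_cAMP,1512.114550219624
pka_dendrite_focal__ac_spine__neck0.3__default,7,auc_pka_catalytic,154.96252857706264
pka_dendrite_focal__ac_spine__neck0.3__default,7,mean_phospho_I1,909.6762353535285
pka_dendrite_focal__ac_spine__neck0.3__default,7,mean_phospho_PDE4,65.23498976746257
pka_dendrite_focal__ac_spine__neck0.3__default,7,auc_phospho_PDE4,1027.4510888375355
pka_dendrite_focal__ac_spine__neck0.3__default,7,mean_frac_pS845_GluR1,0.0335025380710659
pka_dendrite_focal__ac_spine__neck0.3__default,7,peak_spine_Ca,332.80081574405057
pka_dendrite_focal__ac_spine__neck0.3__default,7,peak_dend_Ca,113.47016959021282
pka_dendrite_focal__ac_spine__neck0.3__default,7,auc_spine_cAMP,839.049586046471
pka_dendrite_focal__ac_spine__neck0.3__default,7,auc_dend_cAMP,746.3016080901655
pka_dendrite_focal__ac_spine__neck0.3__default,1020,auc_pka_catalytic,235.9592534410299
pka_dendrite_focal__ac_spine__neck0.3__default,1020,mean_phospho_I1,907.3081565925986
pka_dendrite_focal__ac_spine__neck0.3__default,1020,mean_phospho_PDE4,81.39283022946505
pka_dendrite_focal__ac_spine__neck0.3__default,1020,auc_phospho_PDE4,1281.9370761140744
pka_dendrite_focal__ac_spine__neck0.3__default,1020,mean_frac_pS845_GluR1,0.0328997461928933
pka_dendrite_focal__ac_spine__neck0.3__default,1020,peak_spine_Ca,332.80081574405057
pka_dendrite_focal__ac_spine__neck0.3__default,1020,peak_dend_Ca,114.85395214619103
pka_dendrite_focal__ac_spine__neck0.3__default,1020,auc_spine_cAMP,651.898068486875
pka_dendrite_focal__ac_spine__neck0.3__default,1020,auc_dend_cAMP,574.477328114352
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,auc_pka_catalytic,186.8197862734401
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,mean_phospho_I1,907.5101805116598
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,mean_phospho_PDE4,75.52028816288697
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,auc_phospho_PDE4,1189.44453856547
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,mean_frac_pS845_GluR1,0.0540291878172588
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,peak_spine_Ca,293.6477785976917
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,peak_dend_Ca,117.62151725814743
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,auc_spine_cAMP,431.2707041671432
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,7,auc_dend_cAMP,1618.0431048797554
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,auc_pka_catalytic,246.5569557596798
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,mean_phospho_I1,904.945780119707
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,mean_phospho_PDE4,94.75247648995612
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,auc_phospho_PDE4,1492.351504716809
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,mean_frac_pS845_GluR1,0.06698921319796955
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,peak_spine_Ca,274.07126002451224
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,peak_dend_Ca,112.08638703423462
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,auc_spine_cAMP,380.3717558768766
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1020,auc_dend_cAMP,1454.7982767510066
pka_uniform__ac_spine__neck0.3__default,7,auc_pka_catalytic,193.6069346106868
pka_uniform__ac_spine__neck0.3__default,7,mean_phospho_I1,909.7699157998672
pka_uniform__ac_spine__neck0.3__default,7,mean_phospho_PDE4,66.12291747623911
pka_uniform__ac_spine__neck0.3__default,7,auc_phospho_PDE4,1041.435950250766
pka_uniform__ac_spine__neck0.3__default,7,mean_frac_pS845_GluR1,0.04543147208121828
pka_uniform__ac_spine__neck0.3__default,7,peak_spine_Ca,293.6477785976917
pka_uniform__ac_spine__neck0.3__default,7,peak_dend_Ca,114.85395214619103
pka_uniform__ac_spine__neck0.3__default,7,auc_spine_cAMP,740.7754628091104
pka_uniform__ac_spine__neck0.3__default,7,auc_dend_cAMP,659.8013605159679
pka_uniform__ac_spine__neck0.3__default,1020,auc_pka_catalytic,218.1381777502251
pka_uniform__ac_spine__neck0.3__default,1020,mean_phospho_I1,899.8389738753766
pka_uniform__ac_spine__neck0.3__default,1020,mean_phospho_PDE4,81.66654005528974
pka_uniform__ac_spine__neck0.3__default,1020,auc_phospho_PDE4,1286.2480058708134
pka_uniform__ac_spine__neck0.3__default,1020,mean_frac_pS845_GluR1,0.0801713197969543
pka_uniform__ac_spine__neck0.3__default,1020,peak_spine_Ca,274.07126002451224
pka_uniform__ac_spine__neck0.3__default,1020,peak_dend_Ca,112.08638703423462
pka_uniform__ac_spine__neck0.3__default,1020,auc_spine_cAMP,873.3084935495352
pka_uniform__ac_spine__neck0.3__default,1020,auc_dend_cAMP,776.6617973683276
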