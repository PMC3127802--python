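config,seed,metric,value
pka_spine__ac_spine__neck0.3__default,101,auc_pka_catalytic,65.99828175197965
pka_spine__ac_spine__neck0.3__default,101,mean_phospho_I1,892.1837879531049
pka_spine__ac_spine__neck0.3__default,101,mean_phospho_PDE4,75.66746150177288
pka_spine__ac_spine__neck0.3__default,101,auc_phospho_PDE4,510.75536513696693
pka_spine__ac_spine__neck0.3__default,101,mean_frac_pS845_GluR1,0.02196745562130177
pka_spine__ac_spine__neck0.3__default,1114,auc_pka_catalytic,64.25338161234723
pka_spine__ac_spine__neck0.3__default,1114,mean_phospho_I1,885.9758970423865
pka_spine__ac_spine__neck0.3__default,1114,mean_phospho_PDE4,74.60683592670219
pka_spine__ac_spine__neck0.3__default,1114,auc_phospho_PDE4,503.59614250523975
pka_spine__ac_spine__neck0.3__default,1114,mean_frac_pS845_GluR1,0.059578402366863896
pka_spine__ac_spine__neck0.3__default,2127,auc_pka_catalytic,39.11912151278888
pka_spine__ac_spine__neck0.3__default,2127,mean_phospho_I1,883.634157421442
pka_spine__ac_spine__neck0.3__default,2127,mean_phospho_PDE4,63.20035908799387
pka_spine__ac_spine__neck0.3__default,2127,auc_phospho_PDE4,426.6024238439586
pka_spine__ac_spine__neck0.3__default,2127,mean_frac_pS845_GluR1,0.014644970414201184
pka_spine__ac_dendrite_focal__neck0.3__default,101,auc_pka_catalytic,61.1356556275628
pka_spine__ac_dendrite_focal__neck0.3__default,101,mean_phospho_I1,896.1658857663184
pka_spine__ac_dendrite_focal__neck0.3__default,101,mean_phospho_PDE4,69.60973084272216
pka_spine__ac_dendrite_focal__neck0.3__default,101,auc_phospho_PDE4,469.86568318837453
pka_spine__ac_dendrite_focal__neck0.3__default,101,mean_frac_pS845_GluR1,0.03801775147928994
pka_spine__ac_dendrite_focal__neck0.3__default,1114,auc_pka_catalytic,70.73260639554118
pka_spine__ac_dendrite_focal__neck0.3__default,1114,mean_phospho_I1,889.0171173293276
pka_spine__ac_dendrite_focal__neck0.3__default,1114,mean_phospho_PDE4,77.69937680598538
pka_spine__ac_dendrite_focal__neck0.3__default,1114,auc_phospho_PDE4,524.4707934404013
pka_spine__ac_dendrite_focal__neck0.3__default,1114,mean_frac_pS845_GluR1,0.02659023668639053
pka_spine__ac_dendrite_focal__neck0.3__default,2127,auc_pka_catalytic,30.56141273973864
pka_spine__ac_dendrite_focal__neck0.3__default,2127,mean_phospho_I1,884.8487447735389
pka_spine__ac_dendrite_focal__neck0.3__default,2127,mean_phospho_PDE4,53.352507646342865
pka_spine__ac_dendrite_focal__neck0.3__default,2127,auc_phospho_PDE4,360.1294266128143
pka_spine__ac_dendrite_focal__neck0.3__default,2127,mean_frac_pS845_GluR1,0.004252958579881656
pka_dendrite_focal__ac_spine__neck0.3__default,101,auc_pka_catalytic,74.5944809692865
pka_dendrite_focal__ac_spine__neck0.3__default,101,mean_phospho_I1,893.1322685300947
pka_dendrite_focal__ac_spine__neck0.3__default,101,mean_phospho_PDE4,68.41795264277714
pka_dendrite_focal__ac_spine__neck0.3__default,101,auc_phospho_PDE4,461.82118033874565
pka_dendrite_focal__ac_spine__neck0.3__default,101,mean_frac_pS845_GluR1,0.004326923076923076
pka_dendrite_focal__ac_spine__neck0.3__default,1114,auc_pka_catalytic,63.63753450424166
pka_dendrite_focal__ac_spine__neck0.3__default,1114,mean_phospho_I1,887.967896330333
pka_dendrite_focal__ac_spine__neck0.3__default,1114,mean_phospho_PDE4,67.79070095859554
pka_dendrite_focal__ac_spine__neck0.3__default,1114,auc_phospho_PDE4,457.5872314705199
pka_dendrite_focal__ac_spine__neck0.3__default,1114,mean_frac_pS845_GluR1,0.0028846153846153843
pka_dendrite_focal__ac_spine__neck0.3__default,2127,auc_pka_catalytic,38.78553766256502
pka_dendrite_focal__ac_spine__neck0.3__default,2127,mean_phospho_I1,883.791920723827
pka_dendrite_focal__ac_spine__neck0.3__default,2127,mean_phospho_PDE4,62.75938214638742
pka_dendrite_focal__ac_spine__neck0.3__default,2127,auc_phospho_PDE4,423.62582948811513
pka_dendrite_focal__ac_spine__neck0.3__default,2127,mean_frac_pS845_GluR1,0.05306952662721892
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,101,auc_pka_catalytic,69.6035533640143
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,101,mean_phospho_I1,894.5065199472562
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,101,mean_phospho_PDE4,79.75029973699124
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,101,auc_phospho_PDE4,538.3145232246909
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,101,mean_frac_pS845_GluR1,0.02877218934911242
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1114,auc_pka_catalytic,60.968863702450875
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1114,mean_phospho_I1,888.6027510652319
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1114,mean_phospho_PDE4,75.78150726253317
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1114,auc_phospho_PDE4,511.5251740220989
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,1114,mean_frac_pS845_GluR1,0.023557692307692307
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,2127,auc_pka_catalytic,40.607418690710645
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,2127,mean_phospho_I1,886.069034413674
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,2127,mean_phospho_PDE4,65.11822863144609
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,2127,auc_phospho_PDE4,439.54804326226105
pka_dendrite_focal__ac_dendrite_focal__neck0.3__default,2127,mean_frac_pS845_GluR1,0.014201183431952662
pka_uniform__ac_spine__neck0.3__default,101,auc_pka_catalytic,67.74318189161208
pka_uniform__ac_spine__neck0.3__default,101,mean_phospho_I1,895.9549011089117
pka_uniform__ac_spine__neck0.3__default,101,mean_phospho_PDE4,86.00761047737248
pka_uniform__ac_spine__neck0.3__default,101,auc_phospho_PDE4,580.5513707222642
pka_uniform__ac_spine__neck0.3__default,101,mean_frac_pS845_GluR1,0.01201923076923077
pka_uniform__ac_spine__neck0.3__default,1114,auc_pka_catalytic,64.89488901662384
pka_uniform__ac_spine__neck0.3__default,1114,mean_phospho_I1,886.8274387227301
pka_uniform__ac_spine__neck0.3__default,1114,mean_phospho_PDE4,78.04341485094557
pka_uniform__ac_spine__neck0.3__default,1114,auc_phospho_PDE4,526.7930502438826
pka_uniform__ac_spine__neck0.3__default,1114,mean_frac_pS845_GluR1,0.043121301775147926
pka_uniform__ac_spine__neck0.3__default,2127,auc_pka_catalytic,44.12287926614658
pka_uniform__ac_spine__neck0.3__default,2127,mean_phospho_I1,885.348645358205
pka_uniform__ac_spine__neck0.3__default,2127,mean_phospho_PDE4,62.64343562294779
pka_uniform__ac_spine__neck0.3__default,2127,auc_phospho_PDE4,422.8431904548976
pka_uniform__ac_spine__neck0.3__default,2127,mean_frac_pS845_GluR1,0.0012573964497041422
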