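# Top global COVID-19 scientific and infodemic search keywords,
# 2020-02-20..2020-05-06: total average peak volume, 95% CI, I-scale score.
moniker,total_apc,ci_low,ci_high,iscale
coronavirus,1378,1246,1537,4
corona,530,477,610,8
COVID,345,292,398,1
virus,239,212,292,6
corona virus,159,133,186,7
coronavirus Italy,54,45,62,4
COVID-19,53,45,60,0
coronavirus USA,32,29,36,4
coronavirus China,30,25,34,6
coronavirus Germany,23,20,27,4
corona Italy,13,12,14,7
corona Deutschland,12,10,14,7
SARS,9,8,10,5
corona China,9,7,11,9
corona Wuhan,1,0,2,9
SARS-CoV-2,1,0,1,0
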