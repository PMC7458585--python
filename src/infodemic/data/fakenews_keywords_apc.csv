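# Top global fake-news-related COVID-19 search keywords,
# 2020-02-20..2020-05-06: total average peak volume, 95% CI, I-scale score.
moniker,total_apc,ci_low,ci_high,iscale
coronavirus ozone,19,15,22,5
coronavirus laboratory,16,12,19,9
coronavirus 5G,10,8,13,8
coronavirus conspiracy,9,8,11,9
coronavirus bill gates,8,7,10,6
coronavirus milk,7,6,8,8
coronavirus military,4,4,5,8
coronavirus uv,3,3,4,5
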