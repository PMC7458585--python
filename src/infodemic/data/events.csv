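# News events aligned with search spikes during the study window.
date,label,keyword
2020-03-25,Italian national press agency posts 2015 virus-origins video,coronavirus laboratory
2020-04-04,US president touts hydroxychloroquine as a miracle cure,covid cure
2020-04-17,Nobel laureate claims laboratory-accident origin of the virus,coronavirus laboratory
2020-04-24,US president suggests disinfectant injection as treatment,covid cure
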