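tag,count,group
#2019nCOV,38993,scientific
#SARSCoV2,49011,scientific
#SARS,53633,infodemic
#COVID,5890625,infodemic
#corona,18849998,infodemic
#coronavirus,22458007,infodemic
#COVID19,26213280,scientific
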