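# Top 10 countries by COVID-19-related Instagram hashtag count,
# as of 2020-05-06 (raw post counts; tables display multiples of 100,000).
country,hashtag_count
Italy,963000
Brazil,551000
Spain,376000
Indonesia,298000
Turkey,244000
India,165000
Malaysia,89000
Dominican Republic,83000
United States,75000
Argentina,74000
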