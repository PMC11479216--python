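name,latitude,longitude,elevation,annual_mean_min_temp,annual_mean_max_temp
Dilla,6.380556,38.30694,1515,12.7,28
Fiseha Genet,6.0667,38.18333,2240,12.1,22
Yirga Chefe,6.150667,38.202,1856,10.4,24.5
Hagere Selam,6.49,38.52,2809,7,19.2
Gedebe,5.905667,38.2395,2245,11.9,22.02
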