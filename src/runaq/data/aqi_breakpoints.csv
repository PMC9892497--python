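pollutant,conc_low,conc_high,index_low,index_high,category
pm25,0.0,12.0,0,50,good
pm25,12.1,35.4,51,100,moderate
pm25,35.5,55.4,101,150,unhealthy-for-sensitive-groups
pm25,55.5,150.4,151,200,unhealthy
pm25,150.5,250.4,201,300,very-unhealthy
ozone,0,54,0,50,good
ozone,55,70,51,100,moderate
ozone,71,85,101,150,unhealthy-for-sensitive-groups
ozone,86,105,151,200,unhealthy
ozone,106,200,201,300,very-unhealthy
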