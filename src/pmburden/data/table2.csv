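source,microenvironment,mean_fraction_pct,sd_fraction_pct,fraction_q25_pct,fraction_q75_pct,deaths,deaths_sd,deaths_q25,deaths_q75
ambient_generated,residence,42.1,23.8,22.6,58.9,107700,61000,57800,150600
ambient_generated,other_indoor,10.9,12.9,0.0,16.9,28000,33000,100,43300
ambient_generated,vehicle,2.4,3.9,0.3,2.6,6100,9900,900,6700
ambient_generated,outdoor,7.3,11.1,1.8,7.5,18800,28600,4500,19100
ambient_generated,total,62.7,25.2,,,160500,40400,63300,219600
indoor_generated,residence,28.1,26.3,5.3,47.9,72000,67300,13700,122600
indoor_generated,other_indoor,9.1,12.6,0.0,12.8,23300,32200,0,32800
indoor_generated,total,37.3,25.2,,,95300,24000,13700,155400
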