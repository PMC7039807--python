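division,statistic,total,ag_residence,ag_other_indoor,ag_vehicle,ag_outdoor,ag_total,ig_residence,ig_other_indoor,ig_total
New England,median,13900,4500,1400,300,1000,7200,5500,1200,6700
New England,q25,7900,3400,0,100,200,3700,4200,0,4200
New England,q75,17600,5600,2200,300,1000,9100,6900,1600,8600
Middle Atlantic,median,39600,12800,4100,900,2600,20400,15900,3300,19300
Middle Atlantic,q25,22700,9800,0,100,700,10600,12200,0,12200
Middle Atlantic,q75,50300,15800,6300,1000,2600,25700,19900,4600,24500
East North Central,median,47100,15100,5200,1100,3300,24800,18300,4000,22300
East North Central,q25,26200,11300,0,200,900,12500,13800,0,13800
East North Central,q75,60200,18800,8200,1200,3400,31700,23000,5500,28500
West North Central,median,19700,6100,2100,400,1300,9900,8100,1700,9800
West North Central,q25,11100,4600,0,100,400,5000,6100,0,6100
West North Central,q75,25100,7500,3300,500,1300,12600,10100,2400,12500
South Atlantic,median,56200,14600,5700,1200,3700,25300,26100,4800,30900
South Atlantic,q25,32400,10800,0,200,1000,12000,20400,0,20400
South Atlantic,q75,71600,18200,9000,1400,3800,32500,32400,6700,39200
East South Central,median,21600,5800,2300,500,1500,10000,9800,1800,11600
East South Central,q25,12500,4400,0,100,400,4900,7700,0,7700
East South Central,q75,27500,7100,3700,600,1500,12800,12100,2500,14600
West South Central,median,29300,9800,3300,700,2100,16000,10600,2700,13300
West South Central,q25,15800,7300,0,100,600,8000,7800,0,7800
West South Central,q75,37700,12400,5300,800,2200,20600,13400,3700,17100
Mountain,median,16000,4800,1600,300,1000,7800,6700,1500,8200
Mountain,q25,9000,3700,0,100,300,4000,5100,0,5100
Mountain,q75,20400,6000,2500,400,1000,9800,8400,2100,10500
Pacific,median,38500,11100,3800,800,2500,18200,17000,3300,20300
Pacific,q25,22000,8300,0,100,600,9000,13000,0,13000
Pacific,q75,48900,13800,5900,900,2400,23000,21300,4600,25900
Total,median,281800,84700,29500,6200,19100,139500,118000,24400,142300
Total,q25,159700,63500,0,1100,5000,69600,90100,0,90100
Total,q75,359300,105200,46400,7100,19200,177900,147600,33800,181400
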