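division,ig_res_mean,ig_res_sd,f_inf_mean,f_inf_sd,outdoor_mean,outdoor_p10,outdoor_p90,y0_per_100k,pop
New England,5.78,2.14,0.50,0.08,9.22,7.25,11.20,1429.5,8209960
Middle Atlantic,5.84,2.01,0.50,0.08,9.22,7.25,11.20,1475.6,22655120
East North Central,5.66,1.91,0.46,0.09,9.98,8.74,11.43,1576.8,25115038
West North Central,5.69,1.86,0.45,0.09,9.40,7.74,11.16,1566.0,10965126
South Atlantic,6.47,2.07,0.40,0.08,8.86,6.90,10.66,1481.7,33363675
East South Central,6.81,1.94,0.40,0.08,9.82,8.34,11.37,1759.6,9999343
West South Central,4.80,1.54,0.46,0.09,9.61,8.01,11.14,1449.3,18513908
Mountain,5.38,1.82,0.49,0.09,7.95,6.03,10.25,1332.1,11481569
Pacific,6.30,2.03,0.46,0.08,9.06,6.01,12.88,1241.2,26212977
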