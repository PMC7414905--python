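species,habitat,activity,activity_source,n,mass_mean_g,mass_sd_g,endothermy_mean_c,endothermy_sd_c,slope_th,slope_th_sd,slope_abd,slope_abd_sd,slope_env,slope_env_sd,H_th_abd,P_th_abd,H_abd_env,P_abd_env
Canthon smaragdulus,native_forest,diurnal,literature,8,0.156,0.08,3.138,0.68,-0.0025,0.02,-0.0034,0.01,0.0004,0.0017,0.0028,0.9807,0.03,0.8561
Coprophanaeus saphirinus,native_forest,diurnal,literature,14,0.423,0.23,7.254,1.06,0.0026,0.01,-0.0049,0.01,0.0013,0.0028,4.5,0.0345,3.5,0.0595
Deltochilum brasiliensis,native_forest,ENC,literature,8,1.008,0.07,2.337,1.26,-0.0027,0.01,-0.0008,0.01,-0.0005,0.00089,0.04,0.8775,0.4,0.5546
Deltochilum furcatum,native_forest,ENC,sampling,3,0.663,0.05,3.985,0.79,0.0104,0.01,-0.0022,0.01,0.0013,0.00099,2.3,0.2,0.4,0.7
Deltochilum morbillosum,native_forest,ENC,literature,6,0.228,0.02,2.885,0.47,0.0002,0.0031,-0.0006,0.0015,-3.33e-05,0.00073,0.03,0.8777,0.8,0.4221
Canthon conformis,agroforestry,diurnal,sampling,13,0.04,0.01,3.332,0.97,-0.0058,0.01,-0.0087,0.01,0.0008,0.0016,0.4,0.5049,2.1,0.1438
Canthon quinquemaculatus,agroforestry,diurnal,sampling,10,0.17,0.02,1.841,0.43,-0.0063,0.0035,-0.0036,0.0042,-0.0001,0.00071,2.1,0.1506,3.0,0.0819
Canthon histrio,agroforestry,diurnal,sampling,8,0.147,0.02,3.771,0.69,-0.0051,0.01,0.0034,0.01,1e-05,0.0021,2.5,0.1304,2.5,0.1304
Coprophanaeus cyanescens,agroforestry,ENC,sampling,6,1.713,0.28,9.217,3.99,0.0048,0.01,0.0127,0.03,0.0017,0.0021,0.1,0.7835,0.1,0.7565
Deltochilum aff. komareki,agroforestry,ENC,sampling,5,0.232,0.05,2.019,0.92,0.0021,0.01,-0.002,0.0035,0.0006,0.0021,0.3,0.6905,1.3,0.3095
Dichotomius carbonarius,agroforestry,ENC,literature,7,0.525,0.05,4.042,0.68,-0.0033,0.0033,-0.0011,0.0026,0.0067,0.01,1.6,0.2203,1.5,0.2328
Dichotomius mormon,agroforestry,ENC,sampling,8,1.021,0.16,5.025,1.68,0.0003,0.01,0.0015,0.0048,0.0004,0.001,0.5,0.5054,0.1,0.7422
Dichotomius sericeus,agroforestry,ENC,sampling,5,0.336,0.08,2.779,2.78,0.0099,0.02,0.0022,0.01,-0.0007,0.00087,0.01,0.9999,2.4,0.1508
Canthon curvodilatus,open_pasture,diurnal,literature,4,0.027,0.0029,0.472,0.14,-0.0014,0.01,-0.0004,0.01,0.0004,0.00081,0.3,0.6857,1.3,0.3429
Canthon podagricus,open_pasture,diurnal,literature,11,0.028,0.0035,1.142,0.73,0.0009,0.01,0.0018,0.02,0.0001,0.0015,0.1,0.7926,0.2,0.6222
Dichotomius nisus,open_pasture,ENC,sampling,6,0.511,0.02,6.143,1.14,0.0006,0.0016,0.0011,0.0037,0.0014,0.0021,0.0,0.9999,0.3,0.6126
Ontherus sulcator,open_pasture,ENC,sampling,6,0.317,0.02,2.248,0.33,0.002,0.0046,0.0019,0.0048,-0.0003,0.0018,0.03,0.8777,0.2,0.6667
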