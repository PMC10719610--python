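pollutant,statistic,units,conc_lo,conc_hi,aqi_lo,aqi_hi,category,precision
PM25,mean_24h,ug m^-3,0.0,12.0,0,50,Good,1
PM25,mean_24h,ug m^-3,12.1,35.4,51,100,Moderate,1
PM25,mean_24h,ug m^-3,35.5,55.4,101,150,Unhealthy for Sensitive Groups,1
PM25,mean_24h,ug m^-3,55.5,150.4,151,200,Unhealthy,1
PM25,mean_24h,ug m^-3,150.5,250.4,201,300,Very Unhealthy,1
PM25,mean_24h,ug m^-3,250.5,350.4,301,400,Hazardous,1
PM25,mean_24h,ug m^-3,350.5,500.4,401,500,Hazardous,1
O3,max_rolling_8h,ppm,0.000,0.054,0,50,Good,3
O3,max_rolling_8h,ppm,0.055,0.070,51,100,Moderate,3
O3,max_rolling_8h,ppm,0.071,0.085,101,150,Unhealthy for Sensitive Groups,3
O3,max_rolling_8h,ppm,0.086,0.105,151,200,Unhealthy,3
O3,max_rolling_8h,ppm,0.106,0.200,201,300,Very Unhealthy,3
CO,max_rolling_8h,ppm,0.0,4.4,0,50,Good,1
CO,max_rolling_8h,ppm,4.5,9.4,51,100,Moderate,1
CO,max_rolling_8h,ppm,9.5,12.4,101,150,Unhealthy for Sensitive Groups,1
CO,max_rolling_8h,ppm,12.5,15.4,151,200,Unhealthy,1
CO,max_rolling_8h,ppm,15.5,30.4,201,300,Very Unhealthy,1
CO,max_rolling_8h,ppm,30.5,40.4,301,400,Hazardous,1
CO,max_rolling_8h,ppm,40.5,50.4,401,500,Hazardous,1
SO2,max_1h,ppb,0,35,0,50,Good,0
SO2,max_1h,ppb,36,75,51,100,Moderate,0
SO2,max_1h,ppb,76,185,101,150,Unhealthy for Sensitive Groups,0
SO2,max_1h,ppb,186,304,151,200,Unhealthy,0
SO2,max_1h,ppb,305,604,201,300,Very Unhealthy,0
SO2,max_1h,ppb,605,804,301,400,Hazardous,0
SO2,max_1h,ppb,805,1004,401,500,Hazardous,0
NO2,max_1h,ppb,0,53,0,50,Good,0
NO2,max_1h,ppb,54,100,51,100,Moderate,0
NO2,max_1h,ppb,101,360,101,150,Unhealthy for Sensitive Groups,0
NO2,max_1h,ppb,361,649,151,200,Unhealthy,0
NO2,max_1h,ppb,650,1249,201,300,Very Unhealthy,0
NO2,max_1h,ppb,1250,1649,301,400,Hazardous,0
NO2,max_1h,ppb,1650,2049,401,500,Hazardous,0
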