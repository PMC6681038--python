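analyte,slope,intercept,r_squared,range_low,range_high,lod,loq
mannose,3.0804e4,6.3221e4,0.9998,20.20,202.04,0.19,0.63
glucosamine,7.2843e3,-7.3839e3,0.9999,8.40,151.26,0.83,2.76
lyxose,2.1137e4,1.9181e3,0.9999,4.26,42.63,0.22,0.73
erythrose,5.3561e3,1.3761e4,0.9998,12.14,133.54,0.54,1.80
glucuronic acid,2.5459e4,-4.0005e4,0.9995,8.14,81.38,1.15,3.83
galacturonic acid,3.1860e4,1.2310e4,0.9999,3.96,39.61,0.37,1.23
glucose,2.3516e4,1.5884e5,0.9999,199.82,3596.80,0.29,0.97
galactose,2.7091e4,7.5494e3,0.9998,41.33,413.33,0.74,2.47
xylose,1.7797e4,5.0060e4,0.9996,16.95,152.51,0.57,1.90
fucose,1.6309e4,5.7003e4,0.9991,8.07,80.67,0.78,2.60
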