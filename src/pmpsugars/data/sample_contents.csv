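sample,origin,mannose,glucosamine,lyxose,erythrose,glucuronic acid,galacturonic acid,glucose,galactose,xylose,fucose
S1,Shaanxi,234.88,111.70,291.81,271.27,72.81,46.14,3079.52,484.26,220.69,289.87
S2,Shanxi,145.22,61.86,302.68,460.78,37.15,29.94,2769.76,351.48,342.07,363.18
S3,Shanxi,107.39,99.07,217.79,331.03,31.02,27.53,1473.43,239.13,282.08,289.29
S4,Yunnan,153.97,106.59,182.08,520.85,52.42,55.43,3279.84,268.36,479.31,390.09
S5,Yunnan,175.84,102.97,221.64,439.15,47.16,38.33,2761.47,437.67,306.93,403.57
S6,Shaanxi,136.04,80.02,94.31,373.67,77.96,80.28,3329.49,516.64,284.02,291.84
S7,Shaanxi,160.08,75.85,129.04,355.81,41.13,35.81,2814.63,444.62,289.06,296.59
S8,Henan,82.81,63.42,115.88,153.51,26.26,16.21,1222.47,266.39,101.85,169.37
S9,Hebei,55.98,69.50,77.42,157.88,20.88,15.67,1284.87,126.54,110.60,117.21
S10,Sichuan,69.01,60.01,136.19,150.25,23.89,17.32,1379.81,253.40,129.34,169.23
S11,Jilin,76.03,64.66,50.73,146.89,34.02,32.02,1094.02,222.16,117.18,130.78
S12,Gansu,174.90,153.11,68.71,321.26,70.45,70.53,3474.96,308.13,261.42,224.71
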