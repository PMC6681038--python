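analyte,original,spiked,found,recovery_pct,rsd_pct
mannose,234.88,230,470.88,102.61,1.79
glucosamine,111.70,110,217.41,96.10,2.01
lyxose,291.81,291,576.87,97.96,1.25
erythrose,271.27,271,545.06,101.03,2.36
glucuronic acid,72.81,72,143.73,98.50,1.56
galacturonic acid,46.14,46,90.90,97.30,1.37
glucose,3079.52,3000,6091.52,100.40,0.96
galactose,484.26,485,977.36,101.67,1.01
xylose,220.69,220,439.59,99.50,1.16
fucose,289.87,290,590.60,103.70,1.43
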