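risk,sex,measure,value_1990,value_2019,pct_change_printed
all_risks,Male,dalys_thousands,42898.31,67474,57.29
all_risks,Male,asdr_per_100k,2226.75,1711.58,-23.14
all_risks,Male,paf_pct,48.39,47.22,-2.41
all_risks,Female,dalys_thousands,22580.18,37563.38,66.36
all_risks,Female,asdr_per_100k,1037.14,866.87,-16.42
all_risks,Female,paf_pct,32.62,33.55,2.85
all_risks,Both,dalys_thousands,65478.5,105037.38,60.42
all_risks,Both,asdr_per_100k,1587.05,1262.68,-20.44
all_risks,Both,paf_pct,41.51,41.23,-0.66
air_pollution,Male,dalys_thousands,4291.25,6253.19,45.72
air_pollution,Male,asdr_per_100k,219.38,157.86,-28.04
air_pollution,Male,paf_pct,4.76,4.35,-8.64
air_pollution,Female,dalys_thousands,1463.54,2698.78,84.4
air_pollution,Female,asdr_per_100k,67.37,61.97,-8.02
air_pollution,Female,paf_pct,2.12,2.4,13.16
air_pollution,Both,dalys_thousands,5754.8,8951.97,55.56
air_pollution,Both,asdr_per_100k,138.76,107.36,-22.63
air_pollution,Both,paf_pct,3.63,3.5,-3.39
other_environmental,Male,dalys_thousands,925.51,1299.59,40.42
other_environmental,Male,asdr_per_100k,47.76,32.99,-30.92
other_environmental,Male,paf_pct,1.04,0.91,-12.29
other_environmental,Female,dalys_thousands,287.99,585.89,103.44
other_environmental,Female,asdr_per_100k,13.29,13.44,1.14
other_environmental,Female,paf_pct,0.42,0.52,24.53
other_environmental,Both,dalys_thousands,1213.5,1885.48,55.37
other_environmental,Both,asdr_per_100k,29.43,22.66,-22.98
other_environmental,Both,paf_pct,0.77,0.74,-3.8
tobacco,Male,dalys_thousands,32710,47632.1,45.62
tobacco,Male,asdr_per_100k,1707.61,1207.72,-29.27
tobacco,Male,paf_pct,37.11,33.31,-10.22
tobacco,Female,dalys_thousands,7552.81,11691.47,54.8
tobacco,Female,asdr_per_100k,350.69,267.84,-23.62
tobacco,Female,paf_pct,11.03,10.37,-6.02
tobacco,Both,dalys_thousands,40262.81,59323.57,47.34
tobacco,Both,asdr_per_100k,983.22,711.71,-27.61
tobacco,Both,paf_pct,25.71,23.24,-9.63
alcohol_use,Male,dalys_thousands,6073.94,10470.27,72.38
alcohol_use,Male,asdr_per_100k,300.94,259.87,-13.65
alcohol_use,Male,paf_pct,6.54,7.17,9.65
alcohol_use,Female,dalys_thousands,1885.77,2521.1,33.69
alcohol_use,Female,asdr_per_100k,86.99,58.25,-33.04
alcohol_use,Female,paf_pct,2.74,2.26,-17.59
alcohol_use,Both,dalys_thousands,7959.7,12991.38,63.21
alcohol_use,Both,asdr_per_100k,189.37,155.19,-18.05
alcohol_use,Both,paf_pct,4.95,5.07,2.31
drug_use,Male,dalys_thousands,624.56,966.06,54.68
drug_use,Male,asdr_per_100k,31.29,24.52,-21.66
drug_use,Male,paf_pct,0.68,0.68,-0.51
drug_use,Female,dalys_thousands,411.46,645.12,56.79
drug_use,Female,asdr_per_100k,18.97,14.76,-22.19
drug_use,Female,paf_pct,0.6,0.57,-4.16
drug_use,Both,dalys_thousands,1036.02,1611.18,55.52
drug_use,Both,asdr_per_100k,24.82,19.36,-21.98
drug_use,Both,paf_pct,0.65,0.63,-2.56
high_fpg,Male,dalys_thousands,1798.2,4599.74,155.8
high_fpg,Male,asdr_per_100k,100.9,120.41,19.35
high_fpg,Male,paf_pct,2.19,3.32,51.57
high_fpg,Female,dalys_thousands,1489.43,3981.04,167.29
high_fpg,Female,asdr_per_100k,70.24,90.98,29.54
high_fpg,Female,paf_pct,2.21,3.52,59.51
high_fpg,Both,dalys_thousands,3287.64,8580.78,161.0
high_fpg,Both,asdr_per_100k,83.74,104.24,24.49
high_fpg,Both,paf_pct,2.19,3.41,55.51
high_bmi,Male,dalys_thousands,2236.51,6011.22,168.78
high_bmi,Male,asdr_per_100k,113.66,150.73,32.62
high_bmi,Male,paf_pct,2.47,4.16,68.44
high_bmi,Female,dalys_thousands,2249.66,5164.09,129.55
high_bmi,Female,asdr_per_100k,105.02,117.76,12.13
high_bmi,Female,paf_pct,3.3,4.56,37.9
high_bmi,Both,dalys_thousands,4486.18,11175.31,149.11
high_bmi,Both,asdr_per_100k,109.89,133.93,21.88
high_bmi,Both,paf_pct,2.87,4.37,52.16
dietary_risks,Male,dalys_thousands,5491.49,8347.44,52.01
dietary_risks,Male,asdr_per_100k,286.43,213.16,-25.58
dietary_risks,Male,paf_pct,6.22,5.88,-5.5
dietary_risks,Female,dalys_thousands,3877.51,5603.85,44.52
dietary_risks,Female,asdr_per_100k,180.01,129.18,-28.24
dietary_risks,Female,paf_pct,5.66,5.0,-11.71
dietary_risks,Both,dalys_thousands,9369,13951.29,48.91
dietary_risks,Both,asdr_per_100k,229.56,168.77,-26.48
dietary_risks,Both,paf_pct,6.0,5.51,-8.21
low_physical_activity,Male,dalys_thousands,205.58,478.9,132.95
low_physical_activity,Male,asdr_per_100k,12.89,13.26,2.91
low_physical_activity,Male,paf_pct,0.28,0.37,30.66
low_physical_activity,Female,dalys_thousands,402.34,723.76,79.89
low_physical_activity,Female,asdr_per_100k,19.34,16.58,-14.28
low_physical_activity,Female,paf_pct,0.61,0.64,5.46
low_physical_activity,Both,dalys_thousands,607.92,1202.65,97.83
low_physical_activity,Both,asdr_per_100k,16.35,14.98,-8.37
low_physical_activity,Both,paf_pct,0.43,0.49,14.37
occupational_risks,Male,dalys_thousands,3760.3,5523.05,46.88
occupational_risks,Male,asdr_per_100k,206.29,144.38,-30.01
occupational_risks,Male,paf_pct,4.49,3.98,-11.17
occupational_risks,Female,dalys_thousands,765.15,1441.73,88.42
occupational_risks,Female,asdr_per_100k,35.24,33.1,-6.06
occupational_risks,Female,paf_pct,1.11,1.28,15.57
occupational_risks,Both,dalys_thousands,4525.45,6964.78,53.9
occupational_risks,Both,asdr_per_100k,112.44,84.42,-24.92
occupational_risks,Both,paf_pct,2.94,2.76,-6.28
unsafe_sex,Female,dalys_thousands,6176.25,8955.01,44.99
unsafe_sex,Female,asdr_per_100k,275.05,210.64,-23.42
unsafe_sex,Female,paf_pct,8.65,8.15,-5.73
unsafe_sex,Both,dalys_thousands,6176.25,8955.01,44.99
unsafe_sex,Both,asdr_per_100k,139.98,107.2,-23.42
unsafe_sex,Both,paf_pct,3.66,3.5,-4.36
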