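sample_id,treatment,timepoint_days,replicate,time_us,f
control_r1,control,15,1,10.0,500.2783068881114
control_r1,control,15,1,14.677992676220699,500.5994022707298
control_r1,control,15,1,21.544346900318832,501.29048395000194
control_r1,control,15,1,31.622776601683793,502.7761455424839
control_r1,control,15,1,46.41588833612777,505.9620001184043
control_r1,control,15,1,68.12920690579611,512.7573194744803
control_r1,control,15,1,100.0,527.0876460266504
control_r1,control,15,1,146.7799267622069,556.5967519917893
control_r1,control,15,1,215.44346900318823,614.4891257653793
control_r1,control,15,1,316.2277660168379,717.9969548495719
control_r1,control,15,1,464.15888336127773,875.6988878039548
control_r1,control,15,1,681.2920690579608,1065.9921156960318
control_r1,control,15,1,1000.0,1241.2972019423655
control_r1,control,15,1,1467.799267622069,1369.615258209813
control_r1,control,15,1,2154.4346900318824,1454.92697176323
control_r1,control,15,1,3162.2776601683795,1520.420444757418
control_r1,control,15,1,4641.588833612777,1591.2599283197226
control_r1,control,15,1,6812.920690579608,1685.3922400785827
control_r1,control,15,1,10000.0,1802.5667596652054
control_r1,control,15,1,14677.992676220676,1921.1501061908725
control_r1,control,15,1,21544.346900318822,2019.9202462586668
control_r1,control,15,1,31622.776601683792,2099.1487290619602
control_r1,control,15,1,46415.888336127726,2173.958734604143
control_r1,control,15,1,68129.20690579608,2255.4177691693294
control_r1,control,15,1,100000.0,2337.9258462609378
control_r1,control,15,1,146779.92676220674,2405.60054639217
control_r1,control,15,1,215443.46900318822,2450.232099213951
control_r1,control,15,1,316227.7660168379,2475.3368490376197
control_r1,control,15,1,464158.8833612772,2488.1802948179457
control_r1,control,15,1,681292.0690579608,2494.4296468367365
control_r1,control,15,1,1000000.0,2497.3959258087507
NaCl500_r1,NaCl500,15,1,10.0,500.19481482167794
NaCl500_r1,NaCl500,15,1,14.677992676220699,500.41958158951087
NaCl500_r1,NaCl500,15,1,21.544346900318832,500.90333876500137
NaCl500_r1,NaCl500,15,1,31.622776601683793,501.9433018797387
NaCl500_r1,NaCl500,15,1,46.41588833612777,504.173400082883
NaCl500_r1,NaCl500,15,1,68.12920690579611,508.9301236321362
NaCl500_r1,NaCl500,15,1,100.0,518.9613522186553
NaCl500_r1,NaCl500,15,1,146.7799267622069,539.6177263942525
NaCl500_r1,NaCl500,15,1,215.44346900318823,580.1423880357655
NaCl500_r1,NaCl500,15,1,316.2277660168379,652.5978683947003
NaCl500_r1,NaCl500,15,1,464.15888336127773,762.9892214627683
NaCl500_r1,NaCl500,15,1,681.2920690579608,896.1944809872223
NaCl500_r1,NaCl500,15,1,1000.0,1018.9080413596558
NaCl500_r1,NaCl500,15,1,1467.799267622069,1108.730680746869
NaCl500_r1,NaCl500,15,1,2154.4346900318824,1168.4488802342612
NaCl500_r1,NaCl500,15,1,3162.2776601683795,1214.2943113301926
NaCl500_r1,NaCl500,15,1,4641.588833612777,1263.8819498238058
NaCl500_r1,NaCl500,15,1,6812.920690579608,1329.7745680550079
NaCl500_r1,NaCl500,15,1,10000.0,1411.7967317656437
NaCl500_r1,NaCl500,15,1,14677.992676220676,1494.8050743336107
NaCl500_r1,NaCl500,15,1,21544.346900318822,1563.9441723810667
NaCl500_r1,NaCl500,15,1,31622.776601683792,1619.4041103433722
NaCl500_r1,NaCl500,15,1,46415.888336127726,1671.7711142229002
NaCl500_r1,NaCl500,15,1,68129.20690579608,1728.7924384185308
NaCl500_r1,NaCl500,15,1,100000.0,1786.5480923826563
NaCl500_r1,NaCl500,15,1,146779.92676220674,1833.9203824745193
NaCl500_r1,NaCl500,15,1,215443.46900318822,1865.162469449766
NaCl500_r1,NaCl500,15,1,316227.7660168379,1882.735794326334
NaCl500_r1,NaCl500,15,1,464158.8833612772,1891.726206372562
NaCl500_r1,NaCl500,15,1,681292.0690579608,1896.1007527857157
NaCl500_r1,NaCl500,15,1,1000000.0,1898.1771480661255
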