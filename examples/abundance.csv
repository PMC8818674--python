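protein_id,accession,description,functional_group,control_r1,control_r2,control_r3,treated_r1,treated_r2,treated_r3
P00001,ACC00001,synthetic protein 1,,25010.06,24297.15,26548.05,0.0,0.0,0.0
P00002,ACC00002,synthetic protein 2,,0.0,0.0,0.0,12117.01,12021.29,11732.38
P00003,ACC00003,synthetic protein 3,,4840.19,4475.73,4753.41,24084.98,21590.2,20775.08
P00004,ACC00004,synthetic protein 4,,4111.07,3730.12,4057.7,909.77,566.11,700.93
P00005,ACC00005,synthetic protein 5,,6464.67,6551.29,5963.48,899.47,1010.27,730.29
P00006,ACC00006,synthetic protein 6,,12057.6,12194.18,11755.13,9754.29,9150.9,9409.98
P00007,ACC00007,synthetic protein 7,,3974.64,3554.35,3704.01,4398.52,3807.0,4315.21
P00008,ACC00008,synthetic protein 8,,8008.32,8780.94,8666.18,9358.27,10027.19,9889.61
P00009,ACC00009,synthetic protein 9,,8802.43,7638.37,8550.26,9356.2,8155.63,9579.97
P00010,ACC00010,synthetic protein 10,,17771.84,18058.72,16652.08,19674.84,21076.15,19787.89
P00011,ACC00011,synthetic protein 11,,13576.56,11602.52,11991.14,14662.93,10511.05,13001.58
P00012,ACC00012,synthetic protein 12,,14949.99,14302.16,15769.5,18464.66,17739.01,19507.64
P00013,ACC00013,synthetic protein 13,,5249.76,5038.44,5103.25,6161.26,5894.55,5771.28
P00014,ACC00014,synthetic protein 14,,8317.94,8240.72,9065.65,6058.19,6564.79,6975.36
P00015,ACC00015,synthetic protein 15,,22547.38,23366.15,21090.66,27914.1,27014.0,24841.33
P00016,ACC00016,synthetic protein 16,,48447.06,43888.26,48170.01,37706.65,34742.41,39095.42
P00017,ACC00017,synthetic protein 17,,2778.41,2736.68,2874.87,2857.95,3077.98,3168.31
P00018,ACC00018,synthetic protein 18,,47850.5,45812.61,44134.09,39018.85,35159.58,39178.74
P00019,ACC00019,synthetic protein 19,,35923.78,35815.63,39393.26,41620.9,41016.16,45780.99
P00020,ACC00020,synthetic protein 20,,22951.47,21664.65,20700.92,25603.0,22014.37,21179.06
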